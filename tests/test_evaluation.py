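"""ROC/AUROC, Youden cutoff, Spearman — pinned against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sclerascan as ss
from sclerascan.errors import (
    DegenerateCohortError,
    ParameterError,
    UndefinedCorrelationError,
)
from sclerascan.evaluation import CohortRecord, records_from_frame


def make_records(pos, neg):
    recs = [CohortRecord(f"p{i}", m, None, True) for i, m in enumerate(pos)]
    recs += [CohortRecord(f"n{i}", m, None, False) for i, m in enumerate(neg)]
    return recs


def auroc_bruteforce(pos, neg):
    """Exhaustive concordant-pair count; ties score one half."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_bruteforce(pos, neg):
    """Best J over all observed thresholds with rule score >= t."""
    best_j, best_t = -np.inf, None
    for t in sorted(set(pos) | set(neg)):
        sens = np.mean([p >= t for p in pos])
        spec = np.mean([n < t for n in neg])
        j = sens + spec - 1
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and (best_t is None or t < best_t)):
            best_j, best_t = j, t
    return best_t, best_j


class TestRoc:
    def test_perfect_separation(self):
        res = ss.roc(make_records([50, 60], [30, 40]))
        assert res.auroc == 1.0
        assert 40 < res.optimal_cutoff <= 50
        assert res.youden_j == 1.0

    def test_complete_tie_gives_half(self):
        res = ss.roc(make_records([40], [40]))
        assert res.auroc == 0.5

    def test_interleaved_scores_match_pair_counting(self):
        pos = [41, 55, 38, 47, 60, 44]
        neg = [35, 42, 39, 47, 33, 45]
        res = ss.roc(make_records(pos, neg))
        assert res.auroc == pytest.approx(auroc_bruteforce(pos, neg), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateCohortError):
            ss.roc(make_records([50, 60], []))

    def test_optimal_cutoff_matches_bruteforce_youden(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pos = list(np.round(rng.normal(52, 8, rng.integers(2, 10)), 1))
            neg = list(np.round(rng.normal(40, 6, rng.integers(2, 10)), 1))
            res = ss.roc(make_records(pos, neg))
            t, j = youden_bruteforce(pos, neg)
            assert res.optimal_cutoff == t
            assert res.youden_j == pytest.approx(j, abs=1e-12)

    def test_auroc_equals_rank_statistic(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(8)
        scores = np.round(rng.normal(45, 10, 30), 0)  # rounding forces ties
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        res = ss.roc(make_records(scores[labels], scores[~labels]))
        r = rankdata(scores)
        n_pos, n_neg = labels.sum(), (~labels).sum()
        u = r[labels].sum() - n_pos * (n_pos + 1) / 2
        assert res.auroc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    # scores on a 0.001 grid: the affine transform below must stay injective
    # in floating point for "strictly monotone" to mean anything
    _scores = st.lists(
        st.floats(0, 100).map(lambda v: round(v, 3)), min_size=1, max_size=12
    )

    def test_auroc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = np.round(rng.normal(45, 9, 40), 1)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        res = ss.roc(make_records(scores[labels], scores[~labels]))
        assert res.auroc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(_scores, _scores)
    def test_complement_and_monotone_invariance(self, pos, neg):
        res = ss.roc(make_records(pos, neg))
        flipped = ss.roc(make_records(neg, pos))
        assert res.auroc + flipped.auroc == pytest.approx(1.0, abs=1e-9)
        # strictly monotone transform of scores leaves AUROC unchanged
        f = lambda v: [3.0 * x + 7.0 for x in v]
        assert ss.roc(make_records(f(pos), f(neg))).auroc == pytest.approx(res.auroc, abs=1e-9)


class TestSpearman:
    def test_strictly_monotone_is_plus_minus_one(self):
        x = [1.0, 2.5, 3.0, 7.0, 9.0]
        assert ss.spearman(x, [2, 4, 6, 8, 10]) == pytest.approx(1.0)
        assert ss.spearman(x, [10, 8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # d^2 sum = 4 over n = 5 untied ranks: rs = 1 - 6*4/120 = 0.8,
        # confirmed by the independent rank-Pearson oracle (scipy)
        from scipy.stats import spearmanr

        x, y = [1, 2, 3, 4, 5], [1, 3, 2, 5, 4]
        assert ss.spearman(x, y) == pytest.approx(0.8, abs=1e-12)
        assert ss.spearman(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            ss.spearman([1, 1, 1], [1, 2, 3])

    def test_short_input_rejected(self):
        with pytest.raises(ParameterError):
            ss.spearman([1, 2], [3, 4])

    def test_ties_match_scipy_midranks(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        x = np.round(rng.normal(0, 1, 25), 1)
        y = np.round(x + rng.normal(0, 1, 25), 1)
        assert ss.spearman(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.floats(-50, 50).map(lambda v: round(v, 3)),
            min_size=3, max_size=15, unique=True,
        )
    )
    def test_symmetry_and_monotone_invariance(self, x):
        rng = np.random.default_rng(len(x))
        y = list(rng.normal(0, 1, len(x)))
        if len(set(y)) < 2:
            return
        rs = ss.spearman(x, y)
        assert ss.spearman(y, x) == pytest.approx(rs, abs=1e-12)
        assert ss.spearman([np.exp(v / 50) for v in x], y) == pytest.approx(rs, abs=1e-9)


class TestConfusionAt:
    def test_perfect_separation_cutoff(self):
        sens, spec, counts = ss.confusion_at(make_records([50, 60], [30, 40]), 45.0)
        assert sens == 1.0 and spec == 1.0
        assert counts == {"tp": 2, "fn": 0, "fp": 0, "tn": 2}

    def test_fully_inverted_toy(self):
        sens, spec, _ = ss.confusion_at(make_records([39], [41]), 40.8)
        assert sens == 0.0 and spec == 0.0

    def test_matches_bruteforce_on_synthetic_cohort(self):
        rng = np.random.default_rng(12)
        mhd = np.concatenate([rng.normal(52, 8, 30), rng.normal(39, 4, 30)])
        labels = np.array([True] * 30 + [False] * 30)
        recs = [CohortRecord(f"s{i}", m, None, bool(l)) for i, (m, l) in enumerate(zip(mhd, labels))]
        sens, spec, counts = ss.confusion_at(recs, 40.8)
        assert sens == np.mean(mhd[labels] >= 40.8)
        assert spec == np.mean(mhd[~labels] < 40.8)
        assert sum(counts.values()) == 60


class TestRecords:
    def test_label_derived_from_tsb(self):
        import pandas as pd

        df = pd.DataFrame(
            {"subject_id": ["a", "b"], "mhd": [50.0, 38.0], "tsb": [9.0, 0.8]}
        )
        recs = records_from_frame(df)
        assert [r.label for r in recs] == [True, False]

    def test_inconsistent_label_rejected(self):
        with pytest.raises(ParameterError):
            CohortRecord("x", 50.0, tsb=9.0, label=False)
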