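"""Cohort-level screening statistics: ROC/AUROC, Youden cutoff, Spearman.

Implemented from first principles on purpose — the empirical ROC, the
trapezoidal AUROC (equal to the tie-corrected Mann–Whitney concordance)
and the mid-rank Spearman coefficient are each a few lines, and owning
them lets the test suite pin them against brute-force oracles
(exhaustive pair counting; rank-Pearson) and against scipy/sklearn.

The decision rule everywhere is ``score >= threshold`` → positive,
matching the inclusive screening cutoff of the clinical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError, ParameterError, UndefinedCorrelationError

__all__ = [
    "CohortRecord",
    "RocResult",
    "roc",
    "spearman",
    "confusion_at",
    "records_from_frame",
]

JAUNDICE_TSB = 3.0  # classical definition: jaundice iff TSB >= 3 mg/dL


@dataclass(frozen=True)
class CohortRecord:
    subject_id: str
    mhd: float
    tsb: float | None
    label: bool  # True = jaundice

    def __post_init__(self):
        if self.tsb is not None and bool(self.tsb >= JAUNDICE_TSB) != self.label:
            raise ParameterError(
                f"{self.subject_id}: label {self.label} inconsistent with tsb {self.tsb}"
            )


def records_from_frame(df: pd.DataFrame) -> list:
    """Build cohort records from a DataFrame (subject_id, mhd, tsb[, label])."""
    recs = []
    for _, row in df.iterrows():
        tsb = float(row["tsb"]) if "tsb" in df.columns and pd.notna(row["tsb"]) else None
        if "label" in df.columns and pd.notna(row["label"]):
            lab = bool(row["label"])
        elif tsb is not None:
            lab = tsb >= JAUNDICE_TSB
        else:
            raise ParameterError(f"{row['subject_id']}: neither tsb nor label present")
        recs.append(CohortRecord(str(row["subject_id"]), float(row["mhd"]), tsb, lab))
    return recs


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray   # descending
    sensitivity: np.ndarray  # per threshold
    specificity: np.ndarray
    auroc: float
    optimal_cutoff: float
    youden_j: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _scores_labels(records):
    scores = np.asarray([r.mhd for r in records], dtype=float)
    labels = np.asarray([r.label for r in records], dtype=bool)
    if labels.all() or not labels.any():
        raise DegenerateCohortError("ROC needs at least one positive and one negative")
    return scores, labels


def roc(records, cutoff_criterion: str = "youden") -> RocResult:
    """Empirical ROC over all distinct score thresholds.

    AUROC is the trapezoidal area, which with one ROC point per distinct
    score equals the Mann–Whitney concordance probability with ties
    counted one half. The reported cutoff maximizes Youden's
    J = sensitivity + specificity − 1 (or, with
    ``cutoff_criterion="closest"``, minimizes the distance to the ideal
    (0, 1) corner); ties break toward the smallest threshold.
    """
    if cutoff_criterion not in ("youden", "closest"):
        raise ParameterError(f"unknown cutoff_criterion {cutoff_criterion!r}")
    scores, labels = _scores_labels(records)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    thresholds = np.unique(scores)[::-1]
    pred = scores[None, :] >= thresholds[:, None]  # rule: mhd >= t
    tpr = (pred & labels[None, :]).sum(axis=1) / n_pos
    fpr = (pred & ~labels[None, :]).sum(axis=1) / n_neg
    # area under the (fpr, tpr) polyline anchored at (0,0) and (1,1)
    fx = np.concatenate([[0.0], fpr, [1.0]])
    fy = np.concatenate([[0.0], tpr, [1.0]])
    auroc = float(np.trapezoid(fy, fx))
    if cutoff_criterion == "youden":
        crit = tpr - fpr  # == J; maximize
    else:
        crit = -np.hypot(fpr, 1.0 - tpr)
    best = np.max(crit)
    # ties -> smallest threshold; thresholds[] is descending
    idx = np.where(np.isclose(crit, best, rtol=0, atol=1e-12))[0][-1]
    return RocResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auroc=auroc,
        optimal_cutoff=float(thresholds[idx]),
        youden_j=float((tpr - fpr)[idx]),
    )


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ParameterError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def confusion_at(records, cutoff: float):
    """Sensitivity, specificity and counts at a fixed cutoff (rule >=)."""
    scores, labels = _scores_labels(records)
    pred = scores >= cutoff
    tp = int((pred & labels).sum())
    fn = int((~pred & labels).sum())
    fp = int((pred & ~labels).sum())
    tn = int((~pred & ~labels).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, {"tp": tp, "fn": fn, "fp": fp, "tn": tn}


def plot_roc(result: RocResult, ax=None):
    """ROC curve with the chosen operating point marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    fx = np.concatenate([[0.0], 1.0 - result.specificity, [1.0]])
    fy = np.concatenate([[0.0], result.sensitivity, [1.0]])
    ax.plot(fx, fy, "-", color="#2c5f8a", label=f"AUROC = {result.auroc:.3f}")
    ax.plot([0, 1], [0, 1], ":", color="gray")
    i = int(np.where(result.thresholds == result.optimal_cutoff)[0][0])
    ax.plot(1 - result.specificity[i], result.sensitivity[i], "o", color="#b3402a")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax
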