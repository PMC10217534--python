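"""End-to-end orchestration: image(s) in, assessment report out.

``run_assess`` executes the full measurement chain per image —

    read → estimate/compensate illuminant → median denoise → HSL
    → eye detection (or manual ROIs) → mask refinement
    → hue histogram → per-ROI MHD

— then pools MHDs across eyes and gaze patterns by maximum and applies
the clinical model. The report embeds per-stage intermediates (gains,
per-ROI MHDs and pixel counts) plus the effective configuration and
package version, and contains no timestamp, so repeated runs are
byte-identical.

``run_eval`` computes cohort statistics (ROC/AUROC, Youden cutoff,
Spearman, confusion at the model cutoff) from a cohort table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colorimetry import (
    compensate_illumination,
    denoise,
    estimate_illuminant,
    read_image,
    rgb_to_hsl,
)
from .config import RunConfig
from .errors import (
    DegenerateCohortError,
    InputError,
    NoEyesFoundError,
    SegmentationError,
)
from .evaluation import confusion_at, records_from_frame, roc, spearman
from .hue_stats import extract_mhd, hue_histogram, pool_mhd
from .model import assess
from .segmentation import detect_eyes, manual_roi, refine_mask

logger = logging.getLogger("sclerascan")

__all__ = ["run_assess", "run_eval", "read_cohort_csv"]


def _load(item):
    """Accept a path or an (id, array) pair; return (id, RgbImage)."""
    if isinstance(item, (str, Path)):
        return str(item), read_image(item)
    image_id, arr = item
    return str(image_id), np.asarray(arr)


def run_assess(images, manual_rois=None, config: RunConfig | None = None) -> dict:
    """Assess one subject from 1–4 images (up to 2 gaze patterns × 2 eyes).

    ``images``: paths or (id, uint8 array) pairs. ``manual_rois``:
    optional list of (r0, c0, r1, c1) boxes applied to every image in
    place of automatic detection. Returns the JSON-serializable report;
    a stage failure on one image degrades to the remaining images with a
    warning, but ending up with zero usable ROIs raises
    :class:`NoEyesFoundError`.
    """
    cfg = config or RunConfig()
    if not images:
        raise InputError("at least one image is required")
    per_image_reports = []
    roi_entries = []
    for item in images:
        image_id, img = _load(item)
        try:
            gains = estimate_illuminant(
                img, cfg.compensation.method, cfg.compensation.minkowski_p
            )
            comp = compensate_illumination(img, gains)
            den = denoise(comp, cfg.denoise_kernel)
            hsl = rgb_to_hsl(den)
            if manual_rois:
                rois = [manual_roi(den, bbox) for bbox in manual_rois]
            else:
                rois = detect_eyes(den, cfg.segmentation)
            image_report = {
                "image": image_id,
                "illuminant_gains": [round(float(g), 6) for g in gains.gains],
                "rois": [],
            }
            for roi in rois:
                try:
                    refined = refine_mask(roi, hsl, cfg.mask)
                    hist = hue_histogram(hsl, refined, cfg.bin_width)
                    mhd = extract_mhd(hist)
                except SegmentationError as exc:
                    logger.warning("%s: dropping ROI (%s)", image_id, exc)
                    continue
                roi_entries.append((image_id, refined.side, mhd, hist.n_pixels))
                image_report["rois"].append(
                    {
                        "side": refined.side,
                        "source": refined.source,
                        "bbox": list(refined.bbox),
                        "mhd": mhd,
                        "n_pixels": hist.n_pixels,
                    }
                )
            per_image_reports.append(image_report)
        except (InputError, SegmentationError) as exc:
            logger.warning("stage failure on image %s: %s", image_id, exc)
            per_image_reports.append({"image": image_id, "error": str(exc)})
    if not roi_entries:
        raise NoEyesFoundError(
            "no usable eye region in any input image; supply manual ROIs"
        )
    pooled = pool_mhd(roi_entries)
    assessment = assess(pooled, cfg.model)
    return {
        "sclerascan_version": __version__,
        "config": cfg.to_dict(),
        "images": per_image_reports,
        "pooled_mhd": pooled.pooled_mhd,
        "assessment": assessment.to_dict(),
    }


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (subject_id, mhd, tsb[, label]) with validation."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise InputError(f"cohort file does not exist: {path}") from exc
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise InputError(f"malformed cohort CSV {path}: {exc}") from exc
    required = {"subject_id", "mhd"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"cohort CSV {path} lacks column(s): {sorted(missing)}")
    if len(df) == 0:
        raise InputError(f"cohort CSV {path} has no rows")
    bad = df[~np.isfinite(df["mhd"].astype(float))]
    if len(bad):
        raise InputError(
            f"cohort CSV {path}: non-numeric mhd at line(s) "
            f"{[int(i) + 2 for i in bad.index]}"  # +2: header + 1-based
        )
    return df


def run_eval(cohort, config: RunConfig | None = None) -> dict:
    """Cohort statistics from a CSV path or DataFrame.

    Returns a summary dict (auroc, optimal_cutoff, youden_j, sens/spec at
    both the data-optimal and the model cutoff, Spearman rS when TSB is
    present) plus the ROC table under ``"roc_points"``.
    """
    cfg = config or RunConfig()
    df = read_cohort_csv(cohort) if isinstance(cohort, (str, Path)) else cohort
    records = records_from_frame(df)
    labels = [r.label for r in records]
    if all(labels) or not any(labels):
        raise DegenerateCohortError(
            "cohort contains a single class; ROC statistics are undefined"
        )
    roc_res = roc(records)
    sens_m, spec_m, counts_m = confusion_at(records, cfg.model.cutoff_mhd)
    summary = {
        "n": len(records),
        "n_jaundice": int(sum(labels)),
        "auroc": roc_res.auroc,
        "optimal_cutoff": roc_res.optimal_cutoff,
        "youden_j": roc_res.youden_j,
        "model_cutoff": cfg.model.cutoff_mhd,
        "sensitivity_at_model_cutoff": sens_m,
        "specificity_at_model_cutoff": spec_m,
        "counts_at_model_cutoff": counts_m,
        "roc_points": roc_res.to_frame().to_dict(orient="list"),
    }
    tsb = [r.tsb for r in records]
    if all(t is not None for t in tsb):
        summary["spearman_mhd_tsb"] = spearman([r.mhd for r in records], tsb)
    return summary
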