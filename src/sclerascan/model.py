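"""Jaundice classification and total-serum-bilirubin (TSB) quantification.

A subject's pooled maximum hue degree (MHD) is turned into clinical
outputs with two fixed, clinically derived constants:

* screening: jaundice iff MHD >= 40.8° (boundary inclusive — screening
  favours sensitivity);
* quantification: TSB peaks at MHD = 56.3°, and the estimate decreases
  linearly with the deviation from that peak,

      TSB ≈ 21.1603 − 0.7371 · |56.3 − MHD|   (mg/dL).

The linear-in-absolute-deviation form is the default; a squared-deviation
variant is available via ``deviation="squared"`` for sensitivity
analysis. Estimates below the quantification floor (5 mg/dL) are
reported but flagged invalid: the hue of mildly icteric sclera (TSB
3–5 mg/dL) overlaps the peak region and cannot be quantified reliably.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

from .errors import ParameterError
from .hue_stats import MhdResult

__all__ = ["ModelParams", "JaundiceAssessment", "classify", "estimate_tsb", "assess"]

JAUNDICE = "jaundice"
NORMAL = "normal"


@dataclass(frozen=True)
class ModelParams:
    """Clinical constants of the MHD model (degrees and mg/dL)."""

    cutoff_mhd: float = 40.8    # screening cutoff (degrees)
    peak_mhd: float = 56.3      # MHD at which TSB is highest (degrees)
    intercept: float = 21.1603  # TSB at zero deviation (mg/dL)
    slope: float = 0.7371       # mg/dL per degree of deviation
    quant_floor: float = 5.0    # estimates below this are flagged invalid
    jaundice_tsb: float = 3.0   # classical definition, documentation only
    deviation: str = "abs"      # "abs" | "squared"

    def __post_init__(self):
        vals = (self.cutoff_mhd, self.peak_mhd, self.intercept, self.slope,
                self.quant_floor, self.jaundice_tsb)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError("all model parameters must be finite")
        if not self.cutoff_mhd < self.peak_mhd:
            raise ParameterError("cutoff_mhd must be below peak_mhd")
        if self.slope <= 0:
            raise ParameterError("slope must be positive")
        if self.deviation not in ("abs", "squared"):
            raise ParameterError(f"deviation must be 'abs' or 'squared', got {self.deviation!r}")


@dataclass(frozen=True)
class JaundiceAssessment:
    """Clinical outputs for one subject."""

    pooled_mhd: float
    label: str  # jaundice | normal
    tsb_estimate: float  # mg/dL, always reported
    estimate_valid: bool
    params_used: ModelParams

    def to_dict(self) -> dict:
        d = {
            "pooled_mhd": self.pooled_mhd,
            "label": self.label,
            "tsb_estimate": self.tsb_estimate,
            "estimate_valid": self.estimate_valid,
            "params": asdict(self.params_used),
        }
        return d


def _check_finite(mhd: float) -> float:
    mhd = float(mhd)
    if not math.isfinite(mhd):
        raise ParameterError(f"MHD must be finite, got {mhd}")
    return mhd


def classify(mhd: float, params: ModelParams | None = None) -> str:
    """Binary screening decision: jaundice iff MHD >= cutoff (inclusive)."""
    params = params or ModelParams()
    return JAUNDICE if _check_finite(mhd) >= params.cutoff_mhd else NORMAL


def estimate_tsb(mhd: float, params: ModelParams | None = None) -> tuple:
    """TSB estimate in mg/dL plus a validity flag.

    The estimate is ``intercept − slope · dev`` where ``dev`` is the
    absolute (default) or squared deviation of MHD from the peak. It is
    valid only when it reaches the quantification floor AND the subject
    screens positive; invalid estimates are still returned, flagged.
    """
    params = params or ModelParams()
    mhd = _check_finite(mhd)
    dev = abs(params.peak_mhd - mhd)
    if params.deviation == "squared":
        dev = dev * dev
    tsb = params.intercept - params.slope * dev
    valid = tsb >= params.quant_floor and mhd >= params.cutoff_mhd
    return tsb, valid


def assess(mhd_result: MhdResult, params: ModelParams | None = None) -> JaundiceAssessment:
    """Full per-subject assessment from pooled MHD (deterministic)."""
    params = params or ModelParams()
    pooled = _check_finite(mhd_result.pooled_mhd)
    tsb, valid = estimate_tsb(pooled, params)
    return JaundiceAssessment(
        pooled_mhd=pooled,
        label=classify(pooled, params),
        tsb_estimate=tsb,
        estimate_valid=valid,
        params_used=params,
    )
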