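"""Hue histograms and the maximum-hue-degree (MHD) statistic.

For each eye region, masked chromatic pixels are counted per hue-degree
bin; the MHD is the centre of the most populated bin — the modal hue of
the measured sclera/peri-ocular pixels. A subject contributes up to two
eyes in up to two gaze patterns; the per-subject MHD is pooled as the
maximum over those regions (the most yellow-shifted reading wins, which
is the conservative choice for a screening statistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .colorimetry import HslImage
from .errors import DegenerateRoiError, ParameterError
from .segmentation import EyeRoi

__all__ = ["HueHistogram", "RoiMhd", "MhdResult", "hue_histogram", "extract_mhd", "pool_mhd"]


@dataclass(frozen=True)
class HueHistogram:
    """Pixel counts per hue bin over [0, 360); bins are half-open."""

    bin_width: float
    counts: np.ndarray  # int64, length ceil(360 / bin_width)
    n_pixels: int

    @property
    def bin_edges(self) -> np.ndarray:
        n = len(self.counts)
        return np.minimum(np.arange(n + 1) * self.bin_width, 360.0)

    def to_frame(self):
        """Histogram as a DataFrame with bin_start, bin_end, count columns."""
        import pandas as pd

        edges = self.bin_edges
        return pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": self.counts}
        )


class RoiMhd(NamedTuple):
    image_id: str
    side: str
    mhd: float
    n_pixels: int


@dataclass(frozen=True)
class MhdResult:
    """Per-ROI MHDs for one subject plus their max-pooled value."""

    per_roi: tuple  # of RoiMhd
    pooled_mhd: float


def hue_histogram(hsl: HslImage, roi: EyeRoi, bin_width: float = 1.0) -> HueHistogram:
    """Count masked chromatic pixels per hue bin.

    Bins are ``[k*w, (k+1)*w)``; the final bin is clipped at 360. Counts
    always sum to the number of masked chromatic pixels.
    """
    if not (0 < bin_width <= 360):
        raise ParameterError(f"bin_width must be in (0, 360], got {bin_width}")
    r0, c0, r1, c1 = roi.bbox
    sel = roi.mask & hsl.chromatic_mask[r0:r1, c0:c1]
    hues = hsl.hue[r0:r1, c0:c1][sel]
    if hues.size == 0:
        raise DegenerateRoiError(f"ROI {roi.side} at {roi.bbox}: no chromatic pixels to count")
    n_bins = math.ceil(360.0 / bin_width)
    idx = np.minimum((hues // bin_width).astype(np.intp), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    return HueHistogram(bin_width=float(bin_width), counts=counts, n_pixels=int(hues.size))


def extract_mhd(hist: HueHistogram) -> float:
    """Hue at the histogram peak: the centre of the largest bin.

    Ties break toward the smallest hue (``argmax`` takes the first
    maximum), a documented deterministic convention.
    """
    if hist.n_pixels <= 0 or hist.counts.sum() == 0:
        raise DegenerateRoiError("cannot extract MHD from an empty histogram")
    i = int(np.argmax(hist.counts))
    return (i + 0.5) * hist.bin_width


def pool_mhd(results) -> MhdResult:
    """Pool per-ROI MHDs (up to 2 images × 2 eyes) by maximum."""
    per_roi = tuple(RoiMhd(*r) for r in results)
    if not per_roi:
        raise ParameterError("pool_mhd needs at least one per-ROI result")
    return MhdResult(per_roi=per_roi, pooled_mhd=max(r.mhd for r in per_roi))


def plot_histogram(hist: HueHistogram, ax=None, mark_mhd: bool = True):
    """Render the hue histogram (hue degree vs pixel count)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    edges = hist.bin_edges
    ax.bar(edges[:-1], hist.counts, width=np.diff(edges), align="edge", color="#caa93a")
    if mark_mhd and hist.counts.sum() > 0:
        mhd = extract_mhd(hist)
        ax.annotate(
            f"MHD = {mhd:.1f}°",
            xy=(mhd, hist.counts.max()),
            xytext=(mhd + 20, hist.counts.max()),
            arrowprops={"arrowstyle": "->"},
        )
    ax.set_xlabel("hue (degrees)")
    ax.set_ylabel("pixels")
    return ax
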