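"""Eye-region extraction.

The hue statistic is measured over bilateral eye regions ("including the
surrounding small part of the skin"), so this module produces, per eye,
a bounding box plus a boolean mask of the pixels actually measured.

Detection is a classical heuristic that needs no trained weights: the
sclera reads as a bright, weakly saturated elliptical blob against
darker, more saturated skin. Candidate pixels are thresholded in HSL,
border-touching background is discarded, connected components are
filtered by size and shape, and the best one or two are kept (ordered
left to right). The box is then padded by a configurable margin to take
in the surrounding skin. A manual-ROI path exists for photographs the
heuristic cannot handle.

``refine_mask`` applies the within-ROI exclusions: achromatic pixels
(hue undefined), near-achromatic pixels, specular highlights and deep
shadow are all removed before any hue is counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border

from .colorimetry import HslImage, RgbImage, _validate_rgb, rgb_to_hsl
from .errors import DegenerateRoiError, ParameterError

__all__ = ["EyeRoi", "SegmentationParams", "MaskParams", "detect_eyes", "manual_roi", "refine_mask"]


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for the heuristic sclera detector.

    Both thresholds are relative to image-wide medians so they survive
    the overall exposure shifts that illuminant compensation
    deliberately preserves: candidate pixels must be lighter than the
    median lightness by ``l_offset`` and have encoded chroma (max−min,
    which unlike HSL saturation does not blow up at high lightness)
    below ``c_rel`` times the median chroma — sclera is roughly half as
    chromatic as the surrounding skin at any exposure.
    """

    l_offset: float = 0.04      # required lightness margin over the image median
    c_rel: float = 0.75         # max chroma as a fraction of the image median chroma
    min_area: int = 80          # px; smaller blobs are specks
    max_area_frac: float = 0.10  # fraction of the image a single eye may cover
    min_extent: float = 0.35    # blob area / bbox area (ellipse ≈ 0.785)
    aspect_range: tuple = (0.5, 4.0)  # bbox width / height
    margin: float = 0.15        # bbox padding fraction per side ("surrounding skin")


@dataclass(frozen=True)
class MaskParams:
    """Within-ROI pixel exclusions applied before hue counting."""

    s_min: float = 0.05   # drop near-achromatic pixels
    l_min: float = 0.10   # drop deep shadow (iris/pupil, eyelashes)
    l_max: float = 0.95   # drop specular highlights
    min_pixels: int = 200  # fewer surviving pixels -> degenerate ROI


@dataclass(frozen=True)
class EyeRoi:
    """One eye region: 0-based half-open bbox plus a pixel mask over it."""

    bbox: tuple  # (row_start, col_start, row_end, col_end)
    mask: np.ndarray = field(repr=False)  # bool, shape (row_end-row_start, col_end-col_start)
    side: str = "unknown"  # left | right | unknown
    source: str = "auto"   # auto | manual

    def __post_init__(self):
        r0, c0, r1, c1 = self.bbox
        if r1 <= r0 or c1 <= c0:
            raise ParameterError(f"inverted or empty bbox {self.bbox}")
        if self.mask.shape != (r1 - r0, c1 - c0):
            raise ParameterError(
                f"mask shape {self.mask.shape} does not match bbox {self.bbox}"
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _expand_bbox(bbox, shape, margin):
    r0, c0, r1, c1 = bbox
    mr = int(round(margin * (r1 - r0)))
    mc = int(round(margin * (c1 - c0)))
    return (
        max(0, r0 - mr),
        max(0, c0 - mc),
        min(shape[0], r1 + mr),
        min(shape[1], c1 + mc),
    )


def detect_eyes(img: RgbImage, params: SegmentationParams | None = None) -> list:
    """Locate up to two eye regions on an (illuminant-compensated) image.

    Returns 0–2 :class:`EyeRoi`, ordered left-to-right by column. An empty
    list is a valid result; the caller decides whether to fall back to a
    manual ROI or fail.
    """
    arr = _validate_rgb(img)
    p = params or SegmentationParams()
    hsl = rgb_to_hsl(arr)
    u = arr / 255.0
    chroma = u.max(axis=-1) - u.min(axis=-1)
    l_thr = np.median(hsl.lightness) + p.l_offset
    cand = (hsl.lightness >= l_thr) & (chroma <= p.c_rel * np.median(chroma))
    cand = clear_border(cand)  # anything touching the frame is background
    lbl = label(cand)
    h, w = arr.shape[:2]
    max_area = p.max_area_frac * h * w
    keep = []
    for prop in regionprops(lbl):
        if not (p.min_area <= prop.area <= max_area):
            continue
        r0, c0, r1, c1 = prop.bbox
        bh, bw = r1 - r0, c1 - c0
        aspect = bw / bh
        if not (p.aspect_range[0] <= aspect <= p.aspect_range[1]):
            continue
        if prop.extent < p.min_extent:
            continue
        keep.append(prop)
    keep.sort(key=lambda pr: pr.area, reverse=True)
    keep = sorted(keep[:2], key=lambda pr: pr.centroid[1])
    rois = []
    sides = ["left", "right"] if len(keep) == 2 else ["unknown"]
    for prop, side in zip(keep, sides):
        bbox = _expand_bbox(prop.bbox, (h, w), p.margin)
        mask = np.ones((bbox[2] - bbox[0], bbox[3] - bbox[1]), dtype=bool)
        rois.append(EyeRoi(bbox=bbox, mask=mask, side=side, source="auto"))
    return rois


def manual_roi(img: RgbImage, bbox, side: str = "unknown") -> EyeRoi:
    """Build an all-inclusive ROI from user-supplied bbox coordinates.

    ``bbox`` is (row_start, col_start, row_end, col_end), 0-based and
    half-open; it must lie within the image and be non-inverted.
    """
    arr = _validate_rgb(img)
    r0, c0, r1, c1 = (int(v) for v in bbox)
    h, w = arr.shape[:2]
    if r1 <= r0 or c1 <= c0:
        raise ParameterError(f"inverted or empty bbox {bbox}")
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ParameterError(f"bbox {bbox} outside image bounds {(h, w)}")
    mask = np.ones((r1 - r0, c1 - c0), dtype=bool)
    return EyeRoi(bbox=(r0, c0, r1, c1), mask=mask, side=side, source="manual")


def refine_mask(roi: EyeRoi, hsl: HslImage, params: MaskParams | None = None) -> EyeRoi:
    """Restrict an ROI mask to measurable chromatic pixels.

    Keeps pixels that are chromatic, with saturation >= ``s_min`` and
    lightness within ``[l_min, l_max]``; never adds pixels. Raises
    :class:`DegenerateRoiError` if fewer than ``min_pixels`` survive.
    """
    p = params or MaskParams()
    r0, c0, r1, c1 = roi.bbox
    if r1 > hsl.shape[0] or c1 > hsl.shape[1]:
        raise ParameterError(f"ROI bbox {roi.bbox} outside HSL image {hsl.shape}")
    sat = hsl.saturation[r0:r1, c0:c1]
    lig = hsl.lightness[r0:r1, c0:c1]
    chrom = hsl.chromatic_mask[r0:r1, c0:c1]
    mask = roi.mask & chrom & (sat >= p.s_min) & (lig >= p.l_min) & (lig <= p.l_max)
    n = int(mask.sum())
    if n < p.min_pixels:
        raise DegenerateRoiError(
            f"ROI {roi.side} at {roi.bbox}: only {n} measurable pixels "
            f"survive masking (minimum {p.min_pixels})"
        )
    return replace(roi, mask=mask)
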