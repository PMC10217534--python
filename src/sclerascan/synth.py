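"""Synthetic eye-scene generation with known ground truth.

No public image set exists for trans-conjunctival jaundice, so the test
bed is synthetic: each scene is a small face-like canvas with one or two
eyes (a bright scleral ellipse with an iris/pupil disc, optional
eyelash and specular occluders) on textured skin, framed by a neutral
background band. The generator controls, per scene:

* the true bilirubin level and hence the true scleral hue, through a
  monotone saturating bilirubin→hue map;
* the capture illuminant, as von Kries per-channel gains applied in
  linear RGB (a color cast the pipeline must undo);
* additive Gaussian sensor noise in sRGB counts.

Two deliberate constructions make the scenes honest test beds for the
measurement chain rather than photorealistic renderings:

* the scleral patch is rendered at a *single* 8-bit RGB triple chosen so
  its exact HSL hue matches the requested true hue as closely as 8-bit
  quantization allows — so "recovering the true hue" is well defined;
* the background band is solved per channel so the scene's linear-RGB
  Minkowski means are equal before the cast — i.e. the scenes satisfy
  the achromatic-mean assumption the gray-world / shades-of-gray
  estimators rely on. Real close-up face photographs violate that
  assumption; see the methods note for what this does and does not test.

Skin hue is given smooth spatial texture (a low-pass random field plus a
horizontal gradient) so that skin, which outnumbers sclera inside a
padded eye box, spreads over many hue bins instead of forming a
competing histogram mode — emulating the natural mottling of real skin.

All randomness flows through the single per-scene (or per-cohort) seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import disk, ellipse, line

from .colorimetry import (
    hsl_to_rgb,
    linear_to_srgb,
    rgb_to_hsl,
    srgb_to_linear,
)
from .errors import InfeasibleSceneError, ParameterError

__all__ = [
    "HueMapParams",
    "RenderParams",
    "Occluder",
    "SceneSpec",
    "SceneTruth",
    "hue_map",
    "calibrated_cutoff",
    "make_scene_spec",
    "default_occluders",
    "render_scene",
    "generate_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# bilirubin -> hue map


@dataclass(frozen=True)
class HueMapParams:
    """Saturating bilirubin→scleral-hue map h(t) = h0 + (hmax−h0)·t/(t+k).

    Anchors: h0 = 37° (non-icteric scleral hue), saturating toward 57°
    (near the hue at which observed bilirubin peaks), half-saturation at
    k = 4 mg/dL.
    """

    h0: float = 37.0
    hmax: float = 57.0
    k: float = 4.0


def hue_map(tsb: float, params: HueMapParams | None = None) -> float:
    """True scleral hue (degrees) for a bilirubin level (mg/dL)."""
    p = params or HueMapParams()
    tsb = float(tsb)
    if not np.isfinite(tsb) or tsb < 0:
        raise ParameterError(f"tsb must be finite and >= 0, got {tsb}")
    return p.h0 + (p.hmax - p.h0) * tsb / (tsb + p.k)


def calibrated_cutoff(jaundice_tsb: float = 3.0, params: HueMapParams | None = None) -> float:
    """Generator-scale hue cutoff equivalent to the clinical screening cutoff.

    The clinical cutoff (40.8° on the clinical hue scale) encodes the
    jaundice decision boundary at TSB = 3 mg/dL. Synthetic scenes live on
    the generator's own bilirubin→hue scale, so scoring classification
    against ground-truth groups requires mapping that boundary through
    the generator's hue map: the equivalent cutoff is ``hue_map(3)``
    (≈ 45.57° at defaults). Classification is order-based, so this single
    anchor is the entire calibration.
    """
    return hue_map(jaundice_tsb, params)


# ---------------------------------------------------------------------------
# scene specification


@dataclass(frozen=True)
class Occluder:
    kind: str  # "eyelash" | "specular"
    eye: int   # index into eye_boxes
    center: tuple | None = None  # fractional (row, col) inside the eye box; None = random
    radius: int = 2  # px, specular only

    def __post_init__(self):
        if self.kind not in ("eyelash", "specular"):
            raise ParameterError(f"unknown occluder kind {self.kind!r}")


@dataclass(frozen=True)
class RenderParams:
    """Appearance constants of the synthetic scenes (sRGB-referred HSL)."""

    canvas_hw: tuple = (120, 160)
    border: int = 12                 # background frame width, px
    skin_hue: float = 22.0           # mean skin hue, degrees
    skin_hue_sigma: float = 8.0      # random-field amplitude, degrees
    skin_hue_gradient: float = 8.0   # total left-to-right hue drift, degrees
    skin_field_scale: float = 4.0    # correlation length of the field, px
    skin_sat: float = 0.50
    skin_lightness: float = 0.52
    sclera_sat: float = 0.30
    sclera_lightness: float = 0.60
    iris_hue: float = 25.0
    iris_sat: float = 0.50
    iris_lightness: float = 0.07     # below the mask's l_min: excluded downstream
    iris_radius_frac: float = 0.45   # of the scleral semi-minor axis
    specular_lightness: float = 0.97  # above the mask's l_max
    eyelash_lightness: float = 0.06
    n_eyelashes: int = 4
    balance_p: float = 6.0           # Minkowski order the background balances
    bg_level: float = 0.35           # linear level of the dimmest background channel


def default_occluders(n_eyes: int) -> tuple:
    occ = []
    for i in range(n_eyes):
        occ.append(Occluder("eyelash", eye=i))
        occ.append(Occluder("specular", eye=i))
    return tuple(occ)


def _default_eye_boxes(canvas_hw, n_eyes):
    h, w = canvas_hw
    eh, ew = int(0.20 * h), int(0.225 * w)
    r0 = int(0.38 * h)
    if n_eyes == 2:
        gap = int(0.20 * w)
        c_mid = w // 2
        return (
            (r0, c_mid - gap // 2 - ew, r0 + eh, c_mid - gap // 2),
            (r0, c_mid + gap // 2, r0 + eh, c_mid + gap // 2 + ew),
        )
    if n_eyes == 1:
        c0 = (w - ew) // 2
        return ((r0, c0, r0 + eh, c0 + ew),)
    raise ParameterError(f"n_eyes must be 1 or 2, got {n_eyes}")


@dataclass(frozen=True)
class SceneSpec:
    """Complete, seedable description of one synthetic capture."""

    tsb_true: float
    scleral_hue_true: float
    illuminant_gains: tuple  # linear-RGB per-channel factors
    eye_boxes: tuple         # 1-2 half-open (r0, c0, r1, c1) rectangles
    noise_sigma: float = 3.0  # sRGB counts
    occluders: tuple = ()
    gaze: str = "straight"   # straight | upturned
    seed: int = 0
    render: RenderParams = field(default_factory=RenderParams)

    def __post_init__(self):
        if self.tsb_true < 0:
            raise ParameterError("tsb_true must be >= 0")
        if self.gaze not in ("straight", "upturned"):
            raise ParameterError(f"gaze must be straight or upturned, got {self.gaze!r}")
        h, w = self.render.canvas_hw
        for i, (r0, c0, r1, c1) in enumerate(self.eye_boxes):
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ParameterError(f"eye box {i} {self.eye_boxes[i]} outside canvas {(h, w)}")
        for a, b in itertools.combinations(self.eye_boxes, 2):
            if not (a[3] <= b[1] or b[3] <= a[1] or a[2] <= b[0] or b[2] <= a[0]):
                raise ParameterError("eye boxes must be disjoint")


def make_scene_spec(
    tsb: float,
    seed: int = 0,
    gains=(1.0, 1.0, 1.0),
    gaze: str = "straight",
    n_eyes: int = 2,
    noise_sigma: float = 3.0,
    occluders="default",
    map_params: HueMapParams | None = None,
    render: RenderParams | None = None,
) -> SceneSpec:
    """Build a :class:`SceneSpec` with the true hue tied to ``tsb``.

    The invariant ``scleral_hue_true == hue_map(tsb)`` is enforced here;
    construct :class:`SceneSpec` directly only to break it on purpose.
    """
    render = render or RenderParams()
    boxes = _default_eye_boxes(render.canvas_hw, n_eyes)
    if occluders == "default":
        occluders = default_occluders(n_eyes)
    return SceneSpec(
        tsb_true=float(tsb),
        scleral_hue_true=hue_map(tsb, map_params),
        illuminant_gains=tuple(float(g) for g in gains),
        eye_boxes=boxes,
        noise_sigma=float(noise_sigma),
        occluders=tuple(occluders),
        gaze=gaze,
        seed=int(seed),
        render=render,
    )


@dataclass(frozen=True)
class SceneTruth:
    """A rendered scene plus everything needed to score the pipeline."""

    spec: SceneSpec
    image: np.ndarray = field(repr=False)         # uint8 (H, W, 3)
    sclera_masks: tuple = field(repr=False)       # per-eye bool (H, W): rendered scleral px
    subject_id: str = ""

    @property
    def eye_boxes(self) -> tuple:
        return self.spec.eye_boxes


# ---------------------------------------------------------------------------
# rendering


def _match_hue_rgb8(target_hue: float, sat: float, lightness: float) -> np.ndarray:
    """8-bit RGB triple whose exact HSL hue is as close as possible to target.

    Rounding a float HSL→RGB conversion to 8 bits can shift hue by up to
    ~1° at moderate chroma; searching small integer offsets around the
    rounded triple recovers a hue error well under half a degree while
    staying within a few counts of the requested saturation/lightness.
    """
    ideal = hsl_to_rgb(target_hue, sat, lightness)[()] * 255.0
    base = np.round(ideal).astype(int)
    best, best_score = None, np.inf
    for d in itertools.product(range(-4, 5), repeat=3):
        cand = np.clip(base + np.array(d), 0, 255).astype(np.uint8)
        h = rgb_to_hsl(cand.reshape(1, 1, 3))
        if not h.chromatic_mask[0, 0]:
            continue
        dh = abs((h.hue[0, 0] - target_hue + 180.0) % 360.0 - 180.0)
        score = dh + 0.02 * (abs(h.saturation[0, 0] - sat) + abs(h.lightness[0, 0] - lightness))
        if score < best_score:
            best, best_score = cand, score
    return best


def _smooth_field(rng, shape, scale, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), scale)
    std = f.std()
    if std > 0:
        f *= sigma / std
    return f


def render_scene(spec: SceneSpec) -> SceneTruth:
    """Rasterize a scene spec; deterministic given the spec (incl. seed).

    Composition happens in linear RGB; the illuminant cast is applied as
    per-channel linear gains; Gaussian sensor noise is added after sRGB
    encoding; the result is rounded to 8 bits.
    """
    rp = spec.render
    h, w = rp.canvas_hw
    rng = np.random.default_rng(spec.seed)

    # skin with mottled hue
    hue_field = (
        rp.skin_hue
        + _smooth_field(rng, (h, w), rp.skin_field_scale, rp.skin_hue_sigma)
        + np.linspace(-rp.skin_hue_gradient / 2, rp.skin_hue_gradient / 2, w)[None, :]
    )
    lin = srgb_to_linear(hsl_to_rgb(hue_field, rp.skin_sat, rp.skin_lightness))

    sclera_rgb8 = _match_hue_rgb8(spec.scleral_hue_true, rp.sclera_sat, rp.sclera_lightness)
    sclera_lin = srgb_to_linear(sclera_rgb8 / 255.0)
    iris_lin = srgb_to_linear(hsl_to_rgb(rp.iris_hue, rp.iris_sat, rp.iris_lightness))
    spec_lin = srgb_to_linear(hsl_to_rgb(0.0, 0.02, rp.specular_lightness))
    lash_lin = srgb_to_linear(hsl_to_rgb(0.0, 0.0, rp.eyelash_lightness))

    sclera_masks = []
    for i, (r0, c0, r1, c1) in enumerate(spec.eye_boxes):
        cy, cx = (r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0
        ry, rx = (r1 - r0) / 2.0 - 0.5, (c1 - c0) / 2.0 - 0.5
        eye = np.zeros((h, w), dtype=bool)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w))
        eye[rr, cc] = True

        iris = np.zeros((h, w), dtype=bool)
        icy = cy - (0.5 * ry if spec.gaze == "upturned" else 0.0)
        rr, cc = disk((icy, cx), rp.iris_radius_frac * ry, shape=(h, w))
        iris[rr, cc] = True
        iris &= eye

        occluded = np.zeros((h, w), dtype=bool)
        for occ in spec.occluders:
            if occ.eye != i:
                continue
            if occ.kind == "specular":
                if occ.center is None:
                    fr = rng.uniform(0.3, 0.7)
                    fc = rng.uniform(0.25, 0.75)
                else:
                    fr, fc = occ.center
                rr, cc = disk((r0 + fr * (r1 - r0), c0 + fc * (c1 - c0)), occ.radius, shape=(h, w))
                blob = np.zeros((h, w), dtype=bool)
                blob[rr, cc] = True
                occluded |= blob & eye
                lin[blob & eye] = spec_lin
            else:  # eyelash: short dark strokes hanging from the upper lid
                for j in range(rp.n_eyelashes):
                    fc = (j + 1) / (rp.n_eyelashes + 1)
                    ctop = int(c0 + fc * (c1 - c0 - 1))
                    rtop = int(np.ceil(cy - ry * np.sqrt(max(0.0, 1 - ((ctop - cx) / rx) ** 2))))
                    rr, cc = line(rtop, ctop, min(rtop + int(ry * 0.6), h - 1), min(ctop + 2, w - 1))
                    stroke = np.zeros((h, w), dtype=bool)
                    stroke[rr, cc] = True
                    occluded |= stroke & eye
                    lin[stroke & eye] = lash_lin

        sclera = eye & ~iris & ~occluded
        open_sclera = eye & ~iris
        if open_sclera.sum() == 0 or (occluded & open_sclera).sum() > 0.8 * open_sclera.sum():
            raise InfeasibleSceneError(
                f"eye {i}: occluders cover more than 80% of the sclera"
            )
        lin[sclera] = sclera_lin
        lin[iris & ~occluded] = iris_lin
        sclera_masks.append(sclera)

    # background band solved so pre-cast Minkowski-p channel means are equal
    bg = np.ones((h, w), dtype=bool)
    bg[rp.border : h - rp.border, rp.border : w - rp.border] = False
    p = rp.balance_p
    fg_sum = np.power(lin[~bg], p).sum(axis=0)
    n_bg = int(bg.sum())
    target = fg_sum.max() + n_bg * rp.bg_level**p
    lin[bg] = np.power(np.clip((target - fg_sum) / n_bg, 0.0, 0.98**p), 1.0 / p)

    lin = lin * np.asarray(spec.illuminant_gains, dtype=float)
    enc = linear_to_srgb(np.clip(lin, 0.0, 1.0)) * 255.0
    if spec.noise_sigma > 0:
        enc = enc + rng.normal(0.0, spec.noise_sigma, enc.shape)
    img = np.clip(np.round(enc), 0, 255).astype(np.uint8)
    return SceneTruth(spec=spec, image=img, sclera_masks=tuple(sclera_masks))


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSampler:
    """Two-group bilirubin sampler: truncated normals with resampling.

    Defaults mirror a mixed hepatobiliary cohort: controls 0.77 ± 0.35
    mg/dL confined to [0, 3), jaundiced subjects 9.57 ± 7.11 mg/dL
    confined to [3, ∞), with a jaundice prevalence of 26/51.
    """

    control_mean: float = 0.77
    control_sd: float = 0.35
    jaundice_mean: float = 9.57
    jaundice_sd: float = 7.11
    jaundice_frac: float = 26 / 51
    boundary_tsb: float = 3.0

    def draw(self, rng) -> tuple:
        is_jaundice = bool(rng.random() < self.jaundice_frac)
        if is_jaundice:
            lo, hi = self.boundary_tsb, np.inf
            mu, sd = self.jaundice_mean, self.jaundice_sd
        else:
            lo, hi = 0.0, self.boundary_tsb
            mu, sd = self.control_mean, self.control_sd
        while True:  # resample until group-consistent
            t = rng.normal(mu, sd)
            if lo <= t < hi:
                return t, ("jaundice" if is_jaundice else "control")


def generate_cohort(
    n_subjects: int,
    seed: int = 0,
    sampler: CohortSampler | None = None,
    gain_range: tuple = (0.7, 1.4),
    noise_sigma: float = 3.0,
    map_params: HueMapParams | None = None,
    render: RenderParams | None = None,
):
    """Render a cohort: per subject, two gaze patterns with bilateral eyes.

    Each image gets its own illuminant (per-channel gains uniform in
    ``gain_range``). Returns ``(scenes, cohort)`` where ``cohort`` is a
    DataFrame with subject_id, tsb_true and group columns.
    """
    import pandas as pd

    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    sampler = sampler or CohortSampler()
    rng = np.random.default_rng(seed)
    scenes, rows = [], []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        tsb, group = sampler.draw(rng)
        for gaze in ("straight", "upturned"):
            gains = rng.uniform(gain_range[0], gain_range[1], size=3)
            sseed = int(rng.integers(0, 2**31 - 1))
            sp = make_scene_spec(
                tsb,
                seed=sseed,
                gains=gains,
                gaze=gaze,
                noise_sigma=noise_sigma,
                map_params=map_params,
                render=render,
            )
            truth = render_scene(sp)
            scenes.append(
                SceneTruth(
                    spec=truth.spec,
                    image=truth.image,
                    sclera_masks=truth.sclera_masks,
                    subject_id=sid,
                )
            )
        rows.append({"subject_id": sid, "tsb_true": tsb, "group": group})
    return scenes, pd.DataFrame(rows)


def write_cohort(scenes, cohort, outdir) -> None:
    """Persist a rendered cohort: PNG images + masks, truth manifests, CSV."""
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    for sc in scenes:
        stem = f"{sc.subject_id}_{sc.spec.gaze}"
        Image.fromarray(sc.image).save(outdir / "images" / f"{stem}.png")
        for i, m in enumerate(sc.sclera_masks):
            Image.fromarray((m * 255).astype(np.uint8)).save(
                outdir / "masks" / f"{stem}_eye{i}.png"
            )
        manifest = {
            "subject_id": sc.subject_id,
            "gaze": sc.spec.gaze,
            "tsb_true": sc.spec.tsb_true,
            "scleral_hue_true": sc.spec.scleral_hue_true,
            "illuminant_gains": list(sc.spec.illuminant_gains),
            "eye_boxes": [list(b) for b in sc.spec.eye_boxes],
            "noise_sigma": sc.spec.noise_sigma,
            "seed": sc.spec.seed,
            "image": f"images/{stem}.png",
        }
        (outdir / "truth" / f"{stem}.json").write_text(json.dumps(manifest, indent=1))
    cohort.to_csv(outdir / "cohort.csv", index=False)
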