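# Methods

This note documents the measurement model behind `sclerascan`, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not demonstrate.

## Measurement model

The quantity of interest is the color of the sclera/bulbar conjunctiva,
which yellows progressively with circulating bilirubin. The pipeline
treats a casual photograph as a biased color measurement and removes the
two dominant nuisances — the ambient illuminant and luminance — before
reducing the eye region to a single angle:

1. **Illuminant.** Illumination change is modelled as a von Kries
   diagonal transform: independent per-channel scaling in *linear* RGB.
   The scene illuminant is estimated from the image itself under the
   achromatic-mean assumption — the per-channel Minkowski-*p* means of
   linear RGB are equal for a neutral scene. *p* = 1 is gray-world;
   the default *p* = 6 (shades-of-gray) weights highlights more and is
   usually a better compromise on real scenes. Estimated gains are
   normalized to geometric mean 1: the *color* of the illuminant is
   corrected while overall exposure is deliberately preserved, because
   absolute intensity is not estimable from a single image and the
   downstream statistic does not use it. The commercial compensation
   algorithm used in the original clinical deployment is proprietary
   and undescribed; these estimators are documented stand-ins with the
   same goal, and no equivalence with that system is claimed or tested.
2. **Luminance.** No explicit luminance normalization is performed.
   Converting to bi-conical HSL separates lightness from hue, and only
   hue is consumed downstream, so the statistic is luminance-free by
   construction.
3. **Hue.** Standard double-hexcone HSL: L = (max+min)/2,
   S = (max−min)/(1−|2L−1|) for chromatic pixels, hue the hexagonal
   angle in degrees, red at 0°, yellow at 60°, no smoothing across the
   0/360 seam (scleral hues of interest lie in ~0–120°). Hue is
   undefined where max = min; those pixels carry a False entry in an
   explicit chromatic mask and are never counted.
4. **Eye regions.** The hue histogram is computed over bilateral eye
   regions including a small margin of surrounding skin (15% of the eye
   box per side by default). Within a region, pixels are masked to the
   measurable set: chromatic, saturation ≥ 0.05, lightness in
   [0.10, 0.95] — excluding specular highlights, deep shadow
   (iris/pupil, lashes) and achromatic pixels. A region retaining fewer
   than 200 pixels is degenerate and is dropped with an error naming it.
5. **MHD.** Masked pixels are counted per 1° hue bin ([k, k+1),
   half-open). The maximum hue degree is the *centre* of the most
   populated bin (unbiased under within-bin uniformity); ties break
   toward the smallest hue, a deterministic convention that is
   measure-zero on real data. Per subject, MHDs from up to two eyes in
   up to two gaze patterns are pooled by **maximum** — the most
   yellow-shifted reading wins, the conservative choice for screening.
   An alternative reading of "maximum hue degree" — the largest hue
   *present* rather than the modal hue — is rejected here: the largest
   present hue is an extreme statistic of the noise tail, while the
   histogram peak is stable and matches the statistic's use as a
   per-region summary.
6. **Clinical model.** Screening: jaundice iff MHD ≥ 40.8°, boundary
   inclusive (screening favours sensitivity). Quantification:
   TSB = 21.1603 − 0.7371·dev mg/dL with dev = |56.3 − MHD| by default.
   The printed source expression for the deviation is typographically
   mangled; absolute deviation is adopted because the quantity is
   described as a deviation correlating *linearly* and negatively with
   TSB, and a literally squared deviation with this slope would drive
   estimates negative within ±6° of the peak. The squared reading is
   preserved behind `model.deviation = squared`. The same symmetric
   formula applies above the peak. Estimates are flagged invalid below
   the 5 mg/dL quantification floor or when the subject screens
   negative; they are reported regardless, never suppressed.

## Eye detection

The detector is a classical heuristic chosen to stay dependency-light
and fully testable: no trained weights, no network. Candidate pixels
must be (a) lighter than the image's median lightness by 0.04 and
(b) of encoded chroma (max−min) below 0.75× the image's median chroma.
Both thresholds are *relative to image medians* because compensation
preserves overall exposure: absolute thresholds break under bright or
dim illuminants, while the sclera stays roughly half as chromatic and
~0.08 lighter (in L) than the surrounding skin at any exposure. Chroma
is used instead of HSL saturation because saturation's denominator
vanishes at high lightness and inflates arbitrarily. Components touching
the image border are discarded as background; the rest are filtered by
area (≥ 80 px, ≤ 10% of the image), bbox aspect (0.5–4.0) and extent
(≥ 0.35, a filled ellipse scores ≈ 0.785); the largest one or two
survive, ordered left to right. A manual-ROI path (`--roi`) bypasses
detection entirely. Real-photo robustness is explicitly secondary to
testability; the detector is a pluggable stage and a cascade-based
backend can replace it without touching the rest of the chain.

Coordinates are 0-based, half-open, row-major throughout — fixed so
mask tests can be bit-exact.

## Synthetic scenes

The generator emulates the capture conditions the pipeline is meant for:
two gaze patterns per subject, bilateral eyes, a multiplicative
illuminant cast in linear RGB, and additive Gaussian sensor noise in
sRGB counts (default σ = 3, a deliberate simplification of real camera
noise). Ground truth — true TSB, true scleral hue, gains, eye boxes,
per-eye scleral masks — is emitted alongside every scene.

**Bilirubin → hue map.** No physical model links TSB to scleral hue;
the generator uses a monotone saturating map
h(t) = 37 + 20·t/(t+4) degrees, anchored so that a non-icteric sclera
sits near 37° and severe jaundice saturates toward 57°, near the hue at
which observed TSB peaks; half-saturation at 4 mg/dL. It is a modeling
choice, fully configurable, not a claim about physiology.

**Scale calibration.** The clinical cutoff (40.8°) and quantification
formula live on the *clinical* hue scale; synthetic scenes live on the
generator's scale. The two agree in ordering but not in absolute value,
so classification on synthetic cohorts is scored at the calibrated
cutoff `hue_map(3 mg/dL) ≈ 45.57°` — the image of the TSB = 3 mg/dL
decision boundary that the clinical cutoff encodes
(`sclerascan.calibrated_cutoff()`). Classification is order-based, so
this single anchor is the entire calibration. Absolute TSB estimates on
synthetic scenes are indicative only.

**Design requirements discovered while building the generator:**

- *Sclera rendering.* The scleral patch is a single 8-bit RGB triple
  selected by local search so its exact HSL hue matches the requested
  truth as closely as 8-bit quantization allows (< 0.4° over the
  relevant range) — "recovering the true hue" must be well defined for
  recovery tests to mean anything. Scleral saturation defaults to 0.3
  (so the chromatic mask retains scleral pixels) and lightness to 0.60.
  The lightness value matters more than it looks: it sets scleral
  chroma ≈ 61 counts, making the 8-bit hue lattice (~1° spacing) finer
  than the 1° histogram bins. A lighter sclera (e.g. L = 0.72, chroma
  ≈ 43 counts) quantizes hue onto a ~1.4° comb that aliases against the
  bins and makes the histogram peak wobble by ±2 bins under noise.
- *Gray-world validity.* The background band is solved per channel so
  that the scene's linear-RGB Minkowski-6 means are equal before the
  cast. The estimators assume exactly this; a close-up face that fills
  the frame with skin violates it, and on such photographs the
  compensation inherits a skin-colored bias. The synthetic scenes
  therefore test the *mechanics* of compensation (cast in, cast out),
  not the validity of the achromatic-mean assumption on real faces.
- *Skin texture.* Skin hue gets a smooth random field (σ = 8°,
  correlation ~4 px) plus a horizontal gradient, emulating natural
  mottling. Uniform skin would concentrate the (more numerous) skin
  pixels of the ROI margin into a few hue bins and could outvote the
  sclera's mode.
- Iris/pupil (L = 0.07) and eyelashes (L = 0.06) fall below the mask's
  shadow floor, and specular blobs (L = 0.97) above its highlight
  ceiling, so the measurable set is the open sclera — mirroring how the
  mask is meant to behave on real eyes.

The cohort sampler draws the jaundice group (prevalence 26/51) from
N(9.57, 7.11²) mg/dL truncated to [3, ∞) and controls from
N(0.77, 0.35²) truncated to [0, 3), with resampling at the boundary so
group labels are consistent by construction. All randomness flows from
the single seed passed to `generate_cohort`/`render_scene`; there is no
hidden global state, and identical specs render byte-identical scenes.

What passing these tests shows: the chain recovers a known scleral hue
through casts, noise, occluders and its own segmentation, and the
cohort statistics are implemented correctly. What it does not show:
performance on real conjunctivae (spectral reflectance, vasculature,
gaze-dependent exposure), real camera processing (auto white balance,
demosaicing, JPEG), or faces that violate the achromatic-mean
assumption.

## Evaluation statistics

Empirical ROC over all distinct score thresholds with the inclusive
rule MHD ≥ t; AUROC as the trapezoidal area, which with one point per
distinct score equals the tie-corrected Mann–Whitney concordance
(ties count ½) — the suite pins both identities against exhaustive
pair counting. The operating cutoff maximizes Youden's
J = sens + spec − 1 (standard when a single sensitivity/specificity
pair is reported; a closest-to-corner criterion is available), ties
toward the smallest threshold. Spearman is the Pearson correlation of
mid-ranks, undefined (an error, not NaN) for constant input. Group
descriptives such as Welch's t or normality tests are out of scope —
they describe cohorts, not the instrument.

## Numerical and interface choices

- 8-bit sRGB in and out; IEC 61966-2-1 transfer functions; compensation
  clips to gamut before re-encoding; 16-bit input is rescaled with a
  warning.
- Median filter (3×3 default, kernel 1 = identity) as the noise
  reduction step: it removes salt/speckle and lash fragments without
  shifting the hue of smooth regions the way linear blurs do.
- Reports contain no timestamps and embed the effective configuration
  and package version, so identical inputs give byte-identical reports.
- Exit codes: 0 success, 2 input error, 3 degenerate segmentation,
  4 configuration error; logging to stderr only.

## Problem sizes in the test suite

Scenes are 120×160 px — large enough for ~500 measurable scleral pixels
per eye (well above the 200-pixel degeneracy floor) and small enough
that the full suite, including a 60-subject end-to-end cohort
(240 eyes) and 100 paired cast/no-cast trials, runs in well under a
minute. These sizes are the package's chosen defaults, not limits:
every geometric parameter scales through `RenderParams`.

## Known limitations

- The heuristic detector targets the synthetic scene family and frontal,
  unoccluded eyes; real photographs will often need the manual-ROI path
  or a trained detector backend.
- The 40.8°/56.3° constants and the quantification formula come from a
  single small clinical cohort; the package deliberately ships them as
  fixed defaults and provides the evaluation machinery to re-derive
  cutoffs on new cohorts rather than refitting silently.
- Quantification below 5 mg/dL is unreliable by design of the model
  (mild icterus overlaps the peak region); the validity flag encodes
  this rather than hiding the estimate.
- Single-illuminant scenes only: mixed lighting breaks the von Kries
  diagonal model and is not emulated.
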