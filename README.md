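# sclerascan

Jaundice screening and bilirubin quantification from ordinary
photographs of the eyes.

Excess circulating bilirubin (hyperbilirubinemia, total serum bilirubin
TSB ≥ 3 mg/dL) shows first as yellowing of the sclera and bulbar
conjunctiva. `sclerascan` implements a smartphone-grade,
trans-conjunctival colorimetric pipeline for clinicians and
telemedicine tooling: given one or two casual face photographs per
subject (no flash, no color chart, arbitrary ambient light), it measures
how yellow the scleral pixels are and turns that into a screening
decision and a bilirubin estimate.

## The statistic

1. **Illuminant compensation.** The capture illuminant is estimated with
   a Minkowski-norm color-constancy method (gray-world *p* = 1 or
   shades-of-gray, default *p* = 6) and divided out as a von Kries
   diagonal transform in linear RGB, so the measured color is
   approximately independent of the light source.
2. **HSL hue.** Pixels are converted to the bi-conical
   hue–saturation–lightness space; hue is an angle with red at 0° and
   yellow at 60°, so scleral yellowing is a graded shift of hue.
3. **MHD.** Bilateral eye regions (plus a small skin margin) are
   extracted, achromatic/specular/shadow pixels are masked out, and the
   remaining pixels are counted per hue degree. The **maximum hue
   degree (MHD)** is the modal hue — the centre of the most populated 1°
   bin. Per subject, MHDs from up to 2 eyes × 2 gaze patterns are pooled
   by maximum.
4. **Clinical model.** Screening: jaundice iff MHD ≥ 40.8°. Observed TSB
   peaks at MHD = 56.3°, and is estimated as

   TSB ≈ 21.1603 − 0.7371 · |56.3 − MHD|  (mg/dL),

   reported but flagged invalid below 5 mg/dL, where scleral hue is not
   quantitatively informative.

No clinical image set is distributed; the package ships a first-class
synthetic scene generator (`sclerascan.synth`) with full ground truth —
true bilirubin, true scleral hue, illuminant gains, eye boxes, masks —
against which every stage and the end-to-end pipeline are tested.

## Worked example

```sh
python examples/assess_subject.py
```

renders two captures of a synthetic subject with TSB 12 mg/dL under two
different color casts and runs the full chain:

```
straight: estimated illuminant gains [0.824784, 0.985121, 1.230751]
   left eye: MHD 50.5 deg over 1158 px
  right eye: MHD 52.5 deg over 1144 px
upturned: estimated illuminant gains [1.184251, 0.960722, 0.878939]
   left eye: MHD 53.5 deg over 1136 px
  right eye: MHD 53.5 deg over 1150 px
pooled MHD          : 53.5 deg (true scleral hue 52.0 deg)
screening label     : jaundice
TSB estimate        : 19.10 mg/dL (true 12.0 mg/dL, valid=True)
```

The estimated gains invert each image's cast; the four per-eye MHDs
agree with the true scleral hue to within ~1.5°; the pooled (maximum)
MHD clears the screening cutoff. Other examples:
`examples/illumination_compensation.py` (a warm cast shifts scleral hue
by −12°, compensation restores it to within 0.2°) and
`examples/cohort_screening.py` (30-subject cohort: AUROC 1.000,
Spearman rS = 0.986).

The same chain is available from a shell:

```sh
sclerascan synth --n 10 --seed 42 --outdir fixtures/
sclerascan assess -i fixtures/images/S000_straight.png \
                  -i fixtures/images/S000_upturned.png --out report.json
sclerascan eval --cohort cohort.csv --out summary.json
```

(`assess` accepts repeated `--roi row0,col0,row1,col1` for manual eye
boxes and `--config cfg.yaml` to override any pipeline parameter; exit
codes: 2 input error, 3 degenerate segmentation, 4 config error.)

## Layout

- `src/sclerascan/colorimetry.py` — decoding, sRGB↔linear, illuminant
  estimation/compensation, median denoise, RGB↔HSL
- `src/sclerascan/segmentation.py` — heuristic bilateral eye detection,
  manual ROIs, measurable-pixel masking
- `src/sclerascan/hue_stats.py` — hue histograms, MHD, max-pooling
- `src/sclerascan/model.py` — screening cutoff and TSB quantification
- `src/sclerascan/synth.py` — ground-truth synthetic scene/cohort generator
- `src/sclerascan/evaluation.py` — ROC/AUROC, Youden cutoff, Spearman
- `src/sclerascan/pipeline.py`, `cli.py`, `config.py` — orchestration,
  thin CLI, YAML configuration

See `docs/methods.md` for the model assumptions, parameter defaults,
what the synthetic scenes do and do not emulate, and known limitations.
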