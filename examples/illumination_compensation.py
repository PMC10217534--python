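"""Show why illuminant compensation matters for hue measurement.

Renders the same eye scene twice — once under a neutral illuminant and
once under a strong warm cast — and measures the median scleral hue
before and after the von Kries correction (shades-of-gray estimator,
Minkowski p = 6). The cast shifts the raw hue by several degrees; the
compensated hue returns to within ~2 degrees of the cast-free value,
which is what makes the MHD statistic usable across lighting conditions.
"""

import numpy as np

import sclerascan as ss
from sclerascan.synth import make_scene_spec, render_scene

CAST = (1.4, 1.0, 0.7)  # warm tungsten-like illuminant

neutral = render_scene(make_scene_spec(8.0, seed=6, noise_sigma=0.0, occluders=()))
cast = render_scene(make_scene_spec(8.0, seed=6, gains=CAST, noise_sigma=0.0, occluders=()))
true_hue = neutral.spec.scleral_hue_true
mask = cast.sclera_masks[0]

raw_hue = np.median(ss.rgb_to_hsl(cast.image).hue[mask])
gains = ss.estimate_illuminant(cast.image)
compensated = ss.compensate_illumination(cast.image, gains)
comp_hue = np.median(ss.rgb_to_hsl(compensated).hue[mask])

print(f"true scleral hue            : {true_hue:.2f} deg")
print(f"hue under cast {CAST}  : {raw_hue:.2f} deg "
      f"(shifted {raw_hue - true_hue:+.2f})")
print(f"estimated gains             : {np.round(gains.gains, 3)}")
print(f"hue after compensation      : {comp_hue:.2f} deg "
      f"(residual {comp_hue - true_hue:+.2f})")
# A residual well inside the 1-degree histogram bin means the jaundice
# statistic downstream is effectively independent of the light source.
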