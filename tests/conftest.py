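import numpy as np
import pytest

from sclerascan.colorimetry import linear_to_srgb, srgb_to_linear
from sclerascan.synth import make_scene_spec, render_scene


@pytest.fixture(scope="session")
def smooth_image():
    """Smooth low-frequency sRGB test card (no hard edges)."""
    yy, xx = np.mgrid[0:80, 0:100]
    img = np.stack(
        [
            120 + 40 * np.sin(xx / 30),
            110 + 30 * np.cos(yy / 25),
            90 + 20 * np.sin((xx + yy) / 40),
        ],
        axis=-1,
    )
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def gray_ramp():
    """Achromatic random-ramp scene, linear values in [0.05, 0.45] (no clipping
    headroom issues under casts up to x2)."""
    rng = np.random.default_rng(1)
    lin = rng.uniform(0.05, 0.45, (64, 64, 1)) * np.ones((1, 1, 3))
    return np.clip(np.round(linear_to_srgb(lin) * 255), 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def scene():
    """One rendered two-eye scene (moderate jaundice, identity illuminant)."""
    return render_scene(make_scene_spec(8.0, seed=2))


@pytest.fixture(scope="session")
def scene_pair():
    """Two gaze patterns of one subject under different casts."""
    return (
        render_scene(make_scene_spec(12.0, seed=21, gains=(1.2, 1.0, 0.8), gaze="straight")),
        render_scene(make_scene_spec(12.0, seed=22, gains=(0.85, 1.05, 1.15), gaze="upturned")),
    )


def cast_in_linear(img, gains):
    """Apply a von Kries cast to an 8-bit sRGB image (test utility)."""
    lin = np.clip(srgb_to_linear(img / 255.0) * np.asarray(gains, dtype=float), 0, 1)
    return np.clip(np.round(linear_to_srgb(lin) * 255), 0, 255).astype(np.uint8)


def iou(a, b):
    """Intersection-over-union of two (r0, c0, r1, c1) boxes."""
    r0, c0 = max(a[0], b[0]), max(a[1], b[1])
    r1, c1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / union
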