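import numpy as np
import pytest

from lysotube import synthetic_scenes as ss


@pytest.fixture(scope="session")
def clean_scene() -> ss.Scene:
    """A zero-noise, well-separated scene shared by detection/morphometry tests."""
    cfg = ss.SceneConfig(
        n_round=10,
        n_tubular=8,
        n_frames=1,
        noise_sd=0.0,
        jitter_sd_um=0.0,
        contact_fraction=0.3,
        seed=42,
    )
    return ss.generate_scene(cfg)


@pytest.fixture(scope="session")
def contact_scene() -> ss.Scene:
    """Every lysosome seeded on the ER network; zero noise, no jitter."""
    cfg = ss.SceneConfig(
        n_round=10,
        n_tubular=5,
        n_frames=1,
        noise_sd=0.0,
        jitter_sd_um=0.0,
        contact_fraction=1.0,
        seed=7,
    )
    return ss.generate_scene(cfg)


def rasterize_capsule(length_um, width_um, pixel_size_nm, shape=(48, 64),
                      center=(20.0, 30.0)):
    """Binary capsule mask centred between pixel rows (axis-aligned)."""
    px = pixel_size_nm / 1000.0
    length_px, width_px = length_um / px, width_um / px
    cy, cx = center
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    x0 = cx - (length_px - width_px) / 2
    x1 = cx + (length_px - width_px) / 2
    d = np.hypot(np.clip(xx, x0, x1) - xx, yy - cy)
    return d <= width_px / 2
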