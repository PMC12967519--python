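import numpy as np
import pytest

import trichromequant as tq


@pytest.fixture(scope="session")
def basis() -> tq.StainBasis:
    return tq.StainBasis.masson_default()


@pytest.fixture(scope="session")
def small_scene():
    """One mid-fill synthetic skin scene at reduced resolution, with truth."""
    params = tq.SceneParams(width_px=480, height_px=360, collagen_fill=0.5, seed=1)
    rgb, truth = tq.generate_scene(params)
    return params, rgb, truth


@pytest.fixture(scope="session")
def blue_band_image(basis):
    """Noise-free image: uniform collagen band (conc 1.0) on white background."""
    conc = np.zeros((240, 320))
    conc[60:180, :] = 1.0
    od = conc[..., None] * basis.stain1.v
    truth_band = conc > 0
    return tq.od_to_rgb(od), truth_band
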