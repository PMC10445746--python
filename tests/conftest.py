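import numpy as np
import pytest

from pmdomains import CalibratedImage, CellMask, SceneSpec


@pytest.fixture
def small_scene_spec():
    """A reduced TIRF scene (256x256, ~9x7 µm cell) that keeps the default
    cluster density and coverage but runs fast."""
    return SceneSpec(
        image_shape=(256, 256),
        cell_axes_um=(9.0, 7.0),
    )


@pytest.fixture
def flat_cell():
    """Uniform membrane inside an elliptical cell, no noise, no clusters."""
    h = w = 128
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - 64) / 50) ** 2 + ((xx - 64) / 40) ** 2 <= 1
    pixels = np.where(mask, 200.0, 0.0)
    return CalibratedImage(pixels, 0.1), CellMask(mask, 0.1)
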