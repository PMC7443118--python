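import numpy as np
import pytest

from whatwhere.colliculus import build_projection
from whatwhere.config import ci_profile
from whatwhere.glyphs import make_glyph_dataset
from whatwhere.pipeline import run_pipeline
from whatwhere.retina import LogPolarGrid, RetinalEncoder
from whatwhere.what import MAX_SHIFT, SHIFT_MAP_SIDE, ShiftAccuracyMap


@pytest.fixture(scope="session")
def grid():
    return LogPolarGrid()


@pytest.fixture(scope="session")
def encoder(grid):
    return RetinalEncoder(grid)


@pytest.fixture(scope="session")
def projection(grid):
    return build_projection(grid)


@pytest.fixture(scope="session")
def banks():
    """Glyph train/validation banks shared across the suite."""
    return make_glyph_dataset(120, seed=0).split(0.2)


@pytest.fixture(scope="session")
def synthetic_shift_map():
    """Synthetic stand-in for a measured shift-accuracy map: unimodal,
    peaked at the center, decaying to chance (0.1) with a ~7 px plateau,
    mimicking the transfer curve of a trained foveal classifier."""
    ax = np.arange(-MAX_SHIFT, MAX_SHIFT + 1)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(rr, cc)
    values = 0.1 + 0.8 * np.exp(-0.5 * (r / 7.0) ** 2)
    return ShiftAccuracyMap(values=values, n_samples=0)


@pytest.fixture(scope="session")
def trained_system(banks):
    """One reduced-profile end-to-end training run shared by every test
    that needs trained pathways."""
    train_bank, val_bank = banks
    return run_pipeline(ci_profile(), train_bank, val_bank, seed=1)
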