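import numpy as np
import pytest

from mcsquant.synthetic import SyntheticCellParams, simulate_cell


def small_params(**overrides) -> SyntheticCellParams:
    """A small, fast synthetic cell used throughout the unit tests."""
    defaults = dict(image_shape=(128, 128), n_puncta=12, n_frames=6,
                    n_mito=6, er_nodes=260, seed=11)
    defaults.update(overrides)
    return SyntheticCellParams(**defaults)


@pytest.fixture(scope="session")
def small_cell():
    return simulate_cell(small_params())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
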