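import numpy as np
import pytest
from scipy import ndimage

from rhizoct.synthetic import SyntheticParams, simulate_core


def small_params(**kwargs) -> SyntheticParams:
    """Down-scaled core for fast unit tests: a short 1 mm-band grid."""
    defaults = dict(shape=(24, 150, 150), n_biopores=1, seed=11)
    defaults.update(kwargs)
    return SyntheticParams(**defaults)


@pytest.fixture(scope="session")
def default_core():
    """One full-size paired core shared by read-only tests."""
    return simulate_core(SyntheticParams(seed=7), core_id="core07")


@pytest.fixture(scope="session")
def small_core():
    return simulate_core(small_params(), core_id="small11")


def smooth_random_mask(seed: int, shape=(32, 32, 32), porosity: float = 0.3,
                       sigma: float = 2.0) -> np.ndarray:
    """Spatially correlated random binary mask with tunable fill fraction."""
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return noise > np.quantile(noise, 1.0 - porosity)
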