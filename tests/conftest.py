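import numpy as np
import pytest

from medipreset.preprocess import log2_ratio, median_center, quantile_normalize
from medipreset.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across tests (read-only)."""
    cfg = SimConfig(n_promoters=40, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_signal(small_study):
    """Quantile-normalized signal for the small study."""
    return quantile_normalize(median_center(log2_ratio(small_study.intensities)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
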