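import numpy as np
import pytest

from paleodendro import synthetic_data as sd
from paleodendro.dendro_io import RingWidthSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_forest():
    """A quick 4-tree forest with the reference signal, aligned axes."""
    cfg = sd.reference_forest_config(
        seed=11, n_trees=4, years=80, offsets=[0, 0, 0, 0],
        marker_years={k: v for k, v in sd.REFERENCE_MARKERS.items() if k < 80},
    )
    return sd.simulate_forest(cfg)


@pytest.fixture
def lognormal_series(rng):
    """One plausible ring-width series (positive, skewed, red-ish)."""
    x = np.zeros(120)
    eps = rng.normal(0, 0.3, 120)
    for t in range(1, 120):
        x[t] = 0.4 * x[t - 1] + eps[t]
    widths = 1.5 * np.exp(-0.008 * np.arange(120)) * np.exp(x)
    return RingWidthSeries("SER1", "T1", "1", 0, widths)
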