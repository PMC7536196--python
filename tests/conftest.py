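import numpy as np
import pytest

from hidalgo import compute_mu, find_neighbors, neighbor_stats
from hidalgo.model import HidalgoConfig


@pytest.fixture
def line_stats():
    """Three collinear points at 0, 1, 3 (hand-checkable fixture)."""
    x = np.array([[0.0], [1.0], [3.0]])
    d = np.abs(x - x.T)
    return compute_mu(find_neighbors(d, q=2))


@pytest.fixture
def gauss30_stats():
    """30 points of a 3-D Gaussian with q=3 (generic small fixture)."""
    rng = np.random.default_rng(42)
    return neighbor_stats(rng.standard_normal((30, 3)), q=3)


@pytest.fixture
def small_cfg():
    return HidalgoConfig(K=3, q=3, xi=0.8, n_sweeps=50, n_chains=1, seed=0)
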