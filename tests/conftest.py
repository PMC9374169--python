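import numpy as np
import pytest

from daa.datamodel import MultiViewData, ViewKey
from daa.synthetic import SyntheticSpec, simulate


def random_simplex(rng, shape):
    M = rng.exponential(size=shape)
    return M / M.sum(axis=0)


def make_instance(seed, D=3, N=12, K=2):
    """A small random preprocessed single-view problem plus simplex C, S."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((D, N))
    data = MultiViewData.from_raw({ViewKey("m", "s"): X})
    C = random_simplex(rng, (N, K))
    S = random_simplex(rng, (K, N))
    return data, C, S


@pytest.fixture(scope="session")
def octant_small():
    """Noise-free one-octant dataset, desk scale (n=300)."""
    spec = SyntheticSpec(family="octant", n_samples=300, noise_sd=0.0, seed=42)
    X, gt = simulate(spec)
    return MultiViewData.from_raw({ViewKey("sim", "s1"): X}), gt


@pytest.fixture(scope="session")
def octant_noisy():
    spec = SyntheticSpec(family="octant", n_samples=300, noise_sd=0.05, seed=7)
    X, gt = simulate(spec)
    return MultiViewData.from_raw({ViewKey("sim", "s1"): X}), gt


@pytest.fixture(scope="session")
def antipodal_small():
    spec = SyntheticSpec(family="antipodal", n_samples=300, noise_sd=0.05, seed=7)
    X, gt = simulate(spec)
    return MultiViewData.from_raw({ViewKey("sim", "s1"): X}), gt
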