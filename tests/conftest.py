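import numpy as np
import pytest

from boso.data import SplitData
from boso.sim_bench import SimulationSpec, simulate


def make_split(
    seed: int = 0,
    n_train: int = 30,
    n_val: int = 30,
    p: int = 6,
    s: int = 2,
    snr: float = 2.0,
    rho: float = 0.35,
) -> SplitData:
    """A seeded simulated problem split into equal train/validation halves."""
    spec = SimulationSpec(n=n_train + n_val, p=p, s=s, snr=snr, rho=rho,
                          seed=seed)
    data = simulate(spec)
    return SplitData(
        data.X[:n_train], data.y[:n_train],
        data.X[n_train:], data.y[n_train:],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_split() -> SplitData:
    return make_split(seed=7)
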