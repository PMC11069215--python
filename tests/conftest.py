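import numpy as np
import pytest

from dthazard.data import CompetingRisksDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_hazards(rng, n=1, E=3, T=10, scale=0.8):
    """Random valid hazard tensors: per-step cause sums stay below ``scale``."""
    raw = rng.uniform(0.01, 1.0, size=(n, E, T))
    total = raw.sum(axis=1, keepdims=True)
    return raw / total * rng.uniform(0.2, scale, size=(n, 1, T))


def random_dataset(rng, n=50, p=4, E=2, T=6):
    covariates = rng.uniform(size=(n, p))
    events = rng.integers(0, E + 1, size=n)
    times = rng.integers(0, T, size=n)
    return CompetingRisksDataset(covariates, events, times, E, T)
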