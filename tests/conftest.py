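import numpy as np
import pytest

from lsanet.data_io import Dataset, ReplicatedSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def small_dataset(rng):
    """Four factors, 10 time points, 2 replicates, no missing values."""
    n, m, T = 10, 2, 4
    series = [ReplicatedSeries(rng.standard_normal((n, m))) for _ in range(T)]
    return Dataset([f"f{k}" for k in range(T)], series, n, m)
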