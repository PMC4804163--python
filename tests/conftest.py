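import numpy as np
import pytest

from dnattract.refpmf import reference_pmf
from dnattract.synth.umbrella import sample_umbrella_series


@pytest.fixture(scope="session")
def at10_pmf():
    return reference_pmf("AT10")


@pytest.fixture(scope="session")
def small_at10_windows(at10_pmf):
    """A reduced umbrella data set (coarser protocol) for fast WHAM tests."""
    return sample_umbrella_series(
        at10_pmf, turns=2.0, windows=tuple(float(c) for c in range(23, 33)),
        n_samples=3000, seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
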