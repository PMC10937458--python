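import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from bnct_tcp import (
    DVH,
    SCC_TCP_PARAMS,
    SCC_USC_PARAMS,
)


@pytest.fixture
def scc():
    """Published USC coefficients for SCC (FaDu)."""
    return SCC_USC_PARAMS


@pytest.fixture
def tcp_params():
    return SCC_TCP_PARAMS


@pytest.fixture
def two_bin_dvh():
    return DVH(kind="differential", doses=[18.5, 25.3], volumes=[0.5, 0.5])


def naive_geud(doses, volumes, a):
    """Brute-force power-sum gEUD oracle (no log-space tricks)."""
    doses = np.asarray(doses, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    return float(np.sum(volumes * doses**a) ** (1.0 / a))


def random_valid_dvh(rng, n_max=12, dose_lo=5.0, dose_hi=100.0):
    """Random differential DVH with doses in [dose_lo, dose_hi]."""
    n = int(rng.integers(1, n_max + 1))
    doses = np.sort(rng.uniform(dose_lo, dose_hi, size=n))
    while np.any(np.diff(doses) <= 1e-9):
        doses = np.sort(rng.uniform(dose_lo, dose_hi, size=n))
    vols = rng.dirichlet(np.ones(n))
    return DVH(kind="differential", doses=doses, volumes=vols)
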