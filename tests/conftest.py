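import warnings

import numpy as np
import pytest

from metalv.ensemble import (
    EnsembleParams,
    InteractionSet,
    migration_matrix,
    sample_interactions,
)


@pytest.fixture(autouse=True)
def _quiet_stationarity_warnings():
    # short unit-test windows legitimately trip the drift warning
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*stationarity.*")
        warnings.filterwarnings("ignore", message=".*correlation times.*")
        yield


@pytest.fixture
def two_species_symmetric():
    """Two mutually competing species, a = 0.5, closed-form equilibrium 2/3."""
    A = np.zeros((2, 2, 1))
    A[0, 1, 0] = A[1, 0, 0] = 0.5
    params = EnsembleParams(S=2, M=1, c=1.0, mu_A=0.5, sd_A=0.0, N_c=1e-8)
    return InteractionSet(
        A=A,
        B=np.ones((2, 1)),
        D=np.zeros((1, 1)),
        mask=A[:, :, 0] != 0,
        params=params,
    )


@pytest.fixture
def small_random_system():
    """10 species, 2 patches: generic fixture for Jacobian/rhs checks."""
    params = EnsembleParams(
        S=10, M=2, c=0.5, mu_A=0.1, sd_A=0.1, rho=0.5, d=0.05, N_c=1e-8, seed=3
    )
    return sample_interactions(params)


@pytest.fixture(scope="session")
def scaled_fluctuating_system():
    """S=100, M=4 dense-disorder metacommunity in the fluctuating regime.

    Used by several slower tests; sampled once per session.
    """
    params = EnsembleParams(
        S=100, M=4, c=1.0, mu_A=0.10, sd_A=0.30, rho=0.90,
        d=0.01, N_c=1e-8, seed=7,
    )
    return sample_interactions(params)
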