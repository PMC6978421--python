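import numpy as np
import pytest

from netokit.model import NetoParams, PopulationParams, WagKinetics
from netokit.synth import deterministic_population


@pytest.fixture
def msm_params() -> NetoParams:
    """Biphasic law at the M. smegmatis population means."""
    return NetoParams(0.0, 0.15, 0.61, 2.9)


@pytest.fixture
def msm_pop() -> PopulationParams:
    """M. smegmatis population distribution (printed means and SDs)."""
    return PopulationParams(2.9, 0.8, 3.6, 0.7, 0.15, 0.06, 0.61, 0.13)


@pytest.fixture
def mtb_pop() -> PopulationParams:
    """M. tuberculosis lag/interdivision distribution (speeds as for Msm)."""
    return PopulationParams(6.2, 2.2, 16.3, 3.1, 0.15, 0.06, 0.61, 0.13)


@pytest.fixture
def msm_det_pop() -> PopulationParams:
    """Deterministic (zero-SD) population at the M. smegmatis means."""
    return deterministic_population()


@pytest.fixture
def wag() -> WagKinetics:
    return WagKinetics(i0_frac=0.10, tau_h=2.4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
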