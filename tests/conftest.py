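import numpy as np
import pytest

from needsmsm.estimation import fit_msm
from needsmsm.intensities import TransitionParams
from needsmsm.simulate import SimulationConfig, generate_panel


@pytest.fixture(scope="session")
def sim_cfg() -> SimulationConfig:
    """A moderate synthetic cohort: study-shaped but small enough for tests."""
    return SimulationConfig(n_subjects=600)


@pytest.fixture(scope="session")
def sim_panel(sim_cfg):
    panel, truth = generate_panel(sim_cfg, seed=42)
    return panel


@pytest.fixture(scope="session")
def fitted(sim_panel):
    """Full 28-parameter fit of the session cohort, shared across tests."""
    return fit_msm(sim_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_params(rng, scale=0.3) -> TransitionParams:
    """Random but well-behaved intensity parameters."""
    return TransitionParams(
        beta0=rng.normal(-2.5, scale, size=4),
        xi=rng.normal(0.03, 0.01, size=4),
        beta=rng.normal(0.0, scale, size=(4, 5)),
    )
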