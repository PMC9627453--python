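import numpy as np
import pytest
from hypothesis import settings

from superfbm.params import ModelParams, golding_cox_preset
from superfbm.simulate import simulate_ensemble

settings.register_profile("deterministic", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def preset() -> ModelParams:
    return golding_cox_preset()


@pytest.fixture(scope="session")
def het_ensemble(preset):
    """Heterogeneous (Weibull-population) ensemble, shared across tests."""
    return simulate_ensemble(preset, n_traj=500, n_steps=2 ** 10, dt=1.0, seed=101)


@pytest.fixture(scope="session")
def hom_ensemble(preset):
    """Homogeneous fixed-scale control ensemble."""
    return simulate_ensemble(preset, n_traj=200, n_steps=2 ** 10, dt=1.0,
                             seed=102, fixed_lambda=preset.lambda0)
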