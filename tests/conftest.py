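import warnings

import pytest
from hypothesis import settings

from meientry import model, synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from meientry.config import RunConfig


@pytest.fixture(scope="session")
def closed_params() -> model.ModelParameters:
    """Published rate constants with the closure resolved at the default baseline."""
    return model.closure_solve(model.default_parameters())


@pytest.fixture(scope="session")
def resolved_params(closed_params) -> model.ModelParameters:
    """Closure plus self-consistently resolved tau1/tau2."""
    tau = model.tau_fixed_point(closed_params)
    return closed_params.replace(tau1=tau.tau1, tau2=tau.tau2)


@pytest.fixture(scope="session")
def wildtype(resolved_params) -> model.Trajectory:
    return model.simulate(resolved_params)


@pytest.fixture(scope="session")
def small_cohort(resolved_params):
    """Sixty-cell mixture cohort with default noise, shared across tests."""
    cfg = synth.CohortConfig(n_cells=60, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truths = synth.generate_cohort(cfg, params=resolved_params)
    return cfg, table, truths


@pytest.fixture()
def run_config() -> RunConfig:
    return RunConfig()
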