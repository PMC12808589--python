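import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcpgig import CountPanel
from mcpgig.simulate import default_truth, generate_design, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_truth():
    """True coefficients of the estimator-recovery study (gamma = -1/2)."""
    return default_truth(-0.5)


@pytest.fixture(scope="session")
def mcpgig_panel(study_truth) -> CountPanel:
    """One n=300 panel drawn from the MCPGIG truth (shared across tests)."""
    rng = np.random.default_rng(np.random.SeedSequence([11, 0]))
    return simulate_dataset(generate_design(300, seed=rng), study_truth,
                            family="MCPGIG", seed=rng)


@pytest.fixture(scope="session")
def mp_panel(study_truth) -> CountPanel:
    """One n=200 equidispersed panel from the unmixed multivariate Poisson."""
    rng = np.random.default_rng(np.random.SeedSequence([11, 1]))
    return simulate_dataset(generate_design(200, seed=rng), study_truth,
                            family="MP", seed=rng)


@pytest.fixture(scope="session")
def mcpgigr_fit(mcpgig_panel):
    """Converged MCPGIGR fit of the shared panel."""
    from mcpgig import fit_mcpgigr

    fit = fit_mcpgigr(mcpgig_panel, gamma=-0.5)
    assert fit.converged
    return fit
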