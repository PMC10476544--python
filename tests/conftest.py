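import numpy as np
import pytest

from dsemcfa import (
    McmcSettings,
    ModelSpec,
    default_true_parameters,
    run_mcmc,
    simulate_panel,
)
from dsemcfa.synthetic_data import TrueParameters


@pytest.fixture(scope="session")
def default_params():
    return default_true_parameters()


@pytest.fixture(scope="session")
def recovery_params(default_params):
    """Recovery-study truth: structural block with moderate innovation-variance
    heterogeneity (log-scale variance 1.0) so person-level dynamics are
    informative at the study's series lengths."""
    sd = np.sqrt([0.25, 0.07, 1.0])
    corr = np.array([[1, 0.704, 0.647], [0.704, 1, 0.255], [0.647, 0.255, 1]])
    return TrueParameters(
        item_ids=default_params.item_ids,
        loadings_within=default_params.loadings_within,
        loadings_between=default_params.loadings_between,
        intercepts=default_params.intercepts,
        resid_var_within=default_params.resid_var_within,
        resid_var_between=default_params.resid_var_between,
        gamma=np.array([0.0, 0.45, -3.26]),
        Sigma_b=corr * np.outer(sd, sd),
    )


@pytest.fixture(scope="session")
def small_panel(recovery_params):
    """One simulated panel at reduced size for shared fitting tests."""
    data, res, traj = simulate_panel(
        recovery_params,
        n=80,
        length_distribution=lambda rng, n: rng.poisson(9, n) + 2,
        seed=424,
    )
    return data, res, traj


@pytest.fixture(scope="session")
def fitted_small_panel(small_panel, recovery_params):
    """A converged-ish unconditional fit shared across derivation tests."""
    data, _, _ = small_panel
    spec = ModelSpec(item_ids=list(recovery_params.item_ids), anchor_item="item_1")
    settings = McmcSettings(n_chains=2, n_iterations=2000, seed=7)
    return run_mcmc(data, spec, settings)
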