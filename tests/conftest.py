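import numpy as np
import pytest

from iptwpower import OutcomeModelParams, Scenario, treatment_model_for
from iptwpower.dgp import simulate_observational_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_obs_cohort():
    """A 2000-subject observational cohort with moderate confounding."""
    tparams = treatment_model_for(0.7, 0.25)
    oparams = OutcomeModelParams(beta_treat=0.4)
    scen = Scenario(n_events=2000, marginal_hr=1.25, prevalence=0.25, auc=0.7)
    return simulate_observational_cohort(scen, tparams, oparams, np.random.default_rng(11))
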