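import numpy as np
import pytest
from hypothesis import settings

from oxmis_cea import ParameterSet, base_case

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """Packaged base-case parameter set."""
    return base_case()


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """A random ParameterSet satisfying all model invariants.

    The overall incidence is sampled inside the feasible interval
    [p_high * p_suicide_high, p_suicide_high] so that the low-risk-branch
    risk derived from the mixture constraint is always valid.
    """
    p_high = rng.uniform(0.05, 0.9)
    p_suicide_high = rng.uniform(0.001, 0.2)
    p_overall = rng.uniform(p_high * p_suicide_high, p_suicide_high)
    utility = rng.uniform(0.3, 1.0)
    return ParameterSet(
        p_high_oxmis=p_high,
        p_high_clinical=rng.uniform(0.0, 1.0),
        p_suicide_high=p_suicide_high,
        p_suicide_overall=p_overall,
        hrm_risk_reduction=rng.uniform(0.0, 1.0),
        cost_oxmis=rng.uniform(0.0, 500.0),
        cost_clinical_assessment=rng.uniform(0.0, 1000.0),
        cost_hrm=rng.uniform(0.0, 5000.0),
        cost_lrm=rng.uniform(0.0, 200.0),
        cost_suicide=rng.uniform(0.0, 2000.0),
        utility_smi=utility,
        utility_decrement_hrm=rng.uniform(0.0, utility),
    )
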