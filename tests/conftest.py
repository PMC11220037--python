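import numpy as np
import pandas as pd
import pytest

from eeanet.cohort import build_task_schedule
from eeanet.ddm import ConditionParameters, DDMParameters, simulate_trials


@pytest.fixture(scope="session")
def typical_params() -> DDMParameters:
    """A realistic parameter set for an engaged n-back participant."""
    return DDMParameters(conditions={
        0: ConditionParameters(2.5, 3.0, 1.8, 1.1, 0.35, 0.15, 0.5, 0.03),
        2: ConditionParameters(1.6, 2.2, 1.0, 1.2, 0.40, 0.18, 0.5, 0.05),
    })


@pytest.fixture(scope="session")
def canonical_schedule() -> pd.DataFrame:
    """8 blocks x 10 trials per condition, 2 targets and 2-3 lures per block."""
    return build_task_schedule("s1", seed=123)


@pytest.fixture(scope="session")
def simulated_subject(typical_params, canonical_schedule):
    return simulate_trials(typical_params, canonical_schedule, seed=42)


def random_valid_parameters(rng: np.random.Generator) -> DDMParameters:
    """Random parameter set inside the plausible human RT regime."""
    def cond():
        return ConditionParameters(
            v_target=rng.uniform(-4, 5),
            v_novel=rng.uniform(-4, 5),
            v_lure=rng.uniform(-4, 5),
            a=rng.uniform(0.5, 2.5),
            t0=rng.uniform(0.1, 0.6),
            st0=rng.uniform(0.0, 0.4),
            z=rng.uniform(0.2, 0.8),
            p_contam=rng.uniform(0.0, 0.4),
        )
    return DDMParameters(conditions={0: cond(), 2: cond()})
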