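import numpy as np
import pytest

from cogmech import synthetic as syn


@pytest.fixture(scope="session")
def default_design():
    return syn.generate_task_design(seed=1)


@pytest.fixture(scope="session")
def small_choice_df(default_design):
    cohort = syn.default_reward_effort_cohort(n_subjects=12, seed=3)
    return syn.simulate_reward_effort_cohort(default_design, cohort)


@pytest.fixture(scope="session")
def small_attribution_df():
    cohort = syn.default_attribution_cohort(n_subjects=12, seed=4)
    return syn.simulate_attribution_cohort(cohort=cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
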