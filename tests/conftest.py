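import numpy as np
import pytest

import wmreselect as w


@pytest.fixture(scope="session")
def small_cfg():
    return w.TaskConfig(n_participants=4, n_trials_per_participant=48, seed=11)


@pytest.fixture(scope="session")
def small_table(small_cfg):
    return w.make_trial_table(small_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
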