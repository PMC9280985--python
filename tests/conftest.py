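"""Shared fixtures: small, fast synthetic configurations.

Unit tests run on reduced problem sizes (2 subjects, 5 cycles, 1 kHz);
the acceptance tests use the full study conditions.
"""

import numpy as np
import pytest

from neckcore.signal_model import Condition
from neckcore.synthetic_data import SyntheticConfig, build_study, generate_running_trial


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_config():
    return SyntheticConfig(
        n_subjects=2,
        seed=7,
        fs=1000.0,
        n_cycles=5,
        mvc_trial_duration=1.0,
        rest_trial_duration=1.0,
    )


@pytest.fixture()
def running_trial(small_config, rng):
    trial, truth = generate_running_trial("S01", Condition.CONTROL, small_config, rng)
    return trial, truth


@pytest.fixture(scope="session")
def small_running_study():
    config = SyntheticConfig(
        n_subjects=2,
        seed=21,
        fs=1000.0,
        n_cycles=5,
        mvc_trial_duration=1.0,
        rest_trial_duration=1.0,
    )
    study = build_study(
        config,
        conditions=[
            Condition.CONTROL,
            Condition.FORWARD_PULL,
            Condition.FORWARD_PULL_MASS,
        ],
    )
    return config, study
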