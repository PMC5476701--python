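import dataclasses

import numpy as np
import pytest

from mbplast.preprocess import process_recording
from mbplast.protocol import build_protocol
from mbplast.quantify import cohort_strength_table, cohort_window_table
from mbplast.synthdata import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def paired_protocol():
    return build_protocol("paired", 0)


@pytest.fixture(scope="session")
def unpaired_protocol():
    return build_protocol("unpaired", 0)


@pytest.fixture(scope="session")
def protocols(paired_protocol, unpaired_protocol):
    return {"paired": paired_protocol, "unpaired": unpaired_protocol}


@pytest.fixture(scope="session")
def noiseless_config():
    """Deterministic generator settings: no noise, no between-fly
    scaling, no γ1 dropout, no run-down/bleach."""
    return SyntheticConfig(noise_sd=0.0, fly_amplitude_cv=0.0,
                           gamma1_dropout=0.0, rundown_rate=0.0,
                           bleach_rate=0.0, current_log_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort(protocols, noiseless_config):
    pair = (protocols["paired"], protocols["unpaired"])
    return generate_cohort(pair, noiseless_config, 2)


@pytest.fixture(scope="session")
def noiseless_trace_sets(noiseless_cohort, protocols):
    return [process_recording(f, protocols[f.group])
            for f in noiseless_cohort]


@pytest.fixture(scope="session")
def noiseless_strengths(noiseless_trace_sets, protocols):
    return cohort_strength_table(noiseless_trace_sets, protocols)


@pytest.fixture(scope="session")
def noiseless_windows(noiseless_trace_sets, protocols):
    return cohort_window_table(noiseless_trace_sets, protocols)


@pytest.fixture(scope="session")
def noisy_cohort(protocols, noiseless_config):
    cfg = dataclasses.replace(noiseless_config, noise_sd=0.05,
                              fly_amplitude_cv=0.2, gamma1_dropout=0.3,
                              rundown_rate=0.03, bleach_rate=0.02,
                              current_log_sd=0.3, seed=7)
    pair = (protocols["paired"], protocols["unpaired"])
    return generate_cohort(pair, cfg, 4)


@pytest.fixture(scope="session")
def noisy_strengths(noisy_cohort, protocols):
    sets = [process_recording(f, protocols[f.group]) for f in noisy_cohort]
    return cohort_strength_table(sets, protocols)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
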