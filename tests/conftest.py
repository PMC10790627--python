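import numpy as np
import pandas as pd
import pytest

from oscsync import Session, StimulusGrid
from oscsync.synth import LfpGenParams, SpikeGenParams, gen_lfp_session, gen_phase_locked_spikes


def tiny_session(n_trials=1, n_channels=2, n_samples=2200, seed=0):
    """Minimal hand-built valid session for container tests."""
    rng = np.random.default_rng(seed)
    lfp = rng.standard_normal((n_trials, n_channels, n_samples))
    trials = pd.DataFrame(
        {
            "stimulus_id": [12] * n_trials,
            "sf": [0.06] * n_trials,
            "tf": [3.0] * n_trials,
            "onset_s": [0.5] * n_trials,
            "condition": ["pre"] * n_trials,
        }
    )
    units = pd.DataFrame({"area": ["V1"], "best_channel": [0]}, index=["V1_u0"])
    spikes = {"V1_u0": [np.array([0.6, 1.0]) for _ in range(n_trials)]}
    return Session(
        lfp=lfp,
        channel_depths=np.linspace(100, 100 * n_channels, n_channels),
        channel_columns=np.zeros(n_channels, dtype=np.int64),
        channel_areas=np.array(["V1"] * n_channels, dtype=object),
        spike_trains=spikes,
        units=units,
        trials=trials,
    )


@pytest.fixture
def tiny():
    return tiny_session()


@pytest.fixture(scope="session")
def locked_session():
    """Jitter-free pi/4-lagged two-area session, one stimulus, 20 trials."""
    return gen_lfp_session(
        LfpGenParams(stimuli=(12,), trial_jitter_kappa=1e6,
                     inter_areal_lag=np.pi / 4, seed=3)
    )


@pytest.fixture(scope="session")
def spiking_session():
    """Session with kappa=1 phase-locked units for spike-phase tests."""
    base = gen_lfp_session(LfpGenParams(stimuli=(12,), trial_jitter_kappa=2.0, seed=11))
    return gen_phase_locked_spikes(
        base,
        SpikeGenParams(phase_kappa=1.0, base_rate=0.0, resp_rate=20.0,
                       n_units_per_area=30, seed=42),
    )


@pytest.fixture(scope="session")
def grid():
    return StimulusGrid()
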