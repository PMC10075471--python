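import numpy as np
import pandas as pd
import pytest

from serialdep.io import derive_history_columns
from serialdep.synthetic import (
    SynthBehaviorConfig,
    SynthNeuralConfig,
    default_features,
    simulate_behavior,
    simulate_epochs,
)


def make_trials(pitches, participants=None, choices=None, motors=None, rts=None):
    """Hand-built trial table from per-trial value lists."""
    n = len(pitches)
    participants = ["P01"] * n if participants is None else participants
    choices = [0] * n if choices is None else choices
    motors = [0] * n if motors is None else motors
    rts = [0.5] * n if rts is None else rts
    rows = []
    counters = {}
    for i in range(n):
        p = participants[i]
        counters[p] = counters.get(p, -1) + 1
        rows.append(
            {
                "participant": p,
                "block": 1,
                "trial_index": counters[p],
                "pitch_level": pitches[i],
                "choice": choices[i],
                "motor_response": motors[i],
                "cue_mapping": choices[i] ^ motors[i],
                "reaction_time": rts[i],
                "valid": True,
            }
        )
    trials = pd.DataFrame(rows)
    trials = derive_history_columns(trials, -1)
    trials = derive_history_columns(trials, +1)
    return trials


@pytest.fixture
def toy_trials():
    return make_trials([1, 4, 2, 3, 5, 2], choices=[0, 1, 0, 1, 1, 0], motors=[0, 1, 1, 0, 1, 1])


@pytest.fixture(scope="session")
def behavior_small():
    """Four participants x 300 trials from the default serial-bias model."""
    cfg = SynthBehaviorConfig(n_participants=4, n_trials=300, block_size=50, seed=42)
    return cfg, simulate_behavior(cfg)


@pytest.fixture(scope="session")
def epochs_small():
    """One participant, 200 trials, 12 channels, short epochs around the tone."""
    bcfg = SynthBehaviorConfig(n_participants=1, n_trials=200, block_size=50, seed=7)
    trials = simulate_behavior(bcfg)
    ncfg = SynthNeuralConfig(
        n_channels=12,
        t_start=0.7,
        t_stop=2.1,
        features=default_features(reactivation_gain=0.5),
        noise_amplitude=1.5,
        seed=3,
    )
    return trials, ncfg, simulate_epochs(trials, ncfg)
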