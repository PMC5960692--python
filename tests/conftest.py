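import numpy as np
import pandas as pd
import pytest

from odortrace import SynthConfig, TraceSet, compute_dff, generate_traceset


@pytest.fixture(scope="session")
def small_cfg():
    """Small but structured population: 2 animals × 20 units, 5 odor classes."""
    return SynthConfig(n_animals=2, units_per_animal=20, seed=101)


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return generate_traceset(small_cfg)


@pytest.fixture(scope="session")
def small_dff(small_recording):
    ts, _ = small_recording
    return compute_dff(ts)


@pytest.fixture(scope="session")
def clean_cfg():
    """Noiseless, bleach-free configuration: ΔF/F equals the kernels."""
    return SynthConfig(n_animals=2, units_per_animal=25, seed=7,
                       noise_sd=0.0, bleach_a=0.0, bleach_c=1.0)


@pytest.fixture(scope="session")
def clean_recording(clean_cfg):
    return generate_traceset(clean_cfg)


@pytest.fixture(scope="session")
def clean_dff(clean_recording):
    ts, _ = clean_recording
    return compute_dff(ts)


def make_traceset(data, frame_rate=5.0, stim_onset_frame=25, stim_duration_s=10.0,
                  signal_kind="dff", odors=None, trials=None, animals=None):
    """Hand-rolled TraceSet around a (units, frames, stimuli) array."""
    n_u, _, n_s = data.shape
    if odors is None:
        odors = ["odorA"] * n_s
    if trials is None:
        trials = list(range(1, n_s + 1))
    if animals is None:
        animals = ["flyA"] * n_u
    units = pd.DataFrame({"animal": animals, "unit": np.arange(n_u)})
    stimuli = pd.DataFrame({"odor": odors, "trial": trials})
    return TraceSet(np.asarray(data, float), units, stimuli, frame_rate,
                    stim_onset_frame, stim_duration_s, signal_kind)
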