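"""Shared fixtures: one healthy and one susceptible recording plus a trained
E/I decoder, reused session-wide to keep the suite fast."""

import numpy as np
import pytest

from ipis import ei_decoder as ed
from ipis import lfp_features as lf
from ipis import spike_analysis as sa
from ipis import synthetic_data as sd


@pytest.fixture(scope="session")
def healthy_recording() -> sd.SyntheticRecording:
    return sd.simulate_recording("healthy", duration_s=60.0, seed=1)


@pytest.fixture(scope="session")
def susceptible_recording() -> sd.SyntheticRecording:
    return sd.simulate_recording("susceptible", duration_s=60.0, seed=1)


@pytest.fixture(scope="session")
def detected_states(healthy_recording) -> sd.StateIntervals:
    return sa.detect_states_from_spikes(
        healthy_recording.spikes, healthy_recording.duration_s
    )


@pytest.fixture(scope="session")
def labeled_windows(healthy_recording, detected_states):
    feats = lf.sliding_features(healthy_recording.lfp, healthy_recording.fs)
    return ed.label_windows(feats, detected_states)


@pytest.fixture(scope="session")
def decoder_model(labeled_windows) -> ed.DecoderModel:
    return ed.train_decoder(labeled_windows, "RF", {"n_estimators": 200}, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
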