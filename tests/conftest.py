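import numpy as np
import pytest

from pulsepat.pat_pipeline import run_pat_pipeline
from pulsepat.synthgen import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """10-minute clean regular-rhythm recording with constant 0.25 s PAT."""
    cfg = SynthConfig(duration_s=600.0, seed=1)
    recording, truth, annotations = generate_recording(cfg)
    return cfg, recording, truth, annotations


@pytest.fixture(scope="session")
def clean_pipeline(clean_recording):
    """Full pipeline output on the clean recording."""
    _, recording, truth, annotations = clean_recording
    series, pulses, beats = run_pat_pipeline(recording)
    return recording, truth, annotations, series, pulses, beats


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
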