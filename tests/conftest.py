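import numpy as np
import pytest

from bedvitals import SynthesisConfig, synthesize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_signal():
    """Noiseless 60 bpm / 15 brpm drive signal, 20 s at 100 Hz."""
    return synthesize(SynthesisConfig(hr_bpm=60.0, rr_bpm=15.0, duration_s=20.0))
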