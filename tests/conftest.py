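import numpy as np
import pytest

from smrnf import EEGRecording, Montage, SMR, add_band_oscillation


@pytest.fixture(scope="session")
def montage():
    return Montage()


@pytest.fixture(scope="session")
def silent_rec(montage):
    """60 s of all-zero EEG (a blank canvas for injected signals)."""
    return EEGRecording(np.zeros((montage.n_channels, 256 * 60)), 256.0, montage)


@pytest.fixture(scope="session")
def smr_sinusoid_rec(silent_rec):
    """A pure 13.5 Hz, 10 uV sinusoid on every channel: band power 50 uV^2."""
    return add_band_oscillation(silent_rec, SMR, 10.0, freq=13.5)
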