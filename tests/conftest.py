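import numpy as np
import pytest

from sitesep.audio import Waveform
from sitesep.synth import BackgroundSpec, SongSpec, synth_background, synth_song

RATE = 22_050


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_wave(rng):
    return Waveform(rng.standard_normal(3 * RATE) * 0.05, RATE)


@pytest.fixture
def song_a():
    return synth_song(SongSpec(song_type="A", seed=11), RATE)


@pytest.fixture
def background_bed():
    return synth_background(BackgroundSpec(duration_s=8.0, seed=12), RATE)


def sine(freq_hz: float, duration_s: float, rate: int = RATE, amp: float = 0.5) -> Waveform:
    t = np.arange(int(round(duration_s * rate))) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq_hz * t), rate)
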