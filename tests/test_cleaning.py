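import numpy as np
import pytest

from sitesep.audio import DegenerateInputError, TimeInterval, Waveform
from sitesep.cleaning import (
    CleaningConfig,
    clean_segment,
    estimate_bbr,
    highpass,
    normalize_peak,
    spectral_gate,
)
from sitesep.audio import peak_dbfs

from conftest import RATE, sine


class TestHighpass:
    def test_dc_rejected(self):
        w = Waveform(np.full(RATE, 0.7), RATE)
        out = highpass(w, CleaningConfig())
        assert np.max(np.abs(out.samples)) < 1e-4

    def test_tone_at_twice_cutoff_preserved_within_1db(self):
        w = sine(4000, 2.0)
        out = highpass(w, CleaningConfig(hp_cutoff_hz=2000))
        gain_db = 20 * np.log10(out.rms() / w.rms())
        assert abs(gain_db) < 1.0

    def test_tone_at_cutoff_minus_6db_zero_phase(self):
        """Forward-backward pass squares |H|; Butterworth gives -3 dB
        single-pass at the cutoff, hence -6 dB zero-phase."""
        w = sine(2000, 2.0)
        out = highpass(w, CleaningConfig(hp_cutoff_hz=2000))
        gain_db = 20 * np.log10(out.rms() / w.rms())
        assert gain_db == pytest.approx(-6.02, abs=0.3)

    def test_cutoff_beyond_nyquist_rejected(self, noise_wave):
        with pytest.raises(ValueError):
            highpass(noise_wave, CleaningConfig(hp_cutoff_hz=12_000))

    def test_length_preserved(self, noise_wave):
        assert len(highpass(noise_wave, CleaningConfig())) == len(noise_wave)


class TestNormalizePeak:
    def test_half_scale_closed_form(self):
        w = Waveform(np.array([0.5, -0.25, 0.1]), RATE)
        out = normalize_peak(w, -1.0)
        assert np.max(np.abs(out.samples)) == pytest.approx(10 ** (-1 / 20), abs=1e-9)
        # pure gain: shape unchanged
        assert np.allclose(out.samples / w.samples, out.samples[0] / w.samples[0])

    def test_already_at_target_unchanged(self):
        w = Waveform(np.array([10 ** (-1 / 20), 0.2]), RATE)
        out = normalize_peak(w, -1.0)
        assert np.allclose(out.samples, w.samples, atol=1e-12)

    def test_silence_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_peak(Waveform(np.zeros(100), RATE), -1.0)

    def test_target_reached_exactly(self, noise_wave):
        out = normalize_peak(noise_wave, -1.0)
        assert peak_dbfs(out) == pytest.approx(-1.0, abs=1e-6)


def tone_burst(freq, rate=RATE, total_s=3.0, burst=(1.0, 2.0), amp=1.0):
    """A tone occupying only part of the clip (a transient 'song')."""
    n = int(total_s * rate)
    x = np.zeros(n)
    i0, i1 = int(burst[0] * rate), int(burst[1] * rate)
    t = np.arange(i1 - i0) / rate
    x[i0:i1] = amp * np.sin(2 * np.pi * freq * t)
    return x


class TestSpectralGate:
    def test_pure_noise_attenuated_by_nearly_full_reduction(self, rng):
        w = Waveform(rng.standard_normal(3 * RATE) * 0.05, RATE)
        cfg = CleaningConfig()
        out = spectral_gate(w, cfg)
        reduction_db = 20 * np.log10(w.rms() / out.rms())
        assert reduction_db >= cfg.gate_reduction_db - 3.0

    def test_strong_tone_burst_preserved_within_1db(self, rng):
        noise = rng.standard_normal(3 * RATE) * 0.05
        tone = tone_burst(5000, amp=0.05 * 10 ** (30 / 20))
        w = Waveform(noise + tone, RATE)
        out = spectral_gate(w, CleaningConfig())

        def tone_bin_mag(x):
            seg = x[RATE : 2 * RATE]
            spec = np.abs(np.fft.rfft(seg))
            k = round(5000 * len(seg) / RATE)
            return spec[k - 2 : k + 3].max()

        change_db = 20 * np.log10(tone_bin_mag(out.samples) / tone_bin_mag(w.samples))
        assert abs(change_db) < 1.0

    def test_all_zero_input_passes_through(self):
        w = Waveform(np.zeros(2 * RATE), RATE)
        out = spectral_gate(w, CleaningConfig())
        assert np.all(out.samples == 0)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spectral_gate(Waveform(np.zeros(100), RATE), CleaningConfig())

    def test_never_increases_energy(self, rng):
        w = Waveform(rng.standard_normal(2 * RATE) * 0.1, RATE)
        out = spectral_gate(w, CleaningConfig())
        assert out.rms() <= w.rms() * (1 + 1e-6)

    def test_external_noise_sample_floor(self, rng):
        noise = rng.standard_normal(3 * RATE) * 0.05
        tone = tone_burst(5000, amp=0.5)
        w = Waveform(noise + tone, RATE)
        ref = Waveform(rng.standard_normal(2 * RATE) * 0.05, RATE)
        out = spectral_gate(w, CleaningConfig(), noise_sample=ref)
        # in-band burst survives
        assert out.rms() > 0.1 * w.rms()


class TestEstimateBbr:
    def test_uniform_signal_ratio_zero(self, rng):
        w = Waveform(rng.standard_normal(4 * RATE) * 0.1, RATE)
        est = estimate_bbr(w, TimeInterval(1, 2), (2000, 8000))
        assert est.ratio_db == pytest.approx(0.0, abs=1.0)

    def test_ten_times_rms_is_20db(self, rng):
        x = rng.standard_normal(4 * RATE) * 0.01
        x[RATE : 2 * RATE] *= 10
        est = estimate_bbr(Waveform(x, RATE), TimeInterval(1, 2), (100, 10000))
        assert est.ratio_db == pytest.approx(20.0, abs=1.0)

    def test_screen_rule_flags_below_minus_10db(self, rng):
        x = rng.standard_normal(4 * RATE) * 0.1
        x[RATE : 2 * RATE] *= 0.01  # song 40 dB below background
        est = estimate_bbr(Waveform(x, RATE), TimeInterval(1, 2), (100, 10000))
        assert est.ratio_db < -10
        assert est.flagged_for_removal

    def test_gain_invariance(self, rng):
        x = rng.standard_normal(4 * RATE) * 0.1
        a = estimate_bbr(Waveform(x, RATE), TimeInterval(1, 2), (1000, 8000))
        b = estimate_bbr(Waveform(x * 7.3, RATE), TimeInterval(1, 2), (1000, 8000))
        assert a.ratio_db == pytest.approx(b.ratio_db, abs=1e-9)

    def test_interval_covering_whole_clip_rejected(self, rng):
        w = Waveform(rng.standard_normal(RATE), RATE)
        with pytest.raises(ValueError):
            estimate_bbr(w, TimeInterval(0, 1.0), (1000, 8000))


class TestCleanSegment:
    def test_band_energy_oracle(self, rng):
        """In-band song energy survives within 2 dB; out-of-band rumble
        and broadband noise drop by at least 20 dB."""
        song = tone_burst(5000, amp=0.5, burst=(1.0, 2.0))
        rumble = sine(150, 3.0, amp=0.4).samples
        noise = rng.standard_normal(3 * RATE) * 0.01
        w = Waveform(song + rumble + noise, RATE)
        out = clean_segment(w, CleaningConfig())

        def band_energy(x, lo, hi):
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(len(x), 1 / RATE)
            return spec[(freqs >= lo) & (freqs <= hi)].sum()

        in_before = band_energy(w.samples, 4500, 5500)
        in_after = band_energy(out.samples, 4500, 5500)
        lo_before = band_energy(w.samples, 50, 400)
        lo_after = band_energy(out.samples, 50, 400)
        # normalization rescales everything; compare the in/out band *ratio*
        gain = in_after / in_before
        assert 10 * np.log10(lo_after / (lo_before * gain)) < -20

    def test_silence_raises_at_normalization(self):
        with pytest.raises(DegenerateInputError):
            clean_segment(Waveform(np.zeros(2 * RATE), RATE))

    def test_second_pass_changes_clean_burst_by_under_1db(self, rng):
        song = tone_burst(5000, amp=0.5)
        w = Waveform(song + rng.standard_normal(3 * RATE) * 1e-4, RATE)
        once = clean_segment(w)
        twice = clean_segment(once)
        assert abs(20 * np.log10(twice.rms() / once.rms())) < 1.0

    def test_gain_invariance_of_pipeline(self, rng):
        """highpass and normalization are linear: the output peak is pinned
        regardless of input gain."""
        song = tone_burst(5000, amp=0.3)
        w1 = Waveform(song + rng.standard_normal(3 * RATE) * 0.001, RATE)
        w2 = Waveform(w1.samples * 5.0, RATE)
        o1, o2 = clean_segment(w1), clean_segment(w2)
        assert np.max(np.abs(o1.samples - o2.samples)) < 1e-6
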