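import numpy as np
import pytest

from sitesep.audio import TimeInterval, Waveform
from sitesep.background import (
    loudness_profile,
    mask_positive_segments,
    top_loudest,
)

from conftest import RATE


class TestMaskPositiveSegments:
    def test_no_positives_keeps_everything(self, noise_wave):
        pieces = mask_positive_segments(noise_wave, [])
        assert len(pieces) == 1
        assert pieces[0].offset_s == 0.0
        assert np.array_equal(pieces[0].audio.samples, noise_wave.samples)

    def test_interval_complement(self):
        w = Waveform(np.arange(10 * RATE, dtype=float), RATE)
        pieces = mask_positive_segments(w, [TimeInterval(2, 4)])
        assert [p.offset_s for p in pieces] == [0.0, 4.0]
        assert len(pieces[0].audio) == 2 * RATE
        assert len(pieces[1].audio) == 6 * RATE
        assert pieces[1].audio.samples[0] == 4 * RATE

    def test_full_cover_yields_empty(self, noise_wave):
        assert mask_positive_segments(noise_wave, [TimeInterval(0, 10)]) == []

    def test_overlapping_positives_merged(self):
        w = Waveform(np.ones(10 * RATE), RATE)
        pieces = mask_positive_segments(w, [TimeInterval(1, 4), TimeInterval(3, 6)])
        assert [p.offset_s for p in pieces] == [0.0, 6.0]


class TestLoudnessProfile:
    def test_zero_audio_zero_metric(self):
        p = loudness_profile(Waveform(np.zeros(2 * RATE), RATE))
        assert np.all(p.metric == 0)

    def test_unit_impulse_support_is_two_windows(self):
        """Rolling-sum support (1 window) dilated by rolling-max (1 window)
        gives a plateau of ~2 windows centered on the impulse."""
        rate = 100
        x = np.zeros(10 * rate)
        x[5 * rate] = 1.0
        p = loudness_profile(Waveform(x, rate), window_s=1.0)
        support = np.flatnonzero(p.metric >= 0.999)
        width_s = (support[-1] - support[0] + 1) / rate
        assert width_s == pytest.approx(2.0, abs=0.05)
        center_s = (support[-1] + support[0]) / 2 / rate
        assert center_s == pytest.approx(5.0, abs=0.05)
        assert np.all(p.metric[: 3 * rate] == 0)

    def test_constant_input_closed_form(self):
        rate = 100
        c = 0.25
        p = loudness_profile(Waveform(np.full(10 * rate, c), rate), window_s=1.0)
        mid = p.metric[3 * rate : 7 * rate]
        assert np.allclose(mid, c * rate, rtol=1e-6)

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError):
            loudness_profile(Waveform(np.zeros(0), RATE))


def brute_force_top(metric, rate, total_s, min_piece_s):
    """Reference: greedily add samples in (-metric, index) order, merge runs,
    drop short runs, continue until the duration target is met."""
    n = len(metric)
    target = int(round(total_s * rate))
    min_run = int(round(min_piece_s * rate))
    order = sorted(range(n), key=lambda i: (-metric[i], i))
    selected = np.zeros(n, dtype=bool)
    pos = 0
    kept = 0
    for _ in range(50):
        need = target - kept
        if need <= 0:
            break
        taken = 0
        while pos < n and taken < need:
            i = order[pos]
            pos += 1
            if not selected[i]:
                selected[i] = True
                taken += 1
        if taken == 0:
            break
        # merge + drop short runs
        runs = []
        i = 0
        while i < n:
            if selected[i]:
                j = i
                while j < n and selected[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        kept = 0
        for a, b in runs:
            if b - a < min_run:
                selected[a:b] = False
            else:
                kept += b - a
    runs = []
    i = 0
    while i < n:
        if selected[i]:
            j = i
            while j < n and selected[j]:
                j += 1
            if j - i >= min_run:
                runs.append((i / rate, j / rate))
            i = j
        else:
            i += 1
    return runs


class TestTopLoudest:
    def test_single_burst_selected(self):
        rate = 1000
        x = np.zeros(60 * rate)
        x[20 * rate : 30 * rate] = 0.5  # 10-s loud burst
        w = Waveform(x, rate)
        profile = loudness_profile(w, window_s=1.0)
        ivs = top_loudest(w, profile, total_s=10.0, min_piece_s=2.0)
        assert len(ivs) == 1
        # selection covers the burst (within the 1-s metric dilation)
        assert ivs[0].start_s == pytest.approx(20.0, abs=1.5)
        assert ivs[0].end_s == pytest.approx(30.0, abs=1.5)

    def test_uniform_audio_takes_earliest(self):
        rate = 1000
        w = Waveform(np.full(30 * rate, 0.1), rate)
        profile = loudness_profile(w, window_s=1.0)
        ivs = top_loudest(w, profile, total_s=5.0, min_piece_s=2.0)
        assert ivs[0].start_s == pytest.approx(0.0, abs=1.0)

    def test_matches_reference_enumeration_on_toy_hours(self, rng):
        """Greedy-by-metric selection matches an independent restatement."""
        rate = 200
        for trial in range(5):
            x = rng.standard_normal(30 * rate) * 0.01
            for _ in range(3):  # loud events
                t0 = int(rng.integers(0, 25 * rate))
                x[t0 : t0 + 3 * rate] += rng.uniform(0.2, 1.0)
            w = Waveform(np.abs(x), rate)
            profile = loudness_profile(w, window_s=1.0)
            got = top_loudest(w, profile, total_s=8.0, min_piece_s=2.0)
            ref = brute_force_top(profile.metric, rate, 8.0, 2.0)
            got_flat = [v for iv in got for v in (iv.start_s, iv.end_s)]
            ref_flat = [v for r in ref for v in r]
            assert got_flat == pytest.approx(ref_flat)

    def test_no_piece_shorter_than_two_seconds(self, rng):
        rate = 200
        x = np.abs(rng.standard_normal(40 * rate)) * 0.1
        w = Waveform(x, rate)
        profile = loudness_profile(w, window_s=1.0)
        ivs = top_loudest(w, profile, total_s=10.0, min_piece_s=2.0)
        assert all(iv.duration_s >= 2.0 - 1e-9 for iv in ivs)

    def test_total_duration_near_target(self, rng):
        rate = 200
        x = np.abs(rng.standard_normal(40 * rate)) * 0.1
        x[10 * rate : 20 * rate] += 0.5
        w = Waveform(x, rate)
        profile = loudness_profile(w, window_s=1.0)
        ivs = top_loudest(w, profile, total_s=10.0, min_piece_s=2.0)
        total = sum(iv.duration_s for iv in ivs)
        assert abs(total - 10.0) <= 1.0 + 1e-9  # within one metric window

    def test_oversized_request_returns_whole_recording(self, noise_wave):
        profile = loudness_profile(noise_wave, window_s=1.0)
        with pytest.warns(UserWarning):
            ivs = top_loudest(noise_wave, profile, total_s=1000.0)
        assert len(ivs) == 1
        assert ivs[0].duration_s == pytest.approx(noise_wave.duration_s)
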