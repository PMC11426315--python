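import numpy as np
import pytest

from sitesep.audio import Waveform
from sitesep.metrics import (
    best_threshold_accuracy,
    bss_eval,
    mape,
    normal_ci90,
    si_sdr,
    xcorr_lag,
)

RATE = 22_050


def wf(x):
    return Waveform(np.asarray(x, dtype=float), RATE)


def gram_schmidt_oracle(estimate, references, target_index):
    """Independent brute-force projection decomposition.

    Orthonormalizes the references by explicit Gram-Schmidt and projects
    the estimate with inner products — no shared code with the library
    implementation (which solves a least-squares system).
    """
    e = np.asarray(estimate, dtype=float)
    refs = [np.asarray(r, dtype=float) for r in references]
    t = refs[target_index]
    s_target = (e @ t) / (t @ t) * t
    basis = []
    for r in refs:
        v = r.copy()
        for b in basis:
            v = v - (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            basis.append(v / norm)
    p_all = np.zeros_like(e)
    for b in basis:
        p_all += (e @ b) * b
    e_interf = p_all - s_target
    e_artif = e - p_all

    def db(num, den):
        return np.inf if den <= 0 else 10 * np.log10(num / den)

    sdr = db(s_target @ s_target, (e_interf + e_artif) @ (e_interf + e_artif))
    sir = db(s_target @ s_target, e_interf @ e_interf)
    sar = db((s_target + e_interf) @ (s_target + e_interf), e_artif @ e_artif)
    return sdr, sir, sar


class TestBssEval:
    def test_perfect_estimate_is_infinite(self, rng):
        t = rng.standard_normal(1000)
        r2 = rng.standard_normal(1000)
        m = bss_eval(wf(t), [wf(t), wf(r2)], 0)
        assert m.sdr_db == np.inf and m.sir_db == np.inf and m.sar_db == np.inf
        capped = m.capped()
        assert capped.sdr_db == 300.0

    def test_orthogonal_interferer_closed_form(self, rng):
        t = rng.standard_normal(1000)
        i = rng.standard_normal(1000)
        i -= (i @ t) / (t @ t) * t  # orthogonalize
        a, b = 2.0, 0.5
        m = bss_eval(wf(a * t + b * i), [wf(t), wf(i)], 0)
        expected_sir = 10 * np.log10((a**2 * (t @ t)) / (b**2 * (i @ i)))
        assert m.sir_db == pytest.approx(expected_sir, abs=1e-9)
        assert m.sar_db == np.inf  # estimate lies in span(references)

    def test_noise_at_minus_20db_gives_sdr_near_20(self, rng):
        t = rng.standard_normal(22050)
        noise_ref = rng.standard_normal(22050)
        noise = rng.standard_normal(22050)
        noise *= np.linalg.norm(t) / np.linalg.norm(noise) / 10  # -20 dB
        m = bss_eval(wf(t + noise), [wf(t), wf(noise_ref)], 0)
        assert m.sdr_db == pytest.approx(20.0, abs=0.5)
        ora = gram_schmidt_oracle(t + noise, [t, noise_ref], 0)
        assert m.sdr_db == pytest.approx(ora[0], abs=1e-6)

    def test_agrees_with_gram_schmidt_oracle_on_random_signals(self, rng):
        """Gain-projection metrics match an independent brute-force
        decomposition within 1e-6 dB on random 1,000-sample cases."""
        for _ in range(100):
            t = rng.standard_normal(1000)
            r2 = rng.standard_normal(1000)
            e = rng.standard_normal(1000)
            m = bss_eval(wf(e), [wf(t), wf(r2)], 0)
            sdr, sir, sar = gram_schmidt_oracle(e, [t, r2], 0)
            assert m.sdr_db == pytest.approx(sdr, abs=1e-6)
            assert m.sir_db == pytest.approx(sir, abs=1e-6)
            assert m.sar_db == pytest.approx(sar, abs=1e-6)

    def test_decomposition_reconstructs_estimate(self, rng):
        """s_target + e_interf + e_artif == estimate by construction; verify
        through the oracle decomposition."""
        t = rng.standard_normal(500)
        r2 = rng.standard_normal(500)
        e = rng.standard_normal(500)
        s_t = (e @ t) / (t @ t) * t
        sdr, sir, sar = gram_schmidt_oracle(e, [t, r2], 0)
        assert np.isfinite(sdr) and np.isfinite(sir) and np.isfinite(sar)

    def test_zero_target_rejected(self, rng):
        e = rng.standard_normal(100)
        with pytest.raises(ValueError):
            bss_eval(wf(e), [wf(np.zeros(100)), wf(e)], 0)


class TestSiSdr:
    def test_scale_invariance(self, rng):
        r = rng.standard_normal(1000)
        assert si_sdr(wf(2 * r), wf(r)) == np.inf

    def test_equal_power_orthogonal_noise_is_zero_db(self, rng):
        r = rng.standard_normal(1000)
        n = rng.standard_normal(1000)
        n -= (n @ r) / (r @ r) * r
        n *= np.linalg.norm(r) / np.linalg.norm(n)
        assert si_sdr(wf(r + n), wf(r)) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_noise_level(self, rng):
        r = rng.standard_normal(1000)
        n = rng.standard_normal(1000)
        vals = [si_sdr(wf(r + eps * n), wf(r)) for eps in (0.1, 0.01, 0.001)]
        assert vals[0] < vals[1] < vals[2]


class TestMape:
    def test_exact_is_zero(self):
        assert mape([1, 2, 3], [1, 2, 3]) == 0.0

    def test_fifty_percent(self):
        assert mape([150], [100]) == pytest.approx(50.0)

    def test_hand_computed_mean(self):
        assert mape([11, 18], [10, 20]) == pytest.approx(10.0)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            mape([1.0], [0.0])

    def test_scale_invariance(self):
        assert mape([11, 18], [10, 20]) == pytest.approx(mape([110, 180], [100, 200]))


class TestXcorrLag:
    def test_self_lag_zero(self, rng):
        a = wf(rng.standard_normal(1000))
        assert xcorr_lag(a, a) == 0.0

    def test_100_sample_delay(self, rng):
        x = rng.standard_normal(5000)
        a = wf(x)
        b = wf(np.concatenate([np.zeros(100), x[:-100]]))
        assert xcorr_lag(a, b) == pytest.approx(100 / RATE)
        assert xcorr_lag(a, b) == pytest.approx(4.535e-3, abs=1e-5)

    def test_sample_period_resolution_floor(self):
        assert 1 / RATE * 1e6 == pytest.approx(45.35, abs=0.02)

    def test_all_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            xcorr_lag(wf(np.zeros(100)), wf(rng.standard_normal(100)))


class TestBestThresholdAccuracy:
    def test_separable_scores_perfect(self):
        thr, acc = best_threshold_accuracy([0.9, 0.8], [0.1, 0.2])
        assert acc == 1.0
        assert 0.2 < thr < 0.8

    def test_partially_overlapping_brute_force(self):
        _, acc = best_threshold_accuracy([0.6, 0.4], [0.5, 0.3])
        assert acc == 0.75

    def test_identical_point_masses_give_half(self):
        _, acc = best_threshold_accuracy([0.5], [0.5])
        assert acc == 0.5

    def test_matches_exhaustive_sweep(self, rng):
        pos = rng.uniform(0.3, 1.0, 25)
        neg = rng.uniform(0.0, 0.7, 25)
        thr, acc = best_threshold_accuracy(pos, neg)
        # exhaustive check over a fine grid
        grid = np.linspace(-0.1, 1.1, 2000)
        accs = [
            (np.sum(pos > g) + np.sum(neg <= g)) / 50 for g in grid
        ]
        assert acc == pytest.approx(max(accs))


class TestNormalCi90:
    def test_known_half_width(self):
        x = [1.0, 2.0, 3.0, 4.0]
        mean, half = normal_ci90(x)
        assert mean == 2.5
        assert half == pytest.approx(1.6449 * np.std(x, ddof=1) / 2, abs=1e-3)
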