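"""Evaluation mathematics.

BSS-eval style SDR/SIR/SAR with gain-only (time-invariant scalar)
projections: the estimate is decomposed into a target component (its
orthogonal projection onto the true source), an interference component
(the remainder of its projection onto the span of all references) and
an artifact residual.  The classical 512-tap filter-allowed variant is
deliberately out of scope; the scalar-projection family matches the
pairwise-SDR objective used to train time-domain separators.

Also here: scale-invariant SDR, mean absolute percentage error,
integer-sample cross-correlation lag (the timing-preservation measure —
one sample period at 22,050 Hz is ~45.35 us, the resolution floor), and
the ideal-threshold classification accuracy sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate

from .audio import Waveform

#: Serialization cap for metrics that are exactly +infinity.
METRIC_CAP_DB = 300.0


@dataclass(frozen=True)
class BssMetrics:
    sdr_db: float
    sir_db: float
    sar_db: float

    def capped(self) -> "BssMetrics":
        c = lambda v: min(v, METRIC_CAP_DB)
        return BssMetrics(c(self.sdr_db), c(self.sir_db), c(self.sar_db))


def _ratio_db(num: float, den: float) -> float:
    # denominators below 240 dB under the numerator are numerical residue
    # of the projections (e.g. a perfect estimate); report the distinguished
    # infinity rather than a float-noise-determined large number
    if den <= num * 1e-24:
        return np.inf
    return float(10.0 * np.log10(num / den))


def bss_eval(estimate: Waveform, references: list[Waveform], target_index: int) -> BssMetrics:
    """Gain-projection SDR/SIR/SAR of an estimate against reference sources.

    ``s_target`` is the orthogonal projection of the estimate onto the
    target reference; ``e_interf`` the rest of its projection onto the
    span of all references; ``e_artif`` the residual outside that span.
    """
    e = estimate.samples
    R = np.stack([r.samples for r in references])
    if R.shape[1] != len(e):
        raise ValueError("estimate and references must have equal length")
    t = R[target_index]
    t_energy = float(t @ t)
    if t_energy == 0.0:
        raise ValueError("target reference has zero energy")
    s_target = (float(e @ t) / t_energy) * t
    # least-squares projection onto span of all references
    coef, *_ = np.linalg.lstsq(R.T, e, rcond=None)
    p_all = R.T @ coef
    e_interf = p_all - s_target
    e_artif = e - p_all
    sdr = _ratio_db(float(s_target @ s_target), float((e_interf + e_artif) @ (e_interf + e_artif)))
    sir = _ratio_db(float(s_target @ s_target), float(e_interf @ e_interf))
    st_i = s_target + e_interf
    sar = _ratio_db(float(st_i @ st_i), float(e_artif @ e_artif))
    return BssMetrics(sdr_db=sdr, sir_db=sir, sar_db=sar)


def si_sdr(estimate: Waveform, reference: Waveform) -> float:
    """Scale-invariant SDR in dB."""
    e, r = estimate.samples, reference.samples
    if len(e) != len(r):
        raise ValueError("estimate and reference must have equal length")
    r_energy = float(r @ r)
    if r_energy == 0.0:
        raise ValueError("reference has zero energy")
    proj = (float(e @ r) / r_energy) * r
    noise = e - proj
    return _ratio_db(float(proj @ proj), float(noise @ noise))


def mape(estimates, truths) -> float:
    """Mean absolute percentage error, in percent."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have equal length")
    if np.any(tru == 0.0):
        raise ValueError("mape undefined when a truth entry is zero")
    return float(np.mean(100.0 * np.abs(est - tru) / np.abs(tru)))


def xcorr_lag(a: Waveform, b: Waveform) -> float:
    """Lag (seconds) maximizing cross-correlation; positive = b delayed vs a.

    Integer-sample resolution — no sub-sample interpolation — so the
    best achievable alignment is one sample period.
    """
    if a.rate != b.rate:
        raise ValueError("xcorr_lag requires equal sampling rates")
    if not np.any(a.samples) or not np.any(b.samples):
        raise ValueError("xcorr_lag undefined for all-zero input")
    c = correlate(b.samples, a.samples, mode="full", method="fft")
    lag_samples = int(np.argmax(c)) - (len(a.samples) - 1)
    return lag_samples / a.rate


def best_threshold_accuracy(pos_scores, neg_scores) -> tuple[float, float]:
    """Ideal-threshold classification accuracy.

    Sweeps midpoints of sorted unique scores (plus outer sentinels) and
    returns the (threshold, accuracy) maximizing (TP+TN)/(P+N); ties go
    to the lowest threshold.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be nonempty")
    uniq = np.unique(np.concatenate([pos, neg]))
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best_thr, best_acc = cands[0], -1.0
    total = len(pos) + len(neg)
    for thr in cands:
        acc = (np.sum(pos > thr) + np.sum(neg <= thr)) / total
        if acc > best_acc:
            best_acc, best_thr = float(acc), float(thr)
    return best_thr, best_acc


def normal_ci90(values) -> tuple[float, float]:
    """(mean, 90% normal-approximation half-width) of a sample."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        return np.nan, np.nan
    if len(x) == 1:
        return float(x[0]), 0.0
    half = 1.6448536269514722 * x.std(ddof=1) / np.sqrt(len(x))
    return float(x.mean()), float(half)
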