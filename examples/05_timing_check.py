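"""Timing preservation through chunked separation.

Trilateration needs sample-accurate timing: a shift of even a few
milliseconds in the separated song would translate to meters of
localization error.  This runs 100 seeded mixtures through chunked
oracle-mask separation and reports the worst cross-correlation lag
between each clean song and its estimate.  One sample period at
22,050 Hz (~45.35 us) is the resolution floor of the integer-lag
measure, so a maximum at or below that value means no detectable shift.
"""

from sitesep.workflow import timing_study

result = timing_study(n_trials=100, seed=0)
print(f"trials                 : {len(result.lags_s)}")
print(f"max |misalignment|     : {result.max_abs_lag_us:.3f} us")
print(f"one sample period      : {result.sample_period_us:.3f} us")
print(f"trials with zero lag   : {(result.lags_s == 0).sum()} / {len(result.lags_s)}")
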