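"""Simulated three-microphone trilateration, with and without separation.

Microphones sit 1.5 m above ground at the origin, 10 m north and 10 m
east.  Each trial places a bird within 10 m of a microphone, renders
its song through forest impulse responses, layers identical background
audio on every channel at a song-background ratio of 0.05, estimates
time differences of arrival by cross-correlation and solves the TDOA
system.  Identical background on all channels destroys the delay
structure, so the no-separation baseline collapses; oracle-mask
separation restores meter-level accuracy.
"""

from sitesep.synth import BackgroundSpec, SongSpec, synth_background, synth_song
from sitesep.trilat import run_trials

RATE = 22_050


def song_factory(rng):
    return synth_song(SongSpec(seed=int(rng.integers(2**31))), RATE)


def bg_factory(rng):
    return synth_background(
        BackgroundSpec(duration_s=2.5, lowpass_hz=1500.0,
                       transient_rate_per_min=0.0,
                       seed=int(rng.integers(2**31))), RATE)


_, before = run_trials(40, song_factory, bg_factory, ratio_grid=(0.05,),
                       separate=False, seed=8)
_, after = run_trials(40, song_factory, bg_factory, ratio_grid=(0.05,),
                      separate=True, seed=8)

print("before separation (identity):")
print(before.to_string(index=False))
print("\nafter oracle-mask separation:")
print(after.to_string(index=False))
print("\nmean_error_m is the mean distance between true and estimated bird")
print("positions; pct_within_1m counts trials localized to within a meter")
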