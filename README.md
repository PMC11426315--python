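# sitesep

Site-specific birdsong source separation needs training data that does not
exist: passively recorded field audio never contains the clean song and the
clean background separately. `sitesep` builds such data semiautomatically
from raw recordings — and evaluates separators the way bioacousticians
actually use them — for the Golden-cheeked Warbler (*Setophaga chrysoparia*)
style of monitoring problem, where a target species must be isolated from
road noise, weather and competing species at a specific recording site.

The package covers both halves of that workflow:

**Dataset construction.** Per-window detector scores (e.g. from an external
species classifier run with a 3-s window advanced by 1 s) are ranked by the
joint probability `p_target · Π(1 − p_other)` of a window containing the
target and nothing else; top windows are extracted with 1.5-s buffers
(6-s clips), cleaned by zero-phase high-pass Butterworth filtering, peak
normalization to −1 dBFS and stationary spectral gating, and screened by
birdsong-background ratio (clips more than 10 dB under the background are
dropped). Background banks are mined from the remaining audio by condensing
each stretch to its loudest spans under a rolling-sum/rolling-max loudness
metric. A mixture generator then stitches backgrounds, layers songs with
random time-stretch (±20%), gain (0.15–1.2×) and pitch shift, and emits
`(mixture, song stem, background stem)` triples whose stems sum to the
mixture *exactly* and whose song-background RMS ratio can be pinned to any
target (the evaluation grid is 0.01 … 2).

**Evaluation.** A separator is any callable `mixture → (song, background)`
estimate; an ideal-ratio-mask oracle built from the true stems stands in
for a trained network, and the identity map is the "no separation"
baseline. Long audio is processed in 3-s chunks with 1-s overlap and
0.5-s crossfade merges whose weights sum to one at every sample. Quality is
measured by gain-projection BSS metrics,

    SDR = 10·log10(‖s_target‖² / ‖e_interf + e_artif‖²)
    SIR = 10·log10(‖s_target‖² / ‖e_interf‖²)
    SAR = 10·log10(‖s_target + e_interf‖² / ‖e_artif‖²)

and by three downstream tasks: automated min/max frequency labeling
(energy-centered trim → log spectrogram → Canny edges), timing preservation
(integer-sample cross-correlation lag; one sample period at 22,050 Hz is
45.35 µs), and simulated three-microphone TDOA trilateration through
single-scatter forest impulse responses.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/04_trilateration.py` prints:

```
before separation (identity):
ratio  mean_error_m   ci90_m  pct_within_1m  n
 0.05      9.954051 0.938863            0.0 40

after oracle-mask separation:
ratio  mean_error_m   ci90_m  pct_within_1m  n
 0.05      3.450886 2.690237           75.0 40
```

With the background 20× louder than the song (ratio 0.05) and layered
identically on all three channels, cross-correlation timing collapses and
the unseparated baseline localizes birds with ~10 m mean error and none
within 1 m; after oracle-mask separation the mean error drops to ~3.5 m
with 75% of trials within 1 m. (The residual tail comes from the genuine
two-solution ambiguity of three-microphone TDOA inversion, not from
timing; see `docs/methods.md`.)

Similarly, `python examples/03_feature_labeling.py` shows band-edge
labeling on a buried song recovering the clean-song measurement exactly
after separation (0.0% error) versus 23% / 4.3% before, and
`python examples/05_timing_check.py` reports a maximum misalignment of
0.000 µs across 100 chunk-separated mixtures.

## Command line

A thin CLI wraps the library for field use:

```
sitesep make-fixtures --out fx --seed 1
sitesep build-dataset --fixtures fx --out ds --seed 2
sitesep separate --mixture ds/ex_000_mixture.wav --separator identity --out-prefix est
sitesep evaluate --out reports --seed 0
sitesep trilat-sim --trials 50 --ratio 0.05
sitesep timing-check --trials 100
```

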