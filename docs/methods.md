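# Methods

This note records the models, parameter choices and known limitations
behind `sitesep`, in the order the pipeline runs.

## Audio model

All processing is mono at a canonical 22,050 Hz; files are resampled on
ingest (polyphase, band-limited). Samples are floats in [−1, 1]; PCM16
input is scaled by 1/32768. Time intervals are half-open `[start, end)`
and indexing is 0-based. Multichannel input is averaged to mono: the
recorders being emulated are single-channel, and trilateration treats
each microphone as its own waveform.

## Selection

Detector scores arrive per (window, class) with 3-s windows advanced by
1 s. The joint score `p_target · Π(1 − p_other)` assumes class
independence — the simplest model consistent with "contains the target
and nothing else". Overlapping high-scoring windows of one song are
deduplicated by greedy suppression: walking the ranked list, a window is
dropped if an accepted window of the same recording starts within
`min_gap_s` (default 3 s, one window length). Ties in score resolve to
the earlier start, then lexicographic recording id, making selection
deterministic. Extraction pads 1.5 s on each side (a 3-s window becomes
a 6-s clip), zero-filling at recording edges so clip length is exact.

## Cleaning

Order: high-pass → peak normalize → spectral gate.

* **High-pass**: Butterworth order 5, cutoff 2 kHz (below the warbler
  band, above rumble/road noise), applied forward-backward for zero
  phase — the cutoff therefore sits at −6 dB rather than −3 dB.
* **Normalization**: pure gain to a −1 dBFS peak.
* **Spectral gate**: STFT with a 1024-sample Hann window, hop 256. The
  per-frequency noise floor is the mean magnitude of the quietest 10% of
  frames (by frame energy), or of a supplied noise sample. Detection
  compares magnitudes smoothed over 7 bins × 9 frames against
  floor + 6 dB; bins below are attenuated by 30 dB, and the resulting
  mask is smoothed 3 × 3 before application. The large detection
  neighbourhood matters: per-bin Rayleigh fluctuation of stationary
  noise crosses a 6-dB threshold in ~2% of bins, which would leak
  audible noise islands through the gate; averaging ~60 bins makes the
  crossing probability negligible while genuine signal ridges (which are
  locally coherent) stay above threshold.
* **Semantics**: the gate's floor is estimated from the signal itself,
  so anything stationary — including a tone present in every frame — is
  treated as noise by construction. The gate's contract is transient
  song over stationary background.
* **Screening**: the birdsong-background ratio is the in-band mean power
  of the song span over that of its time complement, in dB; clips below
  −10 dB are flagged for removal. The song span and band come from
  synthesis metadata or detection, since the package has no manual
  vetting step.

## Background mining

The loudness metric is a centered 1-s rolling sum of |x| followed by a
centered 1-s rolling max (both edge-truncated). Selection is greedy by
metric (ties to earlier time), merged into runs, with runs shorter than
2 s discarded and selection refilled until the requested total (default
300 s per hour) is met. The union-of-fragments reading (rather than one
contiguous span) follows from the rolling-max construction, whose whole
point is to prevent fragmentation below ~2 s while allowing multiple
separate loud events to be kept.

## Synthetic fixtures

The song generator is schematic, not a vocal-tract model: A songs are
`n_repeats` downward FM elements (1.10→0.85 × peak frequency), a buzz
(70-Hz AM on a carrier at the peak frequency, depth 0.55), and an
optional rising hook to 1.25 × peak; B songs are an initial buzz at
0.90 × peak, a short note, a main buzz and an optional flourish to
1.30 × peak. Sweeps hold their terminal frequency for 30% of their
duration under a light Tukey taper, so the extreme frequencies exist as
real spectrogram ridges and the generator's band-edge metadata
(min/max instantaneous frequency, AM sidebands included) is measurable
ground truth. Defaults (peak 5 kHz, elements 0.18 s, buzz 0.3–0.7 s)
sit in the species' band; amplitudes are peak-normalized to the spec.

Backgrounds are colored noise (power ∝ 1/f^α, default α = 1), optional
tonal interferers, low-pass rumble and Poisson-scheduled broadband
transients — emulating road noise and non-target activity. An optional
`lowpass_hz` band limit produces the band-disjoint fixtures used by the
separation-helps experiments. What the fixtures do **not** emulate:
reverberation in recorded clips, species-realistic syntax, nonstationary
weather noise, or detector errors correlated with signal content.
Passing tests therefore demonstrate the pipeline's mechanics and
internal consistency, not field performance of any particular separator.

## Mixture generation

Backgrounds are stitched from randomly chosen bank pieces with 50-ms
amplitude-complementary (linear) crossfades — weights summing to one, so
constant inputs stay within their convex hull; an equal-power fade was
rejected because it breaks that conservation property on correlated
material. Songs are augmented per placement: phase-vocoder time-stretch
in [0.8, 1.2] (5-ms edge fades kill resynthesis truncation clicks),
pitch shift in ±1 semitone (stretch + polyphase resample), gain in
[0.15, 1.2]. Song count is Poisson at `songs_per_min`, with a
fixed-count mode for ratio experiments (e.g. 20 songs over 60 s);
placements are uniform and may overlap. The background attenuation
schedule (×0.1 with p=0.05, ×0.05 with p=0.05) is drawn once per
example and applied to the whole background stem, *before* the song
stem is rescaled to any target ratio — so the realized RMS ratio equals
the target to 1e-6. The mixture is literally `song_stem +
background_stem`; additivity is exact by construction. "Total volume"
is RMS throughout: with that convention the ratio equals the amplitude
scale factor, matching the intuition that ratios of 0.01–0.02 are
barely audible.

## Separation and chunking

The oracle ratio mask applies `|S|/(|S|+|B|+ε)` per source on a
1024/256 Hann STFT — the upper bound of mask-based separation given the
true stems, used wherever a trained model would plug in. Chunked
inference uses 3-s windows every 2 s, the last window right-aligned
(re-processing some audio rather than zero-padding the tail). Merging
fades each new chunk in linearly over 0.5 s centered in the overlap
with the outer margins taken from the earlier/later chunk; the weights
form an exact partition of unity, so an identity separator is
reproduced to float tolerance — which is also why chunking cannot
introduce timing shifts.

## Metrics

BSS metrics use gain-only (scalar) projections: `s_target` is the
projection of the estimate onto the true source, interference is the
remainder of its least-squares projection onto the span of all
references, artifacts the residual. The classical 512-tap
filter-allowed decomposition is deliberately out of scope; the scalar
family matches the pairwise-SDR objectives used to train time-domain
separators. Perfect reconstructions produce a distinguished +∞, capped
at 300 dB for serialization; denominators more than 240 dB below their
numerator are treated as projection round-off, not signal.
Cross-correlation lags are integer-sample (no sub-sample
interpolation): the 45.35-µs sample period at 22,050 Hz is the
resolution floor, and "timing preserved" means no measured lag exceeds
it. The ideal-threshold accuracy sweep evaluates midpoints of sorted
unique scores plus outer sentinels, ties to the lowest threshold.
Summaries report 90% normal-approximation confidence intervals.

## Frequency labeling

A clip is trimmed to 3 s centered on the argmax of a 0.5-s moving
average of squared samples (tie to the clip middle, crop clamped to
fit). A sliding average as long as the clip itself would be degenerate
— it has a single valid position — so the window length is a genuine
free parameter here; 0.5 s spans a song's loudest element group.
The log-magnitude spectrogram (1024/256, floor −80 dB) is normalized to
[0, 1]; frames whose analysis window overlaps the clip boundary are
dropped, since the boundary acts as a broadband transient and would
paint spurious vertical edges. Canny runs at σ = 2 with hysteresis
thresholds 0.1/0.3; the lowest and highest edge rows give the band
edges, after two corrections: rows below 500 Hz are ignored (residual
rumble guard, configurable), and both edges are pulled inward by
σ bins because the Gaussian pre-blur places a ridge boundary's gradient
maximum about σ bins outside the ridge. If the detector finds no edges
at all (smooth noise-dominated input), the power-based support — rows
whose peak image value clears the high threshold — is used instead, so
the "before separation" arm of a study still yields a (badly wrong)
number rather than an error, as a power-threshold labeler would.

## Trilateration

Three microphones 1.5 m above ground: origin, 10 m north, 10 m east;
speed of sound 343 m/s. The forest impulse response is a single-scatter
model: a direct tap at `d/c` with amplitude `1/max(d, 1 m)`, plus up to
512 echo taps routed via uniformly placed trees, each delayed by its
two-leg path and attenuated by both legs and a scattering loss (0.3).
The direct tap is always first — echoes travel farther. The background
is added identically (not convolved) to every channel: interference
with no usable delay structure, the worst case for correlation timing.
Birds and solutions are confined to the microphone plane; three
microphones cannot resolve height.

TDOAs are integer-sample cross-correlation lags against channel 0.
Inversion solves `‖p−m_j‖ − ‖p−m_0‖ = c·τ_j` by coarse grid search
(±50 m, 0.5-m step) followed by Levenberg–Marquardt refinement of every
well-separated low-cost basin. With three microphones the two
hyperbolas can genuinely intersect twice; exact ties are broken toward
the array centroid (a near-field prior: the array monitors its own
neighborhood). Inside the array's bounding box, at least 2.5 m from
every sensor, inversion is unique and exact to numerical precision;
near a sensor the hyperbolas become tangent and outside the array a
mirror ghost can win, which is what produces the heavy error tail in
the Monte-Carlo studies (trial positions there follow the
within-10-m-of-a-mic protocol, ghosts included). Failed refinements
fall back to the grid minimum and are flagged, never dropped.

## Problem sizes

Default study sizes are chosen for a laptop-class single core: the
timing study runs 1,000 six-second mixtures; separation-helps
comparisons use 100 trials/examples per arm; evaluation-battery sweeps
default to a handful of examples per condition and are arguments, not
constants. All randomness flows from one master seed through
SHA-256-derived per-stage seeds, so every artifact is bit-reproducible.

## Known limitations

* The oracle mask bounds achievable separation; no trained model ships
  here, and nothing in the fixtures measures how close a real network
  would get to the bound.
* Band-edge labeling assumes one song dominates the crop; simultaneous
  songs of different bands yield the union support.
* The single-scatter forest model has no occlusion, ground reflection,
  air absorption or frequency-dependent scattering.
* The spectral gate assumes stationary noise; nonstationary interference
  (another bird) passes through and must be handled by separation.
* Three-microphone TDOA ambiguity is inherent; a fourth microphone, not
  a better solver, is the fix.
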