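"""Condense a recording to its loudest spans.

Site background banks keep only the interesting interference (passing
cars, other species, voices) rather than hours of near-silence.  The
loudness metric is a 1-s rolling sum of |x| followed by a 1-s rolling
maximum; the top spans by that metric are extracted as pieces of at
least 2 s.  Here a 60-s synthetic 'hour' with three loud events is
condensed to its loudest 10 s.
"""

import numpy as np

from sitesep import Waveform
from sitesep.background import loudness_profile, top_loudest

RATE = 22_050
rng = np.random.default_rng(4)

x = rng.standard_normal(60 * RATE) * 0.01  # quiet bed
events = [(12.0, 4.0), (31.0, 3.0), (47.0, 5.0)]
for t0, dur in events:
    i0 = int(t0 * RATE)
    n = int(dur * RATE)
    x[i0 : i0 + n] += rng.standard_normal(n) * 0.3

w = Waveform(np.clip(x, -1, 1), RATE)
profile = loudness_profile(w, window_s=1.0)
spans = top_loudest(w, profile, total_s=10.0, min_piece_s=2.0)

print("planted events:   " + ", ".join(f"[{t0:.0f}, {t0 + d:.0f}] s" for t0, d in events))
print("extracted spans:  " + ", ".join(f"[{iv.start_s:.1f}, {iv.end_s:.1f}] s" for iv in spans))
total = sum(iv.duration_s for iv in spans)
print(f"total extracted:  {total:.1f} s (requested 10 s; every piece >= 2 s)")
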