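"""Measure peak frequency from audio and check measurement repeatability.

Builds synthetic tone recordings (a proxy for field recordings), measures
each one's peak frequency — the frequency with the highest cumulative
magnitude across spectrogram windows — and quantifies how repeatable three
noisy measurements per species are with the one-way-ANOVA intraclass
correlation.
"""

import numpy as np

import phyloacoustics as pa

rec = pa.make_tone_recording([2000.0, 3500.0], amps=[1.0, 0.4],
                             duration_s=1.0, noise_sd=0.1, seed=0)
print(f"peak frequency of 2 kHz + weaker 3.5 kHz mixture: "
      f"{pa.peak_frequency(rec):.0f} Hz "
      f"(bin width {44100 / 1024:.1f} Hz)")

rng = np.random.default_rng(4)
groups = {}
for i, f in enumerate(rng.uniform(1500, 6000, size=15)):
    groups[f"sp{i:02d}"] = [
        pa.peak_frequency(
            pa.make_tone_recording(f, duration_s=0.3, noise_sd=0.3,
                                   seed=50 * i + j))
        for j in range(3)
    ]
res = pa.repeatability(groups)
print(f"repeatability of 3 noisy measurements x 15 species: R = {res.r:.3f}")
print("\nR near 1 means species differences dwarf measurement noise, i.e."
      "\nthree recordings per species suffice to rank species reliably.")
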