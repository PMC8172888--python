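"""Estimate Pagel's-lambda phylogenetic signal, averaged over a tree sample.

Generates a small synthetic clade whose body mass evolves with strong
phylogenetic signal (lambda 0.9) and whose song duration is more labile
(lambda 0.45), then re-estimates both across a jittered pseudo-posterior of
trees with AIC weighting.
"""

import phyloacoustics as pa

study = pa.simulate_study(pa.SimulationConfig(n_tips=150, n_trees=10, seed=1))
table = pa.run_signal(
    study.traits, study.trees,
    ["body_mass", "song_duration", "forest_prop", "song_peak_freq"],
)
print(table[["lambda", "n", "n_trees"]].round(3))
print(
    "\nlambda near 1 means trait similarity tracks relatedness (Brownian-like"
    "\nevolution); values near 0 mean the phylogeny carries no information."
    "\nBody mass should sit near its planted 0.9, song duration near 0.45."
)
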