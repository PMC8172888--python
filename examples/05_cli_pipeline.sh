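#!/usr/bin/env bash
# The same analysis driven from the shell: simulate a study, estimate
# signal, fit the allometries, and measure repeatability from the
# measurement file. Outputs land in ./example_out/.
set -euo pipefail
mkdir -p example_out

phyloacoustics simulate --out example_out/study --seed 7 \
    --n-tips 120 --n-trees 5

phyloacoustics signal \
    --traits example_out/study_traits.csv \
    --trees example_out/study_trees.nwk \
    --out example_out/study

phyloacoustics pgls \
    --traits example_out/study_traits.csv \
    --trees example_out/study_trees.nwk \
    --out example_out/fit

phyloacoustics repeatability \
    --measurements example_out/study_measurements.csv --voc-class song
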