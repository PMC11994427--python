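#!/bin/sh
# End-to-end shell workflow: simulate -> analyze -> recovery.
set -e

thyrocap simulate --seed 42 --out cohort.csv --truth truth.csv
thyrocap analyze --input cohort.csv --out results/ --plots
cat results/stratum_table.txt
thyrocap recovery --table-medians --seed 7 --replicates 20 --out recovery.json
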