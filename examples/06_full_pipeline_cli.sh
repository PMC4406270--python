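#!/bin/sh
# End-to-end pipeline from one YAML config via the clinescan CLI.
# Writes Genepop + colony table, diversity/theta/IBD tables, the Delta-K
# table, coancestry coefficients, cline fits and the coincidence test
# into ./pipeline_out, with a checksum manifest that makes a second run
# a no-op.
set -e

cat > pipeline.yaml <<EOF
seed: 42
outdir: pipeline_out
simulate:
  n_colonies: 8
  n_per_colony: 20
  n_micro_loci: 8
fst:
  permutations: 200
ibd:
  randomizations: 1000
admixture:
  replicates: 3
  sweeps: 300
  burnin: 120
EOF

clinescan pipeline --config pipeline.yaml --verbose
echo "--- second run skips completed stages ---"
clinescan pipeline --config pipeline.yaml --verbose
ls pipeline_out
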