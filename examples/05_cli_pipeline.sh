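#!/bin/sh
# End-to-end shell pipeline: simulate a benchmark dataset, analyze it
# conditionally on the network, and compare against marginal testing.
set -e

OUT=$(mktemp -d)

condde simulate --scenario direct --shift 2 --seed 7 --out "$OUT/sim"

condde analyze \
    --network "$OUT/sim/network.tsv" \
    --expr "$OUT/sim/expression.tsv" \
    --pheno "$OUT/sim/phenotype.tsv" \
    --adjust holm --alpha 0.05 \
    --out "$OUT/results"

echo "--- significant genes (Holm-adjusted p < 0.05) ---"
grep -v '^#' "$OUT/results/significant_genes.txt"

condde compare \
    --network "$OUT/sim/network.tsv" \
    --expr "$OUT/sim/expression.tsv" \
    --pheno "$OUT/sim/phenotype.tsv" \
    --out "$OUT/compare"

echo "--- conditional vs marginal adjusted p-values ---"
grep -v '^#' "$OUT/compare/compare.tsv" | cut -f1,4,6
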