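#!/bin/sh
# The same pipeline from the shell: simulate a contaminated database,
# screen it, partition the variance and summarize coverage.
set -e

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

cat > "$workdir/config.yaml" <<EOF
n_sites: 6
n_taxa: 8
n_years: 40
sigma_noise: 4.0
outlier_rate: 0.01
bimodal_series_rate: 0.1
seed: 3
EOF

phenoscreen simulate --config "$workdir/config.yaml" --out "$workdir/db"
phenoscreen validate --db "$workdir/db" --out "$workdir/validated"
phenoscreen partition --db "$workdir/db" --out "$workdir/partition.csv" --min-records 200
phenoscreen summarize --db "$workdir/db" --out "$workdir/summary.csv"

echo "--- flagged records ---"
grep -c suspicious "$workdir/validated/phenology.csv" || true
echo "--- variance partition ---"
cat "$workdir/partition.csv"
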