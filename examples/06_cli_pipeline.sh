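#!/usr/bin/env bash
# End-to-end shell pipeline: simulate data, select genes, cross-validate,
# train, and classify — the same steps as the Python examples, via the CLI.
set -euo pipefail
tmp=$(mktemp -d)

srclatlrr simulate --n-genes 150 --n-per-class 12 --corrupt-frac 0.1 \
    --seed 0 --out-expression "$tmp/expr.tsv" --out-labels "$tmp/labels.tsv"

srclatlrr select-genes --expression "$tmp/expr.tsv" --labels "$tmp/labels.tsv" \
    -g 100 --out-scores "$tmp/scores.tsv" --out-expression "$tmp/top.tsv"

srclatlrr cv --expression "$tmp/expr.tsv" --labels "$tmp/labels.tsv" \
    --method src-latlrr --lambda-latlrr 0.1 --k-folds 6 --seed 0 \
    --out-report "$tmp/cv.json"

srclatlrr fit --expression "$tmp/expr.tsv" --labels "$tmp/labels.tsv" \
    --method src-latlrr --lambda-latlrr 0.1 --out-model "$tmp/model.npz"

srclatlrr predict --model "$tmp/model.npz" --expression "$tmp/expr.tsv" \
    --out "$tmp/predictions.tsv"

head -3 "$tmp/predictions.tsv"
rm -rf "$tmp"
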