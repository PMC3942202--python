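"""Trace classification accuracy and removed-noise level against the
noise penalty lambda.

Smaller lambda removes more noise (larger ||E||_1) but can also strip
useful signal; larger lambda removes too little.  The sweep reuses one
fold assignment so the curve isolates the effect of lambda — the same
two-axis picture used to pick lambda on real tumor datasets.
"""

from srclatlrr import (CVConfig, SubspaceSimConfig, generate_subspace_data,
                       lambda_sweep)

em, labels, _ = generate_subspace_data(SubspaceSimConfig(
    n_genes=150, n_per_class=15, corrupt_frac=0.10, seed=2))

table = lambda_sweep(em, labels, [0.01, 0.05, 0.1, 0.5, 1.0],
                     CVConfig(k_folds=5, seed=2))

print(f"{'lambda':>8} {'accuracy':>9} {'||E||_1':>9}")
for row in table.rows:
    print(f"{row['lambda_latlrr']:8.2f} {row['pooled_accuracy']:9.3f} "
          f"{row['mean_E_l1']:9.2f}")
best = max(table.rows, key=lambda r: r["pooled_accuracy"])
print(f"\nbest lambda on this data: {best['lambda_latlrr']} "
      f"(accuracy {best['pooled_accuracy']:.3f})")
print("||E||_1 is non-increasing in lambda; accuracy peaks at a moderate "
      "noise-removal level")
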