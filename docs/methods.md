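# Methods

## Model

An expression matrix `X ∈ R^{m×n}` (m genes, n samples, m ≫ n) with
unit-l2 columns is decomposed by latent low-rank representation:

    min_{Z,L,E}  ||Z||_* + ||L||_* + λ||E||_1   s.t.  X = XZ + LX + E

`XZ` (principal features) captures the self-representation of the
observed samples; `LX` (salient features) captures structure that an
unobserved, larger dictionary would explain — `L` acts as a gene-space
projector; `E` collects sparse gross noise.  As λ → ∞ the model reduces
to the noiseless case `X = XZ + LX` and `E` vanishes identically.  The
problem is convex but its minimizer is known not to be unique; this
package guarantees feasibility and objective quality, not a particular
(Z, L) pair.

Classification uses only `D = LX`.  A test profile `y` is normalized,
projected to `Ly`, sparse-coded by `min_x ||Dx − Ly||² + λ_src||x||₁`,
and assigned the class minimizing `r_i = ||Ly − D δ_i(x)||₂`.  The
intuition: columns of the same class span a low-dimensional subspace, so
the correct class's coefficients suffice to reconstruct `Ly`; denoising
the dictionary weakens spurious cross-class reconstructions.

## Solver

Inexact ALM on the equivalent constrained form with auxiliaries `J = Z`,
`S = L` and multipliers `Y1, Y2, Y3`.  Each iteration performs exact
block minimization in the order J, S, Z, L, E, then multiplier and
penalty updates:

    J ← svt(Z + Y2/μ, 1/μ)
    S ← svt(L + Y3/μ, 1/μ)
    Z ← (I + XᵀX)⁻¹ (Xᵀ(X − LX − E) + J + (XᵀY1 − Y2)/μ)
    L ← ((X − XZ − E)Xᵀ + S + (Y1Xᵀ − Y3)/μ)(I + XXᵀ)⁻¹
    E ← soft(X − XZ − LX + Y1/μ, λ/μ)
    Y1 += μ(X−XZ−LX−E);  Y2 += μ(Z−J);  Y3 += μ(L−S);  μ ← min(ρμ, μ_max)

`svt` shrinks singular values by τ (proximal operator of the nuclear
norm); `soft` is elementwise shrinkage (proximal operator of the l1
norm).  The skinny SVD underlying both applies a fixed sign convention
(largest-magnitude entry of each left singular vector made positive) so
all results are bit-reproducible.

**Tall-matrix factorization.**  With m in the thousands, the m×m blocks
L, S, Y3 are never dense during iteration.  From the economy SVD
`X = UΣVᵀ` (rank r ≤ n), every update preserves the form `G Uᵀ` with
`G ∈ R^{m×r}`: products with `Xᵀ = VΣUᵀ` land in that form, svt of
`G Uᵀ` reduces to the SVD of `G` (Uᵀ has orthonormal rows), and
right-multiplication by `(I + XXᵀ)⁻¹ = I − U diag(σ²/(1+σ²)) Uᵀ` becomes
a column rescaling of `G`.  Per-iteration cost is O(mnr); a 2000×100
problem solves in seconds.  The dense `L` is materialized once at
termination.

**Stopping.**  Convergence requires the maximum of the three constraint
gaps — `||X−XZ−LX−E||_∞`, `||Z−J||_∞` and the Frobenius bound
`||G_L−G_S||_F ≥ ||L−S||_∞` — to fall below `tol · max|X|`.  The third
term is a cheap upper bound, so the check is conservative; exact ∞-gaps
are recomputed once at termination and reported.  Non-convergence within
`max_iter` produces a warning and `converged=False`, not an exception,
so λ sweeps can proceed.

**Defaults** (exposed in `LatLRRParams`): μ0 = 1e-6, ρ = 1.1,
μ_max = 1e6, tol = 1e-6, max_iter = 1000 — conventional inexact-ALM
settings; the convexity of the problem makes the zero initialization a
matter of iteration count only.  Typical runs converge in 130–310
iterations.

## Sparse coding

`solve_l1ls` minimizes `||Wx − y||² + λ||x||₁` (squared data term, the
form the truncated-Newton interior-point literature defines) by FISTA
with step `1/(2σ_max(W)²)` and gradient-based adaptive restart.  The
contract is solver-independent: on return the gradient
`g = 2Wᵀ(Wx − y)` satisfies `|g_j| ≤ λ + tol` off the support and
`|g_j + λ sign(x_j)| ≤ tol` on it (checked every iteration; default
tol = 1e-6, max 5000 iterations — tight enough that classification
decisions do not depend on the backend).  λ_src defaults to 0.01; the
coding penalty is scale-stable because test samples are normalized
before projection.

## Classifier conventions

- Training columns are normalized inside `fit`; the recorded norms
  travel with the model.  Test samples are normalized too: `Ly` is
  compared against a dictionary built from unit-norm columns, and an
  unnormalized y would make λ_src scale-dependent.
- One decomposition is fitted on the pooled multi-class training matrix,
  not per class.
- `L` comes from the training fold only and is applied to test samples;
  no refitting with test data.
- Classes are ordered lexicographically; exact residual ties resolve to
  the smallest class in that order.
- Models persist to an `.npz` archive (keys: method, D, L, labels,
  gene_ids, column_norms, classes, latlrr_meta); reloaded models give
  bit-identical predictions.

## Gene selection

The BW score of gene j is the ratio of between-class to within-class
sums of squares over samples,
`Σ_i (m_{c(i),j} − m_j)² / (Σ_i (x_{ij} − m_{c(i),j})² + ε)` with
ε = 1e-12 guarding zero within-class scatter; a gene constant across all
samples scores 0.  Ranking is stable under ties.  In cross-validation
scores are computed on the training fold only (leakage-safe); a
`global_selection` flag reproduces whole-dataset selection for
comparison with studies that did not fold the filter.

## Evaluation

Stratified k-fold cross-validation (k = 10 by default, k at most the
smallest class size) with pooled accuracy — total correct over total
samples — as the headline number and per-fold accuracies retained.  The
λ sweep runs one cross-validation per λ on a shared fold assignment and
reports mean `||E||₁` across fold decompositions next to accuracy,
giving the two-axis accuracy/noise-level curve used to choose λ.

## Synthetic data

`generate_subspace_data` draws k class bases as QR factors of Gaussian
matrices (orthogonal across classes by default, via one shared QR),
Gaussian coefficients, optional dense Gaussian noise, and sparse ±c
spikes placed uniformly at random on a fixed fraction of entries.
Defaults — 3 classes, 4-dim subspaces, 300 genes, 30 samples/class,
spikes of magnitude 0.5 on 10% of entries when corruption is enabled —
are the study conditions used across the test suite: samples sizes and
class counts in the range of real tumor panels, subspace structure
matching the self-representation premise, and corruption matching the
sparse-E noise model.  What it does **not** emulate: probe/batch
effects, heavy-tailed intensity distributions, correlated gene blocks,
class imbalance, or count noise — so passing tests demonstrate the
method's mechanics under its own assumptions, not field performance on
real microarrays.  `generate_de_genes_data` plants class-specific mean
shifts (shift 2.0 over N(0,1) noise by default) in a random subset of
genes for testing the BW filter.

## Problem sizes

The test suite and acceptance script use 200×60 decomposition instances,
300-gene/90-sample classification datasets, and 2000-gene selection
instances — large enough to exercise the m ≫ n regime and the factored
solver path while keeping full runs to minutes.  λ for the corrupted
classification benchmark is tuned at run time over the fixed grid
{0.05, 0.1, 0.2}; the clean benchmark uses λ = 0.5 (any moderate-to-large
value behaves identically with no planted noise).

## Known limitations

- LatLRR's non-unique minimizer means (Z, L) can differ across BLAS
  builds even when the objective matches; only within-build bit
  reproducibility is guaranteed.
- The solver materializes the dense m×m projector L at the end; for
  m beyond ~20k genes, memory for L (not the iterations) becomes the
  constraint — pre-filter genes first.
- No missing-value support by design; impute upstream or drop genes.
- Residual-based decisions come uncalibrated: no posterior
  probabilities, no rejection option for out-of-library classes.
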