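# Methods

## Model

A pool of `n_i` diploid individuals carries `2*n_i` chromosomes. Genotyping
the pool yields, per diallelic locus, the relative frequency of the mutant
allele (encoded 1; the wild-type is 0), so the observation for pool `i` is a
vector `a_i` of length `L` whose entries lie on the grid `{k/(2*n_i)}`.
Writing the `M` candidate haplotypes as columns of the binary dictionary
`H (L x M)` and pool `i`'s haplotype proportions as `x_i` on the probability
simplex, complete noiseless data satisfy `a_i = H x_i`. Stacking pools,
`A = H X`, `X >= 0`, `1^T X = 1^T`.

Because `M >> L` the inverse problem is ill-posed. The maximum-parsimony
principle resolves it: the pools should be explained by as few *distinct*
haplotypes as possible, i.e. `X` should have as many all-zero rows as
possible, jointly across pools. The combinatorial row-l0 objective is relaxed
to its convex envelope, the sum of row-wise Euclidean norms (a group lasso in
which each haplotype is a group spanning all pools):

```
min_X  sum_j ||X[j,:]||_2
s.t.   H X = A,  1^T X = 1^T,  X >= 0.          (P-exact)
```

Two data-model variants replace the equality constraint:

- noisy calls: `sum_i ||a_i - H x_i||_2^2 <= delta` (P-ball), a single
  Frobenius-ball budget for the whole pool set;
- missing calls: per-pool reduced systems `H_i x_i = a~_i` (P-missing),
  where pool `i`'s masked loci are deleted from its own copy of `H` and of
  `a_i`. The missing pattern is assumed known a priori. The row-norm
  objective is untouched, so support sharing across differently masked pools
  is preserved.

## ADMM solver

All three problems are solved by the alternating direction method of
multipliers with the splitting `Z = X` (and additionally `Z2 = H X` for
P-ball), scaled dual variables `u = y / rho`, and zero initialization.

- **x-update.** Per pool: minimize
  `1/2 ||H x - (a - u2)||^2 + 1/2 ||x - (z - u1)||^2` subject to
  `1^T x = 1`. Stationarity gives `x = U4 (b - mu 1)` with
  `b = H^T (a - u2) + (z - u1)`, `U4 = (I + H^T H)^{-1}`, and the multiplier
  `mu = (1^T U4 b - 1) / (1^T U4 1)` enforcing the sum. By the Woodbury
  identity `U4 = I - H^T (I + H H^T)^{-1} H`, so only the `L x L` Gram
  system is Cholesky-factorized once; the `M x M` form (`M` can be `2^L`) is
  never materialized. For P-missing each distinct mask gets its own reduced
  projector, cached, and pools sharing a mask are updated as one batch.
- **z-update.** The exact proximal map of
  `(1/rho) * sum_j ||row_j||_2 + indicator(Z >= 0)`: clip `X + U1` to the
  nonnegative orthant, then apply row-wise group soft-thresholding
  (`Shrink(r, 1/rho) = max(||r||-1/rho, 0) * r/||r||`, zero rows map to
  zero). The reverse order (shrink, then clip) is not a proximal map; in
  experiments it produced rho-dependent converged-but-suboptimal fixed
  points on dictionaries with near-collinear columns, which is why the
  proximal order is used.
- **Z2-update (P-ball).** Euclidean projection of `H X + U2` onto
  `{Z : ||Z - A||_F^2 <= delta}` — the unique minimizer of the
  Z2-subproblem.
- **duals.** `U1 += X - Z`, `U2 += H X - A` (or `- Z2`; per-pool reduced
  blocks for P-missing).

The reported estimate is the sparse iterate `Z` (it carries nonnegativity
and the parsimony support; at convergence it coincides with `X`, and the
split residual `||X - Z||` is logged), post-processed by clipping negatives
and renormalizing each column, with ulp-level residue pushed into the
largest entry so column sums are exactly 1.

## Parameters

- `rho` (penalty): default `1/a-bar`, `a-bar` = mean observed allele-1
  frequency over non-missing cells — a data-driven scale that works well
  across the tested regimes. Degenerate all-zero data fall back to 1.
- `delta` (noise budget): default 0.1 for the noisy solver, a single scalar
  for the pool set, deliberately not tied to an assumed sigma (the noise
  variance is rarely known); callers may set it from sigma if they have one.
- `tol`, `max_iter`: iteration stops when the relative change
  `||X_k - X_{k-1}|| / ||X_{k-1}||` drops below `tol`, or at `max_iter`
  (default 8000). The default `tol = 1e-20` is below double-precision
  resolution, so runs are iteration-capped by design. Note the relative
  change is not monotone: it can dip near machine precision in the first few
  iterations before the duals ramp up, so a "practical" tol risks a spurious
  early stop — prefer `tol=0` with an explicit iteration budget.
- `support_threshold`: `1e-4` — a population frequency below the resolution
  `1/(2 * sum n_i)` of any realizable frequency in the targeted datasets is
  treated as absent (ligation survivor selection, reported haplotype lists).
- partition-ligation `W`: block width; `Q = ceil(L/W)` blocks of
  equal-as-possible width (earlier blocks take the extra locus). Adjacent
  blocks are paired (1,2), (3,4), ... per round, an odd trailing block is
  carried forward, and each merged dictionary is the Cartesian concatenation
  of the surviving haplotypes from the two sides, capped at 4096 columns by
  dropping lowest-frequency survivors (memory bound). The solver variant and
  config are reused per merged problem; `rho` is re-resolved from each
  sub-problem's own `a-bar` unless set explicitly.

## Aggregation and scoring

The population frequency of haplotype `j` is its share among all sampled
chromosomes: `f_j = sum_i 2 n_i X[j,i] / sum_i 2 n_i` (the plain column mean
for equal pool sizes). Estimates are compared to a gold standard `g` by the
chi-square distance `sum_{g_j != 0} (f_j - g_j)^2 / g_j` (asymmetric; mass
placed on zero-`g` haplotypes is not penalized by this criterion) and the l1
distance `sum_j |f_j - g_j|` (bounded by 2; twice the total variation).
Distributions estimated over different dictionaries are aligned by haplotype
string with zero filling.

## Synthetic data

The simulator emulates the pooled-genotyping pipeline:

- **sampling**: each individual draws two haplotypes i.i.d. from the
  population distribution, so a pool of `n` individuals is a multinomial
  draw of `2n` chromosomes; pool frequencies land exactly on the
  `1/(2n)` grid. The packaged AGT gene table (11 haplotypes over 10 SNPs,
  top frequency 0.507) is the standard worked example; a generic
  `random_distribution(D, L)` (uniform distinct haplotypes, symmetric
  Dirichlet frequencies) stands in for reference-panel haplotype blocks.
- **measurement error**: Gaussian noise with SD `sigma` (realistic range
  0–0.06) added per call, then snapped to the nearest allowed call
  `k/(2n)` with halfway ties rounding up and clipping at 0 and 1. A call
  flips when the noise exceeds half the grid spacing `1/(4n)`, so the
  miscall rate is about `2*Phi(-1/(4 n sigma))` — pooling errors hit larger
  pools harder, which is why small pools are the target regime.
- **missing calls**: a fixed fraction (1–2% in the experiments) of
  (locus, pool) cells masked uniformly at random without replacement.
- the AGT experiments use `n = 2` individuals per pool (the efficient-pooling
  regime; the pool size is exposed as a parameter).

What the simulator does *not* model: linkage-disequilibrium-structured
haplotype panels (draws are i.i.d. from a fixed distribution), locus- or
batch-dependent error rates, correlated missingness, and pool-construction
(pipetting) imbalance. Passing tests therefore demonstrate correctness of
the optimization and the stated statistical trends under the stated error
model, not performance on any particular real assay.

## Numerical choices and degenerate inputs

- Dual variables scaled (`u = y/rho`); initialization `X = Z = U = 0`.
- `(I + H H^T)` is symmetric positive definite for any binary `H`, so the
  Cholesky factorization always exists; a zero dictionary row block makes
  `U4` the identity.
- Exactly representable instances reach data residuals below `1e-6` well
  before the iteration cap; oracle-checked objectives agree with a generic
  convex solver (scipy trust-constr on the smoothed objective
  `sum_j sqrt(||row_j||^2 + eps^2)`, `eps = 1e-9`) to better than `1e-3`
  relative.
- A solution column collapsing to zero mass (pathological) falls back to
  the clipped x-iterate, then to uniform.
- Pools with every locus masked carry no information and are rejected.
- Frequencies within `1e-9` outside `[0,1]` (float round-off from exact
  arithmetic) are clipped on input; larger violations are errors.

## Known limitations

- The group-norm relaxation is not guaranteed to recover the generating
  haplotypes: for dictionaries containing near-collinear column sets (e.g.
  several haplotypes differing at one locus, or concatenation "recombinants"
  of true haplotypes), the minimizer can spread mass over neighbors of the
  true support. This is visible in the AGT experiments as mass on
  low-frequency neighbors, and shrinks with more pools.
- With the full dictionary, masking a locus always leaves a twin haplotype
  consistent with the reduced observations; unique recovery under missing
  data needs a restricted dictionary or other pools pinning the support.
- `delta` is a global budget: one very noisy pool can consume it.
- Partition-ligation inherits greediness: a true haplotype pruned in an
  early block cannot reappear later (mitigated by the low support
  threshold).

## Problem sizes used in the validation pipeline

The test suite and `scripts/acceptance.py` run the experiments at reduced
replicate counts chosen to keep the full pipeline in the minutes range on a
single CPU: oracle comparisons on 20 (tests) / 5 (script) random instances
per variant at `L=4, M=16, O=3`; exact recovery at `L=10, O=20`; the AGT
pool-count protocol with 20 (tests) / 8 (script) replicates at `O=50` and
`O=150`; the noise sweep with 10/5 replicates at `O=75`; missing-data runs
with 6/5 replicates at `O=50`; partition-ligation at `L=12, W=4, O=30`.
Solver runs in these experiments use `tol=0` with explicit iteration budgets
(4000–8000) verified to be in the converged regime for the respective
problem sizes.
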