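# Methods

This note records the models implemented by `qubofs`, the numerical
choices behind them, and their known limitations.  It states what the code
computes; empirical figures are produced by the test suite and
`scripts/acceptance.py`, not asserted here.

## Cost function

Feature selection is posed as minimization of a quadratic binary cost over
selection masks `x ∈ {0,1}^n`:

```
E(x) = -alpha * Σ_i I_i x_i + (1 - alpha) * Σ_{i,j} R_ij x_i x_j
```

* `I_i` — *importance*, the mutual information between feature `i` and the
  continuous target.
* `R_ij` — *redundancy*, the pairwise mutual information between features
  `i` and `j`, with `R_ii = 0` (a feature is never redundant with itself).
* `alpha ∈ [0,1]` trades importance (`alpha → 1`) against redundancy
  (`alpha → 0`).

The double redundancy sum runs over ordered pairs, so the symmetric
canonical matrix reproduces it directly: `Q_ii = -alpha·I_i`,
`Q_ij = (1-alpha)·R_ij` for `i ≠ j`, and `E(x) = xᵀQx + offset`.
An equivalent upper-triangular export (couplings doubled) and an Ising
mapping `x = (1+σ)/2` with
`E(σ) = offset + Σ h_i σ_i + Σ_{i<j} J_ij σ_i σ_j`
are provided for interoperability with binary-quadratic-model tooling; the
round trip is verified by exhaustive enumeration in the tests.

### Mutual information estimation

Continuous features and the target are discretized into `B` quantile bins
(left-closed/right-open intervals, last bin closed; duplicate quantile
edges from tied data are merged, so the effective bin count can be below
`B`).  MI is the plug-in estimator on the empirical joint bin frequencies,
in nats.  Only ratios of MI values matter downstream, so the log base is a
free convention.

The plug-in estimator is positively biased for independent variables by
roughly `(|A|-1)(|B|-1)/(2p)` nats; the tests bound estimates on
independent data by this bias plus a permutation-null spread.

### Choice of `B` and `alpha`

The package defaults are `B = 15` bins and `alpha = 0.9`.  These were
fixed by a sensitivity analysis on the synthetic benchmark (exhaustive
enumeration of the cardinality-constrained optimum across seeds):

* With `alpha` near 0.5 the redundancy double-sum — about `k²` pairwise
  terms among mutually correlated features — dominates the `k` importance
  terms, and the global optimum prefers low-redundancy uninformative
  features over the planted ones.  Recovery requires importance-dominant
  weighting; `alpha ∈ [0.85, 0.95]` is an equivalently good plateau.
  At the other end, `alpha ≳ 0.97` loses the redundancy signal that
  separates a source feature from its near-perfect copy.
* `B = 15` maximizes the energy margin between sources and their noisy
  copies at 10,000 observations; `B = 10` and `B = 20` recover the planted
  set in fewer seeds.

Both parameters are exposed everywhere (`select_features`, CLI flags,
config files).

### Cardinality constraint

`|x| = k` is enforced by adding `M (Σ x_i - k)²`, expanded into the
canonical form (diagonal `+M(1-2k)`, off-diagonal `+M`, offset `+Mk²`).
The automatic weight

```
M = 1 + max_i ( |Q_ii| + 2 Σ_{j≠i} |Q_ij| )
```

exceeds the magnitude of any single-flip change of the base energy, so any
constraint-violating mask can lower the penalized energy by moving one
flip toward weight `k`; minima of the penalized model therefore satisfy
the constraint exactly (verified against a constrained exhaustive oracle).
The factor 2 on the off-diagonal row sum is required by the symmetric
`xᵀQx` convention, in which each coupling is counted twice.

## Solvers

* **Exhaustive enumeration** — chunk-vectorized scan of all `2^n` masks
  (`n ≤ 25`) or all `C(n,k)` fixed-weight masks (`≤ 5·10⁶`); the oracle
  for every other solver.
* **Simulated annealing** — `n_reads = 100` independent chains of
  `n_sweeps = 1000` single-flip Metropolis sweeps, vectorized across
  reads.  The geometric inverse-temperature ladder is sized to the model's
  own energy scales: the hot end accepts the largest single-flip bound
  with probability ½, the cold end resolves the smallest nonzero coupling
  magnitude (ratio clipped at 1e8).  Scaling only to the largest entry
  would leave the schedule too hot to resolve base-cost differences once a
  large penalty term dominates the matrix.
* **Iterated tabu search** — best admissible single-flip moves with a
  recency tabu list (tenure `min(20, n/4)`), aspiration on improving the
  incumbent, `10n` iterations per restart, 10 restarts with `n/5` random
  perturbation flips.  Ties break toward the lowest feature index.

All solvers are deterministic under a fixed seed.  If a heuristic returns
a mask of the wrong weight, a greedy repair adds/removes features by
marginal contribution and finishes with a swap descent that is locally
optimal among single exchanges at fixed `k`.

Selected features are ranked by ascending *marginal contribution*
`Q_ii + 2 Σ_{j≠i, x_j=1} Q_ij` — the energy change from clearing that bit
in the unpenalized model — so the most energy-lowering feature comes
first.

## Synthetic benchmark

`SyntheticSpec` defaults: `n = 50` features, `p = 10,000` observations,
sources `s = [5, 11, 7, 1, 14]` and planted copies `t = [16,...,20]`
(1-based), `rho = 0.1`.

1. Correlation structure: `B ~ N(0,1)` (n×n), `C = BᵀB`, normalized to a
   unit-diagonal correlation matrix `R`.
2. `X ~ MVN(0, R)`; each planted column is overwritten with
   `X[:,t_m] = X[:,s_m] + rho·ε`, giving pair correlation
   `1/√(1+rho²) ≈ 0.995`.
3. Target:
   `y = 0.5·cos(7·X_s4) + sin(X_s3·X_s2) + 0.1·exp(X_s5)·log2(|10·X_s1| + g) + rho·ε'`
   with guard `g = 1e-8` — the raw logarithm is undefined for half of the
   Gaussian draws, so the absolute value plus guard makes the expression
   total while preserving its scale.  The guard may shift baseline
   accuracies slightly relative to other resolutions of that ambiguity.
4. Features are z-scored; the target is min-max scaled to `[0,1]`.

Recovery accuracy is the set overlap with the planted sources,
`|selected ∩ s| / |s|`.  The generator does not attempt realistic
scRNA-seq counts (negative binomial, dropout); it is a Gaussian benchmark
with planted, near-duplicated predictors.

## Baselines

All comparison selectors run on the identical standardized dataset per
seed and return exactly `k` indices:

* **LASSO / elastic net** — regularization path (100 alphas; mixing 0.5
  for elastic net); the `k` largest-|coefficient| features at the sparsest
  path point with ≥ `k` nonzeros.  Selections whose coefficient is exactly
  zero are flagged and not credited by the accuracy score.
* **Random forest** — impurity importances of a 100-tree forest.  100
  trees were chosen after checking that the top-5 ranking is unchanged
  from 500 trees on this benchmark at a fifth of the cost; subsampling
  features or rows degrades accuracy and was rejected.
* **RReliefF** — in-package regression Relief variant (200 sampled
  instances, 10 nearest neighbours by Manhattan distance on
  range-normalized attributes, rank-exponential neighbour weights).
  Relief-family scores are implementation-sensitive; results are reported,
  not asserted.
* **mRMR** — greedy MI-quotient selection `argmax I_j / mean(R_j,S)` on
  the package's own MI estimates; equally implementation-sensitive.
* **SFFS** — sequential forward selection minimizing 5-fold
  cross-validated squared error of a depth-regularized regression tree
  (`min_samples_leaf = 20`).  A linear-model criterion is also available
  via the estimator argument, but a linear fit cannot see the mean-zero
  nonlinear response terms of the benchmark and selects near-randomly
  there.

Wall times are recorded for reports but never asserted.

## Single-cell front end

* Formats: MatrixMarket triplet directories (plain or gzipped, with
  features/barcodes sidecars), dense CSV/TSV (either orientation), h5ad.
* QC defaults: ≥ 1,000 reads per cell, ≤ 15% mitochondrial fraction
  (`MT-` prefix, case-insensitive, configurable), ≥ 500 detected genes per
  cell; then ≥ 15 nonzero cells per gene on the surviving cells.
* Normalization: analytic Pearson residuals under a gene-by-cell product
  expectation with negative-binomial overdispersion `theta = 100`, clipped
  to `±√(n_cells)`; verified against the scanpy reference implementation.
* Pseudotime: a principal-curve fit to a user-supplied 2-D embedding —
  PC1 initialization, iterated least-squares cubic splines on a rank
  parameterization with re-projection onto the densely sampled curve
  (exact segment projection, no grid quantization), normalized arc length
  in `[0,1]`.  The fit is a linear smoother per coordinate, so the result
  is invariant under translation, rotation and uniform scaling of the
  embedding, up to the (arbitrary, flippable) direction.  Embedding
  computation itself is out of scope: coordinates are consumed, and a
  precomputed pseudotime vector can be used directly, which is the most
  faithful route when one exists.  The principal curve assumes a
  non-self-intersecting trajectory whose first principal axis gives a
  roughly monotone initial ordering; strongly looping embeddings can
  defeat the initialization.
* Expression profiles: LOESS (locally weighted linear regression,
  span 0.3) per gene on a 100-point pseudotime grid.

## Evaluation diagnostics

* **Landscape enumeration** — every `m`-subset of a feature shortlist
  evaluated in the model (budget `C(|top|, m) ≤ 10⁶`), sorted by energy.
* **Energy paths** — cumulative energy of a ranking's prefixes inside one
  shared cost matrix, making rankings from different methods directly
  comparable.
* **K-fold stability** — the global selection is computed on all
  observations; for each of `folds` held-out sets (stratified by target
  quantile so every fold spans the target's range, a requirement for
  quantile binning), the cost function is rebuilt from the *training*
  portion — the standard cross-validation subset — re-binned, and
  re-solved.  Each fold reports the set overlap with the global selection
  and the energy ratio `E_global(x_fold) / E_global(x_global)`.  The
  overlap metric treats the global selection as the reference; it measures
  stability, not correctness.

## Limitations

* MI estimation is fixed-grid quantile binning; k-NN or kernel estimators
  are out of scope.
* The cardinality penalty makes the landscape stiffer by design; for very
  large `n` the penalized matrix is dense (`+M` everywhere), which is
  inherent to the quadratic expansion of the constraint.
* Baseline accuracies for Relief-family and mRMR selectors depend strongly
  on implementation details and should be read as indicative.
* No quantum-annealer or cloud-solver integration: the classical solvers
  are the supported backends, with the Ising/coordinate exports as the
  interoperability seam.
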