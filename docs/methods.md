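# Methods

## Model

`hcsim` treats an expression matrix X (n samples × N variables) as a
hierarchy of correlated modules. A first, *adaptive* partition P₁ groups
variables by squared Pearson correlation and sets aside a noise subset C0;
each proper cluster is decomposed by PCA, keeping at most k components.
The residuals E¹ = X − X¹ are re-partitioned inside each cluster by a
*separator* stage and decomposed again, for up to g levels. Because each
level's scores are sample-orthogonal to the residual they leave, the
decomposition satisfies, exactly and per variable,

    Var(Xᵢ) = Var(Xᵢᴿ) + Var(Eᵢᵍ),

and, within any cluster whose PCs are all retained, the cluster's variance
equals the sum of its PC variances. These identities are asserted in the
test suite at 1e-8 relative tolerance and are the bookkeeping backbone: the
fit stops when V_E = Σ Var(Xᴿ)/Σ Var(X) reaches the target f_E or the level
budget g_max is exhausted, and it aborts upfront (InsufficientVarianceError)
when f_E·V_X exceeds the variance held outside C0.

Simulation replaces the fitted PCs with synthetic ones drawn from a
multivariate normal with the PCs' correlation matrix (Cholesky of the
eigenvalue-floored, re-scaled estimate), either scaled to the PC variances
(normal variant) or mapped through per-PC metalog quantile functions via a
Gaussian copula (fitted variant). Per-variable Gaussian noise with the
residual variance restores each variable's total variance; C0 variables are
simulated as pure noise around their mean.

## Stage details and defaults

* **Adaptive stage.** Markov clustering on S = cor², inflation 2.0,
  pruning threshold 1e-5, convergence 1e-8, max 100 iterations; self-loops
  set to each column's maximum off-diagonal weight. These are the canonical
  defaults of the MCL literature. Before clustering, edges whose weight is
  indistinguishable from the null — below the (1 − edge_alpha) quantile of
  the r² null Beta(1/2, (n−2)/2), edge_alpha = 1e-3 — are removed; on a
  dense all-pairs graph this is what lets unconnected variables fall out as
  singletons instead of being absorbed into the nearest basin. Clusters
  below max(min_size = 3, rel_frac × membership-weighted median cluster
  size) become C0; rel_frac defaults to 0 (off). The membership-weighted
  median (the cluster size a typical variable experiences) is used rather
  than the plain median of sizes so that many small clusters cannot drag
  the reference size down.
* **Separator stage.** Complete linkage on dᵢⱼ = 1 − cor(Eᵢ,Eⱼ)²; cuts
  into n_g = 2…7 groups are scored by normalized entropy
  (−Σ pᵢ log pᵢ)/log n_g, and the maximal-entropy cut wins. Exact ties
  break to the **largest** n_g: an even 2-cut of four equal sub-modules
  ties the true 4-cut at entropy exactly 1, and only the finer split
  resolves the structure within the level budget; the fully degenerate case
  (all residuals mutually |cor| = 1) instead returns an even cut at the
  smallest n_g, since no cut is better than any other. Residual columns
  with variance < 1e-12 are excluded from the distances and attached to
  their most-correlated peer afterwards.
* **Decomposition.** PCA is centering-only (no per-variable scaling), so
  the ledger holds in raw variance units. Each PC's sign is fixed so its
  largest-|loading| coefficient is positive, making fits reproducible
  across linear-algebra backends. Clusters whose residual variance falls
  below 1e-6 of their original variance are frozen — neither re-fit nor
  subdivided. Default g_max = 3: in practice two to three levels capture
  what is distinguishable from noise.
* **Metalog marginals.** Unbounded form only (PC scores are unbounded),
  default 5 terms, plotting positions (i − 0.5)/n, OLS in quantile space.
  Feasibility (strictly increasing quantile function on a 999-point grid)
  is checked; infeasible fits step down a term at a time, and a PC whose
  fit never becomes feasible falls back to a normal marginal.
* **Copula order.** The fitted variant correlates standard normals first
  and transforms margins second (NORTA). The PC *Pearson* correlations are
  therefore preserved only approximately after transformation; rank
  correlations are preserved exactly, which is what the tests assert for
  this variant.
* **PD repair.** Eigenvalues of the PC correlation matrix are floored at
  1e-10 and the matrix re-scaled to unit diagonal — cheap and adequate when
  the PC count is far below n; the applied floor is recorded in
  `repair_log`. When the PC count exceeds n − 1 the estimate is singular
  and repair is mandatory (flagged `rank_deficient`).
* **C0 downstream.** Noise-subset variables are reconstructed as their
  mean and simulated as pure full-variance noise. Whether to model them at
  all is a genuine design fork; pure noise is the conservative choice and
  is isolated in one place (`add_variance_matching_noise` + the simulator).

## Seeding

All randomness flows from one user seed through named substreams
(`sha256(seed | stage)` truncated to 31 bits), so the generator, the
simulator and the noise step are independently reproducible and changing
one stage's draws never perturbs another's.

## Synthetic fixture

The generator plants a two-level factor hierarchy: every variable in a
child block is √p·parent factor + √c·child factor + √(1−p−c)·noise, with
factors standardized in-sample, so p + c is the variable's signal fraction
and the population correlation matrix is known in closed form (same child:
p + c; same parent: p; across parents: p·ρ; noise: 0). The default fixture
uses 3 parents with {3, 4, 4} children of 12 variables each, shares
0.4/0.3, 8 pure-noise variables, n = 500 — the shape of the worked 3 + 11
cluster hierarchy at a size where the full test suite runs in seconds.
Non-normal marginals are produced by monotone per-column transforms
(exp for lognormal; z + 2.5·tanh(2.5 z) for a bimodal shape), which
preserve rank structure exactly while perturbing Pearson correlations.

What the fixture does *not* emulate: counts and library-size effects,
dropout, nonlinear dependence, and the very unbalanced module sizes of
real transcriptomes. Passing tests therefore demonstrate correctness of
the algorithmic contracts and recovery under the planted linear-factor
model, not performance on raw sequencing data.

## Evaluation battery

Networks are unsigned: edge weight cor², diagonal excluded, no soft-
threshold power. Degree is the weighted connectivity; the clustering
coefficient is the Zhang–Horvath weighted form; TOM is the standard
unsigned topological overlap; all four are pinned to brute-force loop
oracles at 1e-12 in the tests. Model-vs-reference scoring reports the max
and mean squared cross-correlation over all variable pairs and the RMSE
between the two correlation matrices (off-diagonal, unordered pairs).
Topology distributions are compared by the two-sample KS statistic.

The independence check compares the maximal squared cross-correlation
against the null distribution of the *maximum* over all N² pairs
(Šidák-adjusted Beta(1/2, (n−2)/2) quantile at level 0.999). A single-pair
null quantile would be the wrong yardstick: the max over ~2·10⁴ pairs
exceeds it even for truly independent data, as the i.i.d. control in
`examples/simulate_new_dataset.py` shows.

## Known limitations

* The simulation replicates the covariance of the generating PCs — a
  linear summary; nonlinear relations in the reference are not carried
  over.
* MCL is run on a dense matrix (O(N³) per iteration); for N ≫ 10⁴ a sparse
  implementation or a precomputed partition (`hcr_fit(...,
  initial_partition=...)` / `fit_decomposition`) is the intended route.
* HCS(f) preserves Pearson PC correlations only approximately (see copula
  order above).
* The entropy criterion evaluates only the cuts produced by complete
  linkage; it does not search all partitions.
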