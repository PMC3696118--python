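# Methods

## The problem

Structural correlation networks describe how brain morphology covaries
across people: nodes are atlas regions, and an edge weight is the Pearson
correlation of a regional morphometric value (here, regional gray-matter
volume) across subjects.  Such networks are routinely summarized by
small-world parameters — normalized clustering `gamma = C/C_null`,
normalized path length `lambda = L/L_null`, and the small-world index
`SW = gamma/lambda` — all of which depend on the *null networks* used for
normalization.  Correlation networks carry transitive structure (strong
r(A,B) and r(B,C) force an elevated r(A,C)), so they are inherently more
clustered than degree-matched random graphs, and the choice of null model
changes both the within-group estimates and the between-group statistics.
This package implements the whole benchmarking pipeline for three null
families and the resampling inference that compares them, runnable end to
end on a synthetic-data generator because the originating clinical cohorts
are not public.

## Pipeline

1. **Covariate correction** (`preprocess`).  Per region, ordinary least
   squares of volume on an intercept plus nuisance covariates (age, sex,
   total-brain-volume proxy); residuals replace the raw values.  The
   intercept is always included so residual columns are mean-centred —
   without it the Pearson step would be ill-defined.  Fitting is per group
   by default; a pooled mode (`correct_regional_volumes_pooled`) is
   provided because published pipelines rarely state which was used, and
   pooled fitting leaks group mean differences into the residuals.

2. **Network construction** (`netcon`).  The region x region Pearson matrix
   (with its covariance twin, needed by HQS) is thresholded at fixed edge
   densities: the E = round(d·n(n−1)/2) most *positive* correlations are
   kept.  Signed ordering (not |r|) is used because the windowed analysis
   treats "low density" as synonymous with "strong correlation"; negative
   correlations can only enter once the positive tail is exhausted.  Ties
   are broken by lexicographic node pair, making edge sets nested across
   densities and thresholding fully reproducible.  `D_min` is the smallest
   grid density at which every group's network is connected; the default
   analysis grid is [0.22 : 0.02 : 0.50] with windows [0.22, 0.30],
   [0.30, 0.38], [0.38, 0.46], [0.46, 0.50].

3. **Null models** (`nullmodels`).
   * **TOP** — connected, simple, degree-preserving double-edge-swap
     rewiring (default 10 accepted swaps per edge).  Swaps violating
     simplicity are rejected; connectivity is enforced with an adaptive
     check window: batches of swaps are committed only if a BFS confirms
     the graph is still connected, and a failing batch is rolled back and
     the window shrinks to a single swap.  At every commit point the graph
     is simple, connected, and has the input's exact degree sequence; the
     windowing only changes which intermediate states are reachable, not
     the invariants.  Inputs that are already fragmented (possible for
     bootstrap networks at `D_min`) cannot satisfy a connectivity
     constraint; `allow_fragmented=True` then falls back to plain
     degree-preserving swaps with a warning.
   * **HQS** — a random covariance C = B·Bᵀ with B an n x m_f matrix of
     i.i.d. Normal(mu, sigma²) entries, where `m_f = max(2,
     round((dbar²−e²)/v))`, `mu = sqrt(e/m_f)`, `sigma² =
     sqrt(mu⁴ + v/m_f) − mu²`, and dbar/e/v are the mean diagonal, mean
     off-diagonal and (population) off-diagonal variance of the observed
     covariance.  These constants make E[C_ij] = e, Var[C_ij] = v and
     E[C_ii] ≈ dbar; the identities are verified analytically in the unit
     tests and by Monte-Carlo in the acceptance suite.  The draw is
     converted to a correlation matrix and thresholded by rank at the
     matched density (density matching rather than a fixed r cutoff,
     because the null correlation values need not follow the empirical
     distribution); thresholding on the correlation rather than the
     covariance scale is this package's documented choice.
   * **COR** — each subject's regional values are independently permuted
     and the Pearson matrix recomputed, then thresholded at the matched
     density.  Each subject's value multiset is preserved exactly.  Note
     that row permutation also preserves each subject's overall level, so
     a shared global component of the correlations survives; what COR
     destroys is the block/community structure (the strong,
     network-forming correlations collapse toward the bulk).
   * HQS and COR outputs are not guaranteed connected.  Ensembles
     (`null_ensemble`, default m = 20) count fragmented members and
     support three policies: `keep` (default; path length is then computed
     over connected pairs only), `discard` with a bounded redraw budget,
     and `error`.

4. **Metrics** (`metrics`).  Binary clustering coefficient (triangle count
   over possible neighbour pairs, degree-<2 nodes contribute 0) and
   characteristic path length (mean shortest path over *connected* ordered
   pairs, excluded pairs counted).  The connected-pairs convention was
   chosen over largest-component or harmonic means to keep one auditable
   rule that leaves ensemble means finite when HQS/COR members fragment;
   it biases L slightly downward for fragmented graphs.  Degree skewness
   is the population Fisher–Pearson g1 (no bias correction; no estimator
   is canonical here), with positive g1 meaning a right tail of high-degree
   hubs; regular graphs return 0 with a warning.

5. **Inference** (`inference`).  Metric-versus-density curves are compared
   by the discrete FDA area `A = Σ_i |y2(x_i) − y1(x_i)|`, with the signed
   sum reported alongside so direction is never lost.  Two tests:
   * *Dependent* (between null models, one group): 300 bootstrap resamples
     of the subjects by default; per resample, curves under each model;
     observed statistic is the area between model mean curves; the null
     swaps model labels within each bootstrap sample (5000 shuffles by
     default).  Comparing mean curves (not the mean of per-bootstrap
     |areas|, which is invariant under label swaps and therefore unusable)
     is the implemented reading; a per-bootstrap signed variant is
     available.  Bootstrap resampling inflates correlations by duplicating
     subjects; this cancels in model comparisons because every model sees
     the same resamples.
   * *Independent* (between groups): subjects are reassigned to
     pseudo-groups of the original sizes (1000 permutations by default)
     and association matrices, networks and curves are rebuilt per
     permutation.  For normalized metrics the faithful mode regenerates
     null ensembles inside every permutation; a fast mode reuses null
     means computed once from the pooled data and is labeled approximate
     in every report.  All windows of a windowed analysis are evaluated
     from a single permutation pass.
   * p-values use the add-one convention (count ≥ observed + 1)/(n + 1),
     upper tail on the non-negative area statistic, so p ∈ (0, 1];
     Bonferroni correction is available for families of model pairs.
   * Replicability: repeated ensembles at `D_min`, one-way ANOVA on
     per-set null means (per model — pooling models would mix scales), and
     Levene's test comparing per-member dispersion across models.
   * Skewness analysis: Pearson correlation between per-bootstrap-network
     degree skewness and (i) between-model differences in normalized
     clustering / SW, and (ii) the clustering of matched TOP nulls.

## Synthetic cohorts

`simulate` draws two groups (defaults 31 and 28 subjects — a
healthy-control-like and a patient-like cohort — with 90 regions) from a
multivariate normal whose correlation matrix is block-constant: 6 blocks,
within-block r = 0.6, between-block r = 0.15.  Block structure is what
makes the thresholded network clustered and hence small-world; the values
were chosen so that the group networks are connected at density 0.22 and
the normalized clustering stays clearly above 1 across the whole grid, and
compound symmetry within blocks keeps positive semidefiniteness trivial to
verify (smallest eigenvalue 1 − within_block_r).  A group difference is
injected by multiplying the second group's between-block correlation by
`group_effect` ∈ (0, 1].  Covariates are age ~ U(5, 19) years, sex ~
Bernoulli(1/2), and a total-volume proxy ~ N(1200, 100); their effects are
strictly linear (defaults 0.5, 2.0 and 0.01 volume units per covariate
unit) so that the OLS correction can remove them exactly in expectation.
Region values are `10 + noise_sd · Z + X·beta` with noise_sd = 1.  One
master seed drives deterministic substreams per group.

What the generator does *not* emulate: anatomical geometry and lobar
organization, non-Gaussian morphometry, heteroscedastic or nonlinear
covariate effects, site effects, and the empirical degree-distribution
tails of real cortical networks.  Passing tests therefore demonstrate the
correctness and calibration of the machinery and the *qualitative*
null-model phenomena (transitivity-inflated clustering, dispersion
differences, direction flips), not quantitative agreement with any
clinical dataset.

## Numerical choices

* PSD tolerance −1e−8 on smallest eigenvalues (scaled by matrix magnitude
  for covariances); symmetric matrices checked to 1e−12.
* Edge-count quantization by round-half-away-from-zero; the achieved
  density is recorded and used downstream.
* HQS moments use the population variance of the off-diagonal entries; a
  variance at float-noise level (≤ 1e−12·max(dbar, e)²) is treated as zero
  and rejected.
* Rewiring seeds are reduced mod 2³¹−1 for the compiled kernel; ensembles
  and resampling derive per-member seeds from a `SeedSequence`, so results
  are reproducible bit-for-bit given the resolved configuration.
* The rewiring attempt cap is 100× the target swap count; graphs with no
  rewirable pair (complete graphs) are returned unchanged with a warning,
  and falling short of the swap budget warns with the achieved count.

## Problem sizes used in tests and reports

The shipped test suite and acceptance script run the pipeline at reduced
resampling sizes chosen as the smallest that leave the statistical
assertions well-powered: ensembles of 10–20 nulls, 50 bootstrap resamples,
500–2000 label shuffles, 200–500 group permutations, and calibration
studies at 40 regions with 200 replicate runs.  The full-scale defaults
(300 bootstraps, 5000 shuffles, 1000 permutations, 50 replicability sets)
remain the package defaults and are what `run_pipeline` uses unless a
configuration overrides them.

## Known limitations

* The independent test's fast mode ("reuse") treats null means as fixed
  across permutations; it is clearly labeled and the faithful mode is the
  default for single tests.
* L on fragmented graphs is a connected-pairs mean; comparing it across
  graphs with very different fragmentation is not meaningful.
* The skewness correlations on synthetic cohorts are weak and
  seed-dependent; the generator's degree distributions are narrower than
  empirical cortical networks, so these analyses demonstrate mechanics,
  not effect sizes.
* HQS requires a positive mean off-diagonal covariance; data dominated by
  negative covariances have no HQS null here.
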