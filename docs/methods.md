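# Methods

## Model

`bfamet` fits a Bayesian factor-analytic (FA) mixed model to long-format
multi-environment trial (MET) data. A plot observation of genotype *i* in
block *b* of environment *j* is modelled as

    y = X1 β + Σ_k λ_k diag(X2 α_k) Zf f_k + Z δ + ε ,

which is the summation (spectral) form of the classical FA mixed model
y = Xβ + Z(Γ ⊗ I_m)f + Zδ + ε with Γ = [λ_1 α_1, …, λ_k α_k]:

* **β** (length = number of occurring environment–block cells): fixed
  cell effects, cell-means coding, no global intercept. Trait units.
* **λ_1 ≥ … ≥ λ_k ≥ 0**: singular values of the genetic covariance;
  **α_k**: orthonormal environment eigenvectors. Identification of the
  loading matrix comes entirely from this spectral parameterization —
  there is no rotational freedom and no Heywood cases, because
  Σ = Σ_k λ_k² α_k α_kᵀ + Ψ is positive semidefinite by construction.
* **f** (m × k): genotype factor scores, standard-normal prior (unit
  factor variance is what makes Σ = ΓΓᵀ + Ψ the genetic covariance).
* **δ** (mp): genotype-by-environment specific effects, N(0, I_m ⊗ Ψ),
  Ψ = diag(ψ_1 … ψ_p); **fixed at zero in the full-rank model k = p**,
  which is then an unstructured-covariance model.
* **ε**: residuals with R = blockdiag_j(σ²_ej I): homogeneous within an
  environment, heterogeneous across environments. This heteroscedasticity
  is why the eigenvector conditionals are Gaussian rather than von
  Mises–Fisher, and why the corrected-subspace sampling scheme below is
  needed.

Priors: effectively flat Gaussians for β and λ (variance 10¹²; λ
truncated to the ordered nonnegative cone), spherical-uniform for each
α_k on its constraint set, Scale-inv-χ²(ν_e = 0, 0) for σ²_ej and
Scale-inv-χ²(ν_k = 1, 0) for ψ_j. The ν_k = 1 default matches the
degrees of freedom that the ψ full conditional uses; both hyperparameters
are configurable through `PriorSpec`.

## Gibbs sampler

All conditionals are conjugate. One scan updates
β → λ_1..λ_k → α_1..α_k → f → δ → Ψ → σ²_e, recomputing each partial
residual from the current state (correctness over micro-optimization; the
incidence structure makes every update O(n) to O(n k²)).

Numerical/structural choices:

* **β**: cell-means coding makes X1ᵀR⁻¹X1 diagonal; the update is
  elementwise and is estimable whenever every used cell has ≥ 1 record.
* **λ_k**: truncated-normal draw on [λ_{k+1}, λ_{k−1}] so that a
  single-coordinate update keeps the vector ordered and nonnegative.
  Truncated normals are drawn by inverse CDF on [Φ(a), Φ(b)] with a
  far-tail fallback to `scipy.stats.truncnorm`. A numerically null factor
  (regressor ≈ 0) falls back to the truncated prior, with a warning.
* **α_k**: the Gaussian conditional ignores orthonormality, so the draw is
  made in the corrected subspace: H = orthonormal complement (QR-based
  Gram–Schmidt) of the columns updated earlier in the scan, a Gaussian
  draw of the (p−s)-dimensional coordinates, unit normalization, and
  back-transformation α_k = H α̃ (norm-preserving). Because Δ_kᵀR⁻¹Δ_k is
  diagonal, the subspace moments are cheap. A singular conditional (e.g.
  f_k ≡ 0) falls back to the spherical-uniform prior on the subspace.
* **f**: the stacked-score precision I + A4ᵀR⁻¹A4 is block diagonal by
  genotype, so the joint draw factorizes into m independent k-dimensional
  Gaussians (batched Cholesky).
* **δ, Ψ, σ²_e**: elementwise Gaussian and scaled-inverse-χ² draws; ψ_j
  uses the specific effects and genotype count of the cells observed in
  environment j; σ²_ej uses its environment's n_j residuals.
* **Initialization**: β at cell means; the genotype × environment table of
  residual means gives a sample covariance whose top-k eigenpairs seed
  (λ, α); σ²_e at within-environment residual variances; ψ at the
  variance the k factors leave unexplained (0 if full rank). Factor
  scores start at the principal-component regression scores of that
  table rather than at zero: a zero start makes every factor numerically
  null at scan one, so λ_1 would be drawn from the near-flat truncated
  prior (~10⁶) and the chain would need a very long burn-in to recover.
* **Sign convention**: the likelihood is invariant to joint
  (α_k, f_k) sign flips. At storage time each retained draw is aligned so
  the coordinate of α_k with the largest absolute running posterior mean
  is positive (f_k flipped jointly). This is summary-time relabeling and
  does not change the chain's law; `biplot_coordinates` re-applies the
  same convention so displays are flip-invariant.
* The fit refuses environments with fewer than 2 observations (the
  residual-variance conditional would be improper under ν_e = 0) and
  datasets with zero within-cell variance.
* Determinism: one `numpy` Generator seeded from `SamplerConfig.seed`
  drives the whole run; identical inputs give bitwise-identical chains.
* Every retained draw is validated (ordering, orthonormality to 1e−8,
  variance positivity); a violation raises with the scan index.

### Known behavior at k < p

With the default ν_k = 1, S²_k = 0 prior, the joint (δ, Ψ) update has an
absorbing regime at zero: once ψ_j becomes small, δ's conditional mean and
variance collapse, and ψ_j follows (a multiplicative random walk with
negative drift at these signal-to-noise levels). Reduced-rank fits on the
default simulated design therefore typically end with ψ ≈ 0 and behave as
pure k-factor models, with the unexplained genetic variance absorbed by
the residual variances. This is a property of the improper specific-
variance prior, not of the sampler; setting S²_k > 0 gives a proper prior
but does not remove the slow mixing between the spike and the slab. The
headline analyses (parameter recovery, cross-validation, variance
partition) all use the full-rank model, where δ and Ψ are exactly zero by
definition.

## Posterior inference

* **MAP proxy**: midpoint of the shortest interval containing 5% of the
  sorted draws (an HPD-based mode estimate; fraction configurable). Its
  Monte-Carlo spread is ~0.04 at 10⁵ standard-normal draws.
* **HPD intervals**: shortest contiguous window holding ceil(prob·N)
  sorted draws; ties break to the lowest start.
* **Bivariate credibility regions** for biplots: Euclidean distance of
  each paired draw to the coordinatewise posterior mean, farthest 5%
  discarded, convex hull of the rest (no Gaussian-ellipse assumption; the
  axes are not standardized before computing distances). A region's
  `contains_origin` flag reports whether the biplot origin lies in the
  hull — regions excluding the origin are the reportable ones.
* **Variance partition**: at the posterior mean state (loadings entering
  as posterior means of the products λ_k α_k), geometric means over
  environments of diag(ΓΓᵀ), diag(ΓΓᵀ + Ψ), ψ and σ²_e. For a full-rank
  fit the loadings recover the whole genetic variance and ψ ≡ 0 exactly.
* **Convergence diagnostics**: Geweke difference-of-means z (windows
  0.1/0.5) with AR-model spectral variance estimates (order by AIC, ≤ 20);
  Heidelberger–Welch Cramér–von Mises stationarity scan discarding
  successive 10% prefixes plus the 95% halfwidth test; Raftery–Lewis
  two-state run-length control ((q, r, s) = (0.025, 0.005, 0.95)) with
  BIC-based thinning selection. All are pure functions of the draw
  sequence; constant chains raise an explicit degenerate-chain error.
  Note that the AR spectral estimator inflates under strong
  nonstationarity, damping (but not hiding) the Geweke statistic.

## Cross-validation and model selection

Whole genotype × environment cells (all replicates) are deleted in k
equal folds — 10-, 3-, 2-fold for 10%, 33%, 50% deletion — under two
constraints: every environment keeps ≥ 1 observed cell and every genotype
stays observed in ≥ 1 environment. Fold plans are seeded and resampled
(bounded retries) until feasible. Deleted cells are predicted by the
posterior mean of [environment fixed effect averaged over its block cells
+ Σ_k λ_k α_jk f_ik + δ_ij] from a chain fitted to the training records
only; the observed value of a deleted cell is the phenotypic mean of its
replicates (a deleted observation has no defined block identity). Metrics:
PRESS = mean squared prediction error, pooled and per-fold Pearson
correlation (both pooled-over-folds and mean-per-fold are available, as
the two conventions differ), statistical efficiency SE = PRESS_full /
PRESS_k, and AICM = 2(l̄ − s²_l) computed from the retained per-draw
log-likelihoods with the N−1 variance.

Per-fold fits use deliberately short chains (6,000 scans, 1,000 burn-in,
thinning 2 — 2,500 retained), the package's desk-scale default for the 15
fits of a 10/3/2-fold study; headline fits use 10,000 scans with 2,000
burn-in. AICM is reported on the raw log-likelihood scale; rescaled
(per-observation) AICM values from other software are not directly
comparable.

The marginal-BLUP comparison fits the simple two-way model (environment-
block cells fixed, genotype random with a single variance) by REML via
`statsmodels` MixedLM and reports the squared correlation between
first-factor posterior-mean scores and the genotype BLUPs. A genotype
variance estimated at zero returns all-zero BLUPs.

## Synthetic-data generator

`SimulationDesign` emulates a randomized-complete-block MET with three
genotype stability groups: by default m = 20 genotypes (5
positive-unstable, 5 negative-unstable, 10 stable), p = 5 environments,
q = 2 replicates, and per-environment residual variances
(0.546, 1.209, 4.690, 7.377, 9.026) trait-units². Each genotype draws a
marginal effect N(±μ or 0, 1) (Gaussian realizations around the group
magnitude) and independent per-environment interactions N(0, 2) for the
unstable groups, N(0, 1) for the stable group; observations add the
environment/block fixed effects (default 0) and heteroscedastic Gaussian
noise. The implied across-environment genetic covariance is
Var(g)·J + E[interaction variance]·I, with Var(g) = 1 + 0.5 μ².

The group magnitude defaults to μ = 2.4, chosen once so that the design
sits in the signal regime its residual-variance profile is meant for: a
first-factor magnitude of λ₁² = 5·Var(g) + 1.5 ≈ 21, and an intraclass
correlation implying a maximum achievable observed-vs-predicted
correlation of ≈ 0.84 at the cell level. Weaker magnitudes (e.g. ±1.5)
leave so little shared signal that even an oracle predictor using the
true covariance cannot exceed ≈ 0.36 pooled predictive correlation under
50% cell deletion.

`SimulatedTruth` records the realized effects: the realized residual
variance is the pooled within-cell replicate variance (the quantity σ²_e
is identified by), and the realized genetic covariance is the sample
covariance of the realized genotype × environment genetic values, whose
top eigenpair defines the realized first-factor loadings (sign:
largest-magnitude coordinate positive, the sampler's own convention).

What the generator does not emulate: interactions are independent across
environments (no genuine low-rank interaction structure beyond the shared
marginal axis), there is no incomplete-block field layout beyond generic
cell deletion, no spatial trends, and no pedigree relatedness. Passing
tests therefore demonstrate recovery of marginal-plus-noise genetic
structure under heteroscedastic errors, not performance under structured
G×E or non-Gaussian field effects.

## Problem sizes used by the test suite and acceptance script

Headline fits use 10,000-scan chains on the 200-record default design
(seconds each); repeat-run coverage uses 50 replicates of that fit;
cross-validation refits 15 short chains. These sizes are the package's
desk-scale defaults and keep the full study reproducible on a laptop;
all are configurable upward.

## Known limitations

* Reduced-rank (k < p) fits inherit the specific-variance spike behavior
  described above.
* The normalize-then-backtransform eigenvector draw targets the
  constrained conditional only approximately (the exact conditional on
  the sphere is Fisher–Bingham); this is the method's prescribed scheme,
  and posterior uncertainty of weakly identified trailing factors is
  correspondingly generous.
* AICM differences between candidate orders are typically tiny (the
  spectral identification makes marginal likelihoods nearly equal across
  k), so order selection should lean on PRESS/SE, as the selection table
  reports.
* With very sparse training data (heavy cell deletion) the posterior is
  wide and residual variances are partly confounded with weakly
  identified genetic variance; predictive correlations degrade
  accordingly.
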