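# Methods

## Model

All computations assume the additive two-way model per feature

    Y_ijr = α + β_j + γ_i + ε_ijr,   ε_ijr ~ N(0, σ²) i.i.d.,

with batches `i = 1..m`, groups `j = 1..M` and replicates `r = 1..n_ij`.
Batch and group act as pure location shifts, noise is homoscedastic, and
features are independent except where batch effects are shared by
construction. The batch–group contingency table `n_ij` (its proportions, not
its size) governs every diagnostic in the package.

Identifiability: the model is fit with a reference-cell design matrix
(intercept + M−1 group dummies + m−1 batch dummies) and the estimates are
re-expressed so that the `n_i−`-weighted mean of the batch effects and the
`n_−j`-weighted mean of the group effects are zero. Subtracting batch
effects in this parameterization preserves the grand mean of the data,
which makes centering-based and model-based adjustments directly
comparable. The common location of batch effects is not estimable and is
absorbed into the intercept.

A design is *fittable* when the bipartite batch–group graph over nonzero
cells is connected (checked by union-find) and the residual degrees of
freedom `n − M − m + 1 ≥ 1`. Disconnection is a warning in the audit report
but a hard error for fitting — the least-squares solve also verifies the
design-matrix rank equals `m + M − 1` so a defective design cannot silently
fall through to a pseudo-inverse artifact.

## Effective sample size

For groups A and B, the within-batch difference `Ȳ_iA − Ȳ_iB` has variance
`σ²/ν_i` with `ν_i = 1/(1/n_iA + 1/n_iB)`; the precision-weighted pool over
batches has variance `σ²/ν`, `ν = Σν_i`, and coincides with the two-way
least-squares contrast (an identity the tests verify on random two-group
designs — with a third group present the least-squares contrast can be
strictly more precise than the within-batch pool, so the identity is stated
and tested for M = 2). A batch missing either group has `ν_i = 0`: it adds
nominal but not effective sample size. Ratios are reported as `+∞` for
fully confounded pairs rather than erroring, so the audit still produces a
report for degenerate published designs.

## Adjustments

* `center_batches` subtracts each batch's per-feature mean (optionally
  restoring the grand mean). In unbalanced designs the batch mean absorbs
  the composition-weighted group structure `β̄_i = Σ_j (n_ij/n_i−) β_j`,
  shrinking and distorting group contrasts.
* `anova_adjust` subtracts the weighted-centered least-squares batch
  effects. Group contrasts are preserved exactly and within-batch sample
  differences are untouched, but the shared estimation error `γ̂_i − γ_i`
  correlates all samples of a batch.
* `eb_adjust` moderates the per-feature batch-effect estimates toward their
  cross-feature mean with weight `τ̂²_i/(τ̂²_i + s²_gi)`, where `τ̂²_i` is the
  method-of-moments excess variance of the estimates across features and
  `s²_gi = σ̂²_g · [T(X'X)⁻¹T']_ii` their per-feature sampling variance.
  This is a location-only normal-prior shrinkage; the full location–scale
  empirical-Bayes machinery of dedicated batch-correction tools is out of
  scope. With no true batch effects `τ̂² ≈ 0` and the adjustment nearly
  vanishes (so downstream tests stay calibrated); with strong shared
  effects it approaches `anova_adjust` together with its calibration
  problem. A fixed `shrink` weight in [0, 1] interpolates the same path.

## Corrected null F law

Under the null, adjusted data are `(I − Γ)y` where `Γ` maps a data vector
to its per-sample centered batch-effect estimate. The one-way between-group
sum of squares is the quadratic form with matrix `(I − Γ)' A (I − Γ)`
(`A` = projection onto group means minus grand mean), so `SSB ~ Σ λ_i χ²₁`
with `λ_i` the nonzero eigenvalues, computed here by explicit
eigendecomposition of the n×n matrix (O(n³), auditable, exact to machine
precision; ~1 s at n = 1200). The mixture is mapped to a scaled F by
Satterthwaite moment matching — `q̃ = (Σλ)²/Σλ²`, `σ̃² = Σλ²/Σλ` — which
reproduces the stated properties `q̃ ≤ M−1` and `q̃σ̃² ≥ (M−1)σ²` with
equality exactly on balanced designs. The one-way statistic computed with
the naive `n − M` denominator then follows

    F ≈ inflation · df_correction · F_{q̃, n−M−m+1},
    inflation = Σλ/((M−1)σ²),  df_correction = 1 + (m−1)/(n−M−m+1).

For M = 2 there is a single eigenvalue, `Σλ/σ² = ν₀/ν` (verified to 1e−8
against the effective-sample-size algebra on 200 random designs) and the
law is exact; for M > 2 it is an approximation whose quality is *measured*
by the simulation module, not assumed (KS distance of corrected p-values
from uniform, asserted < 0.02 for the two-group case at 20 000 features).
`corrected_p` labels itself Satterthwaite-approximate for M > 2.

## Simulation engine

`simulate_dataset` draws `Y = β_j + γ_i + ε` with `ε ~ N(0, σ²)`, σ = 1 by
default (standard-normal null). Random batch effects are drawn
independently per (feature, batch) — constant-across-feature effects would
be shrunk away by cross-feature pooling and would understate the problem —
for a *fixed count* `round(fraction · n_features)` of features (not a
Bernoulli draw), so truth sets are reproducible. Default fraction 0.1 and
`batch_effect_sd = 1` in the scaled-size experiments; the magnitude is a
free parameter since only the location of the null distribution, not the
adjusted-data law, depends on it (the adjustment map is linear and removes
constant-per-batch shifts exactly). All randomness flows through
`numpy.random.default_rng(seed)` (PCG64) with the seed recorded in configs
and reports.

The three-group scenario uses counts batch1 = (8, 2, 2), batch2 = (2, 8, 8),
true means (0, 0, −1.5), σ = 1, and opposite batch shifts (+1.5, −1.0)
whose sample-weighted mean is zero (the unidentifiable common location is
fixed at zero by construction). Group 3 must also be unevenly split:
otherwise the per-batch contamination terms coincide and centering induces
no spurious group1–group2 gap. "Naive" intervals in the coverage comparison
are the pooled-variance one-way t intervals (df `n − M`) a user of adjusted
data would compute.

What the simulations emulate — and do not: independent Gaussian features
with location-only batch effects. Real expression data add
intensity-dependent variance, probe effects, and feature correlation beyond
shared batches; calibration results here demonstrate the *design-driven*
miscalibration mechanism and its correction, not full realism of
microarray noise.

## Problem sizes and numerical choices

Monte-Carlo checks use 10⁵ replicates for variance/covariance oracles
(assertions at 3 standard errors), 2·10⁴ features for calibration checks
(binomial SE ≈ 0.0015 at α = 0.05), and 500 replicates for interval
coverage — sizes at which the targeted effects exceed noise by an order of
magnitude while a full test run stays in the tens of seconds. Tolerances:
exact linear-algebra identities at 1e−10–1e−12, refit/orthogonality checks
at 1e−8, eigenvalue identities at 1e−8. Eigenvalues are clipped at zero and
the top M−1 retained; ties and near-zero values are harmless because only
the power sums Σλ, Σλ² enter the law.

## Known limitations

No continuous covariates, nested batches, missing data (load-time error by
design — masking would silently change `n_ij` per feature), moderated
variance estimators, or contrasts beyond group comparisons. The corrected
p-value repairs the reference distribution but does not recover the
efficiency lost by the two-step workflow; a blocked analysis remains the
better choice whenever it is available.
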