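# Methods

## The independent-Poisson view of UMI counts

UMI counts collapse PCR duplicates, so each matrix entry x_gc estimates the
number of captured molecules of gene g in cell c. The package treats every
entry as its own Poisson variable X_gc ~ Poisson(λ_gc), independent across
genes and cells. Zeros need no special mechanism under this view: they are
simply draws from entries with small rates. The per-entry MLE (the count
itself) is useless, so all inference pools information, in two ways: a
closed-form two-way baseline for the departure representation, and a
latent-factor GLM-PCA fit for goodness-of-fit work.

## Two-way baseline

The baseline log rate is μ + α_g + β_c with Σ e^α = G and Σ e^β = C for
identifiability. The MLE is closed-form (log grand mean; log row/column
means minus μ̂) and satisfies the score equations exactly; the test suite
verifies agreement with a generic constrained optimizer to 1e-6 on random
small matrices. Rows or columns with zero totals make the MLE infinite, so
`filter_counts` removes them first. Degenerate 1×C and G×1 matrices are
allowed (the constraint forces the corresponding effects to zero).

## Departure representation

Departures use the averaged CDF F̃(x;λ) = (P(X≤x) + P(X<x))/2 rather than
either one-sided convention: P(X≤x) pins zeros at e^{-λ} ≈ 1 for small λ,
P(X<x) pins them at ≈ 0, while F̃ has mean exactly ½ under the true model
for any λ. The logit of F̃ (clamped to [1e-10, 1−1e-10], both sides, so
double precision never overflows) gives the dense departure matrix D. The
Poisson CDF is evaluated via the regularized incomplete gamma function, so
rates up to ~1e5 are handled without summation loss; accuracy against
direct pmf summation is better than 1e-10 in probability. Note that a 1e-10
agreement in probability cannot pin the *logit* near the clamp (slope
1/(p(1−p))); tests compare logits with exactly that amplification allowed.

The mid-distribution logit is symmetric between the two tails only
asymptotically: Poisson skewness decays like 1/√λ, and the measured maximal
asymmetry |D(x) + D(2λ−x)| within ±2√λ is 0.42 at λ=50, 0.08 at λ=1000,
0.035 at λ=5000. The symmetry test asserts this decay rather than
small-sample symmetry.

## Poissoneity diagnostics

Goodness of fit is assessed on aggregates: the m = 200 entries whose
estimated rates are nearest a target λ₀ (ties broken by row-major index)
are treated as an approximately i.i.d. sample. Aggregation keeps rate
heterogeneity second-order while giving the tests enough data. Four
diagnostics are used; the default target grid is {0.1, 0.5, 2, 20},
skipping targets outside the estimated rate range.

* **KS distance.** sup_x |ECDF − theoretical CDF|, with the asymptotic
  continuous-null p-value (conservative for discrete data — measured null
  rejection ≈ 0.008 at nominal 0.05). By default the theoretical reference
  is the mixture CDF (1/m) Σ F(x; λ̂_i) over the aggregate's own rates,
  which equals F(x; λ₀) when the rates are homogeneous; at desk-scale
  matrices (~3e4 entries) the nearest-200 rates genuinely spread around λ₀
  and the single-rate reference would reject correct models.
* **Over-dispersion score test.** Alternative Var(X) = (1+α)λ, α > 0. The
  auxiliary regression of y_i = (x_i − μ_i)² − x_i on μ_i (no intercept)
  gives α̂ = Σμy/Σμ²; the statistic studentizes with the *null* variance
  Var(y_i) = 2μ_i², i.e. z = Σμ_i y_i / √(2Σμ_i⁴). The common plug-in
  (estimated residual variance, as in R's AER) is left-skewed at m = 200
  — measured type-I 0.024–0.028 at nominal 0.05 — because the numerator and
  the variance estimate are correlated for skewed y; the null-variance form
  measures 0.052–0.059. Per-entry means μ_i = λ̂_i by default (heterogeneous
  null); a pooled-mean mode reproduces the classic single-sample test.
* **Zero-inflation test.** Π = observed zero fraction; null expectation
  (1/m) Σ e^{-λ̂_i}, null variance (1/m²) Σ e^{-λ̂_i}(1 − e^{-λ̂_i}) from the
  Bernoulli indicators; one-sided Gaussian inference for excess zeros. If
  every rate is so large that e^{-λ̂} underflows, the test reports p = 1
  with a degenerate-null flag.
* **Q-Q envelopes.** Observed order statistics against Poisson
  mid-quantiles (quantiles of (i−½)/m, chosen for symmetry with the
  averaged CDF); the band is the pointwise [2.5%, 97.5%] range of sorted
  simulated samples. Percentile rather than min–max bands keep the band
  width stable in the number of simulations; the width is configurable.

One-sided alternatives throughout (over-dispersion α > 0, excess zeros),
since under-dispersion and zero deflation are not the failure modes of
interest for droplet data.

**Familywise control in the battery.** A "battery" run (three tests × up
to four targets) at per-test level 0.05 would falsely reject a correct
model ~22% of the time; `battery_accepts` therefore applies a Bonferroni
threshold α/n_tests across the battery. Mixture alternatives reject at
p ~ 1e-30, so power is unaffected. Individual reports keep raw p-values.

## GLM-PCA

The rate model log λ_gc = log n_c + α_g + Σ_l ξ_gl ρ_cl is maximized by
blockwise damped Newton: per-gene coefficient updates (shared design
[1, ρ]) then per-cell updates (design ξ), each batched across units with
per-unit step halving, so the total deviance trace is monotone by
construction. Initialization: α at its L=0 closed form
α_g = log(Σ_c x_gc / Σ_c n_c), factors from N(0, 1e-3²) noise under the
given seed — the fit starts essentially at the null model, which also makes
the converged likelihood at L > 0 at least the L = 0 likelihood. Defaults:
tol = 1e-6 relative deviance, max_iter = 200; non-convergence is recorded
on the fit and warned about, not raised. The ξρᵀ factorization is rotation
invariant and deliberately not identified — only the implied rates are
consumed downstream.

`select_L` returns the smallest candidate dimension whose rate fit passes
the battery, or None if all fail. This encodes the trial-and-error
principle for choosing L: too few dimensions leave cluster structure in
the residuals (the battery rejects), too many overfit. On homogeneous
synthetic data L = 0 is accepted; on a two-type mixture the accepted L is
strictly larger; a mixture restricted to candidate [0] yields None.

## Clustering (Hclust-Departure)

At each node: refit the two-way baseline on the node's cells (genes
all-zero within the node are dropped for that node only), recompute
departures, bisect the cells by Ward/Euclidean agglomeration cut at k = 2,
and test the split. Recursion continues only while splits are significant,
depth < J and both children could still be split meaningfully; a node with
fewer than 2S cells is never tested (neither child could reach S), and a
child below 2S becomes a leaf at its own turn. Leaves are named by their
binary path from the root. Identical inputs and seed give byte-identical
JSON trees (per-node seeds are spawned deterministically from the root
seed). Depth (not total split count) is what J bounds, capping the tree at
2^J leaves. No correction is applied across the many split tests; each
node's p-value answers its own local question, and the explicit stop rules
are the over-splitting guard.

**Split significance.** A SigClust-style Monte-Carlo test: the statistic is
the 2-cluster index CI = within-split SS / total SS; the null is a single
multivariate Gaussian whose covariance *spectrum* equals the eigenvalues of
the node's sample covariance, each floored at the median per-gene variance,
simulated on independent coordinates (CI and Ward clustering are rotation
invariant, so only the spectrum matters). Each null draw goes through the
same cut-then-score procedure, and p = (1 + #{null CI ≤ observed}) /
(1 + n_mc). Matching the spectrum rather than per-coordinate variances is
essential: the leading principal directions of even a homogeneous sample
exceed any axis-aligned variance, and a null that ignores them rejects
homogeneous departure data 23–35% of the time, versus ~0 with the spectral
null (spherical-Gaussian rejection ≤ 0.05 nominal measured at 0.00, power
1.0 at 10-σ planted separation). The variance floor guards near-constant
coordinates (genes with tiny rates). The cut is made before the test (the
alternative — testing merge heights — is a sigclust2 refinement not
adopted here). n_mc defaults to 100 (p resolution 1/101), a desk-scale
trade-off; raise it for final analyses.

**Markers.** Between two cell groups, each gene's departures are compared
with the two-sample t-test when both groups have ≥ 30 cells, the Wilcoxon
rank-sum test otherwise, followed by Benjamini–Hochberg adjustment.
Categories: *red* (adjusted p < 0.05 and |mean departure difference| > 4),
*orange* (significant, smaller shift), *black* (not significant). A gene
with zero variance in both groups gets p = 1 and a degeneracy flag.

## Crafted experiments

Library-size magnification perturbs every entry by sign(β̂_c)·p_gc with
p_gc ~ Poisson(|e^{μ̂+α̂_g+(1+F)β̂_c} − λ̃_gc|), truncated at zero; F = 0 is
the identity because the rate collapses to zero. sign(0) is taken as +1
(inert, since the rate is then zero). Cluster planting adds
Poisson(F·λ̃_gc) counts on the block of top-total genes × randomly chosen
cells (gene ties broken by row order; cells sampled without replacement;
one RNG stream per (seed, F, replicate)). Recovery is scored with the
permutation-model adjusted Rand index and purity (whose all-singletons
pathology is documented); `sweep` emits per-replicate scores and
mean ± sd per F. The pipeline argument is a plain callable
(counts → labels), so external clustering methods can be benchmarked
without becoming dependencies.

## Synthetic data

Counts are drawn from λ_gc = exp(μ + α_g + β_c + δ_{g,k(c)}): Gaussian
gene/cell effects recentred so the identifiability constraints hold
*exactly* (making the truth directly comparable with the closed-form
estimates), plus cluster-specific log-fold offsets δ on designated gene
sets. Cell-cluster sizes follow deterministic largest-remainder rounding —
fractions 0.1/0.3/0.6 at C = 200 give exactly 20/60/120. Noise models:
Poisson, negative binomial (Var = λ + λ²/size; over-dispersed positive
control) and zero-inflated Poisson (structural zeros with probability π₀).

Defaults: α_sd = 1.5, β_sd = 0.4, μ = −2.2, which yields ~92% zeros —
droplet-like sparsity. What the generator does *not* emulate: ambient RNA,
barcode collisions, gene–gene correlation beyond cluster structure, and
batch effects; passing tests say nothing about robustness to those.

Two depth regimes are used deliberately. The homogeneous negative control
runs at the droplet-like default. The clustered fixtures (`two_types`,
`three_types_136`) and the crafted-experiment benchmarks run at μ = 0
(~60% zeros), emulating deeply sequenced plate-based experiments: at 92%
zeros a log-4 shift on 10% of genes is not recoverable by *any* method —
even a Ward split restricted to the true marker genes reaches only
ARI ≈ 0.47 — whereas at plate depth the pipeline recovers planted types
exactly. The `doubletlike` fixture sums two independent cells' draws;
the result is still Poisson entrywise but with a rate surface no single
two-way fit matches, which is what the dispersion diagnostic detects.

## Problem sizes and reproducibility

The validation experiments (tests and `scripts/acceptance.py`) use:
50 random ≤6×6 matrices for the MLE cross-check; x ∈ [0,200] ×
λ ∈ {0.01…1e4} for departure accuracy; 1000 replicates at m = 200 for test
calibration; 100–500 replicates for power; 100 seeded homogeneous runs
(G=300, C=120) for the negative control; fixtures of 300–400 genes and
120–200 cells for planted-type recovery; and a G=600, C=250 base with a
60-gene × 110-cell planted block, 5–10 replicates per F ∈ {0, 0.5, 1, 2},
for the crafted sweep. These sizes were chosen to make every experiment
rerunnable on a laptop in minutes; all randomness flows from a single seed
(SeedSequence-spawned per experiment), and identical seeds reproduce every
number exactly.

## Known limitations

* The Poisson assumption is for UMI-collapsed counts; read counts without
  UMIs are over-dispersed by PCR amplification and will fail the battery.
* The split test's Gaussian null is a convenient surrogate for "one
  homogeneous population of departure vectors"; heavy-tailed departures at
  extreme sparsity make it conservative rather than anti-conservative, but
  it is a model choice, not an exact null.
* Very sparse data (≳90% zeros) carry little per-cell information; cluster
  recovery there requires many more cells than the desk-scale fixtures.
* p-values across the recursive tree are not corrected for multiplicity.
* The KS p-value is conservative for discrete data by construction; treat
  it as a screen, not a calibrated test.
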