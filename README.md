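# dipd — independent-Poisson departures for UMI count matrices

`dipd` models every entry x<sub>gc</sub> of a genes × cells UMI count matrix
as its own Poisson random variable, and turns the question "which cells are
alike?" into "which counts depart from a homogeneous Poisson baseline?".
It is aimed at single-cell analysts who want a clustering pipeline without
feature selection or resolution tuning, and at method developers who need
per-entry goodness-of-fit diagnostics for count models.

## The model

A crude two-way log-linear baseline captures gene- and cell-level (library
size) variation only:

    λ̃_gc = exp(μ + α_g + β_c),     Σ_g e^{α_g} = G,  Σ_c e^{β_c} = C

with the closed-form MLE μ̂ = log(ΣΣx/(G·C)), α̂_g = log(row mean) − μ̂,
β̂_c = log(column mean) − μ̂. Everything biologically interesting — cell
types, states, doublets — lives in the *departure* of each count from this
baseline, measured by the averaged (mid-distribution) Poisson CDF

    F̃(x; λ) = ( P(X ≤ x) + P(X < x) ) / 2,

which has mean exactly ½ under the true model, then mapped through a logit
(clamped to [10⁻¹⁰, 1−10⁻¹⁰]). The resulting dense matrix D replaces the
sparse counts: unexpectedly small counts become large negative values,
unexpectedly large counts large positive ones.

On top of this representation the package provides:

* **Hclust-Departure** — recursive Ward/Euclidean bisection of cells with a
  SigClust-style Monte-Carlo significance gate at every split; the baseline
  is refit inside each subcluster. Stops on non-significance, maximum depth
  J (default 10, so ≤ 2¹⁰ leaves) or minimum cluster size S (default 10).
  The significance level is the only substantive tunable.
* **Poissoneity diagnostics** — aggregate the 200 entries whose estimated
  rates are nearest a target λ₀ and test them with a KS distance, the
  Cameron–Trivedi over-dispersion score test (Var = (1+α)λ, α > 0), a
  zero-inflation test on the observed zero fraction Π, and Q-Q envelope
  plots with simulated variation bands.
* **Poisson GLM-PCA** — a minimal latent-factor rate model
  log λ_gc = log n_c + α_g + Σ_l ξ_gl ρ_cl used to estimate per-entry rates
  for the diagnostics, with an automatic latent-dimension search.
* **Crafted experiments** — controlled perturbations of real or synthetic
  data (library-size magnification; planted Poisson clusters of strength F)
  scored by adjusted Rand index and purity.
* **Synthetic data** — generators for homogeneous, clustered, doublet-like,
  over-dispersed and zero-inflated count matrices with known truth.

## Worked example

```python
from dipd import (filter_counts, fit_twoway, dipd, hclust_departure,
                  departure_markers, adjusted_rand_index)
from dipd.synthetic import fixture

m, truth = fixture("two_types")       # 2 planted cell types, log-4 shift
m = filter_counts(m)                  # 296 genes x 120 cells, 61.6% zeros

fit = fit_twoway(m)                   # mu = 0.139
D = dipd(m, fit)                      # departures in [-15.11, 14.90]

tree = hclust_departure(m, seed=0)
print(tree.n_leaves)                  # 2
print(tree.root.p_value)              # 0.0099  (split is significant)
labels = tree.labels()
print(adjusted_rand_index(labels.values, truth))   # 1.0

leaves = tree.leaves()
table = departure_markers(D, leaves[0].cell_indices, leaves[1].cell_indices)
print(table["category"].value_counts().to_dict())
# {'black': 235, 'orange': 57, 'red': 4}
```

The root split has Monte-Carlo p = 0.0099 (the smallest value 1/(1+n_mc)
can resolve at n_mc = 100), both children are homogeneous (p = 1.0), and
the two leaves reproduce the planted types exactly (ARI = 1). The marker
table flags 4 genes as "red" — FDR-adjusted p < 0.05 *and* mean departure
difference beyond ±4 (the strongest, g0012, shifts by −9.3) — and 57 as
"orange" (significant but smaller shift).

The same steps are available from the shell:

```bash
dipd simulate --g 300 --c 120 --out-dir sim/
dipd cluster sim/ --out-labels labels.tsv --out-tree tree.json
dipd depart sim/ -o D.csv --pcs 15      # departure matrix for external tools
dipd gof sim/ --glmpca-L 0,1,2,5 -o gof.tsv
```

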