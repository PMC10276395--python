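"""Synthetic UMI matrices with known ground truth.

Counts are drawn entrywise from a log-linear rate surface

    lambda_gc = exp( mu + alpha_g + beta_c + delta_{g, k(c)} ),

the two-way baseline extended with optional cluster-specific gene offsets
delta (cell c belongs to cluster k(c); delta is non-zero only on each
cluster's affected gene set).  Gene and cell effects are drawn Gaussian and
then recentred so that sum e^alpha = G and sum e^beta = C hold exactly,
making the true parameters directly comparable with the closed-form
estimates.  Noise models: plain Poisson, negative binomial (over-dispersed
positive control) and zero-inflated Poisson.

Defaults emulate sparse droplet data: alpha_sd = 1.5, beta_sd = 0.4 and
mu = -2.2, which puts the zero fraction near 90%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .counts_io import CountMatrix

RATE_OVERFLOW = 1e6


@dataclass(eq=False)
class ClusterSpec:
    """One planted cell cluster: fraction of cells, affected genes, log-fold offset."""

    fraction: float
    genes: np.ndarray   # gene indices carrying the offset
    delta: float        # log-fold change on those genes


@dataclass(eq=False)
class SyntheticSpec:
    G: int
    C: int
    mu: float = -2.2
    alpha_sd: float = 1.5
    beta_sd: float = 0.4
    clusters: list[ClusterSpec] = field(default_factory=list)
    noise: str = "poisson"       # "poisson" | "negbin" | "zip"
    negbin_size: float = 1.0     # NB dispersion (Var = lam + lam^2/size)
    zip_pi0: float = 0.0         # structural-zero probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clusters:
            total = sum(c.fraction for c in self.clusters)
            if not np.isclose(total, 1.0):
                raise ValueError(f"cluster fractions sum to {total}, expected 1")
        if self.noise not in ("poisson", "negbin", "zip"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def _recentre(effects: np.ndarray) -> np.ndarray:
    """Shift so that sum(exp(effects)) equals len(effects) exactly."""
    return effects - np.log(np.exp(effects).mean())


def _cluster_sizes(fractions: Sequence[float], C: int) -> list[int]:
    """Largest-remainder rounding of C * fractions (deterministic, sums to C)."""
    raw = np.asarray(fractions) * C
    sizes = np.floor(raw).astype(int)
    remainder = C - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes.tolist()


def generate(spec: SyntheticSpec) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Draw a count matrix from *spec*.

    Returns (counts, truth labels per cell, true rate matrix).  Labels are
    cluster indices (all zero when no clusters are planted).
    """
    rng = np.random.default_rng(spec.seed)
    alpha = _recentre(rng.normal(0.0, spec.alpha_sd, size=spec.G))
    beta = _recentre(rng.normal(0.0, spec.beta_sd, size=spec.C))
    log_rate = spec.mu + alpha[:, None] + beta[None, :]

    labels = np.zeros(spec.C, dtype=int)
    if spec.clusters:
        sizes = _cluster_sizes([c.fraction for c in spec.clusters], spec.C)
        start = 0
        for k, (cl, size) in enumerate(zip(spec.clusters, sizes)):
            cells = slice(start, start + size)
            labels[cells] = k
            genes = np.asarray(cl.genes, dtype=int)
            if genes.size:
                log_rate[np.ix_(genes, np.arange(spec.C)[cells])] += cl.delta
            start += size

    rates = np.exp(log_rate)
    if rates.max() > RATE_OVERFLOW:
        raise ValueError(
            f"maximum rate {rates.max():.3g} exceeds the overflow guard {RATE_OVERFLOW:g}"
        )
    if spec.noise == "poisson":
        values = rng.poisson(rates)
    elif spec.noise == "negbin":
        size = spec.negbin_size
        values = rng.negative_binomial(size, size / (size + rates))
    else:  # zip
        values = rng.poisson(rates)
        values[rng.random(rates.shape) < spec.zip_pi0] = 0
    gene_ids = [f"g{i:04d}" for i in range(spec.G)]
    cell_ids = [f"cell{j:04d}" for j in range(spec.C)]
    return CountMatrix(values, gene_ids, cell_ids), labels, rates


_FIXTURE_SEED = 20230

FIXTURE_NAMES = ("homogeneous_small", "two_types", "three_types_136", "doubletlike")


def fixture(name: str, seed: int = _FIXTURE_SEED) -> tuple[CountMatrix, np.ndarray]:
    """Deterministic named datasets covering the main test surfaces.

    homogeneous_small
        G=300, C=100, no clusters — negative control.
    two_types
        Equal mixture; the second type shifts 10% of genes by log 4.
        Plate-like depth (mu = 0, ~60% zeros), as in the deeply sequenced
        clonal-line positive controls.
    three_types_136
        Fractions 0.1 / 0.3 / 0.6, distinct marker blocks, log 4 offsets,
        plate-like depth.
    doubletlike
        Each cell is the sum of two independent homogeneous cells' draws —
        Poisson again entrywise, but with a mismatched rate structure.
    """
    rng = np.random.default_rng(seed)
    if name == "homogeneous_small":
        m, labels, _ = generate(SyntheticSpec(G=300, C=100, seed=seed))
        return m, labels
    if name == "two_types":
        G = 300
        marked = rng.choice(G, size=G // 10, replace=False)
        spec = SyntheticSpec(
            G=G, C=120, mu=0.0,
            clusters=[ClusterSpec(0.5, np.array([], dtype=int), 0.0),
                      ClusterSpec(0.5, marked, np.log(4.0))],
            seed=seed,
        )
        m, labels, _ = generate(spec)
        return m, labels
    if name == "three_types_136":
        G, C = 400, 200
        blocks = rng.permutation(G)[: 3 * (G // 10)].reshape(3, G // 10)
        spec = SyntheticSpec(
            G=G, C=C, mu=0.0,
            clusters=[ClusterSpec(0.1, blocks[0], np.log(4.0)),
                      ClusterSpec(0.3, blocks[1], np.log(4.0)),
                      ClusterSpec(0.6, blocks[2], np.log(4.0))],
            seed=seed,
        )
        m, labels, _ = generate(spec)
        return m, labels
    if name == "doubletlike":
        base = SyntheticSpec(G=300, C=200, seed=seed)
        m, _, _ = generate(base)
        half = m.n_cells // 2
        values = m.values[:, :half] + m.values[:, half: 2 * half]
        doublets = CountMatrix(values, list(m.gene_ids),
                               [f"dbl{j:04d}" for j in range(half)])
        return doublets, np.zeros(half, dtype=int)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
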