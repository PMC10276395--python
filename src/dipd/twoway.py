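"""Closed-form maximum likelihood for the two-way Poisson approximation.

The baseline model treats every UMI count as Poisson with a purely additive
log-rate

    log lambda_gc = mu + alpha_g + beta_c,

where alpha_g is a gene effect and beta_c a cell (library-size) effect.
Under the identifiability constraints sum_g e^{alpha_g} = G and
sum_c e^{beta_c} = C the MLE is available in closed form:

    mu_hat      = log( sum_gc x_gc / (G * C) )
    alpha_hat_g = log( row mean of gene g )   - mu_hat
    beta_hat_c  = log( column mean of cell c ) - mu_hat

All computation is done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .counts_io import CountMatrix


@dataclass(eq=False)
class TwoWayFit:
    """MLE of the additive two-way Poisson model."""

    mu: float
    alpha: np.ndarray  # (G,) gene effects, sum e^alpha = G
    beta: np.ndarray   # (C,) cell effects, sum e^beta = C

    @property
    def n_genes(self) -> int:
        return self.alpha.size

    @property
    def n_cells(self) -> int:
        return self.beta.size

    @cached_property
    def lambda_tilde(self) -> np.ndarray:
        """Implied rate matrix exp(mu + alpha_g + beta_c), shape (G, C)."""
        return np.exp(self.mu + self.alpha[:, None] + self.beta[None, :])

    def log_rate(self) -> np.ndarray:
        return self.mu + self.alpha[:, None] + self.beta[None, :]


def fit_twoway(m: CountMatrix) -> TwoWayFit:
    """Fit the two-way approximation by its closed-form MLE.

    Raises
    ------
    ValueError
        If any gene row or cell column has zero total (the log of its mean
        is -inf); run :func:`dipd.counts_io.filter_counts` first.
    """
    x = m.values
    G, C = x.shape
    row_tot = m.gene_totals.astype(float)
    col_tot = m.cell_totals.astype(float)
    if np.any(row_tot <= 0) or np.any(col_tot <= 0):
        raise ValueError(
            "zero row/column totals make the two-way MLE infinite; "
            "apply filter_counts before fitting"
        )
    total = float(row_tot.sum())
    mu = np.log(total) - np.log(G) - np.log(C)
    alpha = np.log(row_tot) - np.log(C) - mu
    beta = np.log(col_tot) - np.log(G) - mu
    return TwoWayFit(mu=float(mu), alpha=alpha, beta=beta)


def poisson_loglik(x: np.ndarray, lam: np.ndarray) -> float:
    """Poisson log-likelihood up to the x! term: sum(x log lam - lam)."""
    from scipy.special import xlogy

    return float(np.sum(xlogy(x, lam) - lam))


def score_residuals(m: CountMatrix, fit: TwoWayFit) -> tuple[np.ndarray, np.ndarray, float]:
    """Score equations at the fit: per-gene, per-cell and total (x - lambda) sums.

    All three are ~0 at the closed-form estimates.
    """
    resid = m.values - fit.lambda_tilde
    return resid.sum(axis=1), resid.sum(axis=0), float(resid.sum())
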