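"""Departure representation: logit of the averaged Poisson CDF.

A count's position within its baseline Poisson(lambda_tilde) is measured by
the mid-distribution (averaged) CDF

    F_tilde(x; lam) = ( P(X <= x) + P(X < x) ) / 2,

which maps unexpectedly small counts near 0 and unexpectedly large counts
near 1, and — unlike either one-sided CDF convention — has mean exactly 1/2
under the true model even for highly discrete small-lambda entries.  The
departure matrix D applies a logit transform, clamping F_tilde into
[1e-10, 1 - 1e-10] so the logit stays finite in double precision.

The Poisson CDF is evaluated through the regularized incomplete gamma
function (scipy), not naive pmf summation, so rates up to ~1e5 are fine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logit

from .counts_io import CountMatrix
from .twoway import TwoWayFit

CLAMP = 1e-10


@dataclass(eq=False)
class DepartureMatrix:
    """Continuous genes x cells matrix of departures D_gc."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def avg_cdf(x, lam):
    """Averaged (mid-distribution) Poisson CDF, elementwise.

    Parameters
    ----------
    x
        Non-negative integer count(s).
    lam
        Positive Poisson rate(s), broadcastable against ``x``.

    Returns
    -------
    (F(x) + F(x-1)) / 2 under Poisson(lam), with F(-1) = 0; strictly in (0, 1).
    """
    x = np.asarray(x)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("avg_cdf requires lam > 0")
    if np.any(x < 0) or not np.issubdtype(np.asarray(x).dtype, np.number):
        raise ValueError("avg_cdf requires integer x >= 0")
    upper = stats.poisson.cdf(x, lam)
    lower = np.where(x > 0, stats.poisson.cdf(x - 1, lam), 0.0)
    return (upper + lower) / 2.0


def departure_values(x, lam, clamp: float = CLAMP):
    """logit of the averaged CDF with the double-precision clamp applied."""
    f = avg_cdf(x, lam)
    f = np.clip(f, clamp, 1.0 - clamp)
    return logit(f)


def dipd(m: CountMatrix, fit: TwoWayFit) -> DepartureMatrix:
    """Departure matrix of *m* relative to its two-way baseline rates.

    D_gc = logit( F_tilde(x_gc; lambda_tilde_gc) ), clamped.  Output is
    dense on purpose: zeros at large expected rates become informative
    strongly negative departures.
    """
    if m.shape != (fit.n_genes, fit.n_cells):
        raise ValueError(
            f"shape mismatch: counts {m.shape} vs fit ({fit.n_genes}, {fit.n_cells})"
        )
    D = departure_values(m.values, fit.lambda_tilde)
    return DepartureMatrix(D, list(m.gene_ids), list(m.cell_ids))
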