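"""Minimal Poisson GLM-PCA for per-entry rate estimation.

Latent-factor Poisson model with cell-total offsets:

    log lambda_gc = log n_c + alpha_g + sum_l xi_gl * rho_cl

with gene intercepts alpha_g, factor scores xi (G x L) and loadings rho
(C x L).  It is fit by blockwise damped Newton (gene-wise coefficient
updates at fixed loadings, then cell-wise at fixed scores); each block step
is accepted only if it lowers that unit's Poisson deviance, so the total
deviance trace is monotone non-increasing.  Only the implied rate matrix is
consumed downstream — the xi*rho^T factorization is rotation-invariant and
reported as-is.

At L = 0 the model collapses to the analytic offset-intercept MLE
alpha_g = log( sum_c x_gc / sum_c n_c ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Sequence

import numpy as np
from scipy.special import xlogy

from .counts_io import CountMatrix

_ETA_MAX = 30.0  # exp(30) ~ 1e13; rates beyond this are unphysical for UMIs


@dataclass(eq=False)
class GlmPcaFit:
    gene_intercepts: np.ndarray      # (G,)
    scores: np.ndarray               # (G, L) xi
    loadings: np.ndarray             # (C, L) rho
    offsets: np.ndarray              # (C,) log n_c
    L: int
    deviance_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @cached_property
    def lambda_hat(self) -> np.ndarray:
        """Implied rates exp(log n_c + alpha_g + xi_g . rho_c), shape (G, C)."""
        eta = self.offsets[None, :] + self.gene_intercepts[:, None]
        if self.L > 0:
            eta = eta + self.scores @ self.loadings.T
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


def poisson_deviance(x: np.ndarray, lam: np.ndarray, axis=None):
    """2 * sum( x log(x/lam) - (x - lam) ); the x log x term is 0 at x = 0."""
    return 2.0 * np.sum(xlogy(x, x) - xlogy(x, lam) - (x - lam), axis=axis)


def _batched_newton_step(Y, X, offset, coef, max_halvings=30, ridge=1e-10):
    """One damped Newton step for U independent Poisson regressions.

    Y: (U, N) responses; X: (N, K) shared design; offset: (U, N);
    coef: (U, K).  Step-halving per unit on that unit's deviance guarantees
    no unit's deviance increases.
    """
    U, K = coef.shape
    eta = offset + coef @ X.T
    lam = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    grad = (Y - lam) @ X                                 # (U, K)
    hess = np.einsum("un,nk,nl->ukl", lam, X, X)         # (U, K, K)
    hess = hess + ridge * np.eye(K)[None, :, :]
    step = np.linalg.solve(hess, grad[:, :, None])[:, :, 0]
    dev0 = poisson_deviance(Y, lam, axis=1)
    t = np.ones(U)
    best = coef
    for _ in range(max_halvings):
        cand = coef + t[:, None] * step
        eta = offset + cand @ X.T
        lam = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        dev = poisson_deviance(Y, lam, axis=1)
        improved = dev <= dev0 + 1e-12
        best = np.where(improved[:, None], cand, best)
        if improved.all():
            break
        t = np.where(improved, t, t / 2.0)
    return best


def fit_glmpca(
    m: CountMatrix,
    L: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> GlmPcaFit:
    """Fit Poisson GLM-PCA with latent dimension *L* by alternating maximization.

    Initialization: gene intercepts at their L=0 closed form; scores and
    loadings from N(0, 1e-3^2) noise under *seed*, i.e. starting essentially
    at the null model.  Stops when the relative deviance change drops below
    *tol*; hitting *max_iter* records ``converged=False`` (a warning, not an
    error).
    """
    x = m.values.astype(float)
    G, C = x.shape
    if L < 0 or (L > 0 and L >= min(G, C)):
        raise ValueError(f"latent dimension L={L} must satisfy 0 <= L < min(G, C)")
    n_c = m.cell_totals.astype(float)
    if np.any(n_c <= 0) or np.any(m.gene_totals <= 0):
        raise ValueError("matrix has zero rows/columns; apply filter_counts first")
    offsets = np.log(n_c)
    alpha0 = np.log(m.gene_totals.astype(float)) - np.log(n_c.sum())

    if L == 0:
        lam = np.exp(offsets[None, :] + alpha0[:, None])
        dev = float(poisson_deviance(x, lam))
        return GlmPcaFit(alpha0, np.zeros((G, 0)), np.zeros((C, 0)), offsets,
                         0, [dev], True, 0)

    rng = np.random.default_rng(seed)
    alpha = alpha0.copy()
    xi = rng.normal(0.0, 1e-3, size=(G, L))
    rho = rng.normal(0.0, 1e-3, size=(C, L))

    def total_dev():
        eta = offsets[None, :] + alpha[:, None] + xi @ rho.T
        return float(poisson_deviance(x, np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))))

    trace = [total_dev()]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # gene block: per-gene coefficients [alpha_g, xi_g.], design [1, rho]
        Zg = np.hstack([np.ones((C, 1)), rho])
        coef = _batched_newton_step(x, Zg, np.broadcast_to(offsets, (G, C)),
                                    np.hstack([alpha[:, None], xi]))
        alpha, xi = coef[:, 0], coef[:, 1:]
        # cell block: per-cell loadings rho_c., design xi, offset log n_c + alpha_g
        off_cells = offsets[:, None] + alpha[None, :]
        rho = _batched_newton_step(x.T, xi, off_cells, rho)
        trace.append(total_dev())
        prev, cur = trace[-2], trace[-1]
        if prev - cur <= tol * max(abs(prev), 1.0):
            converged = True
            break
    if not converged:
        warnings.warn(f"GLM-PCA did not converge in {max_iter} sweeps", RuntimeWarning)
    return GlmPcaFit(alpha, xi, rho, offsets, L, trace, converged, it)


def select_L(
    m: CountMatrix,
    candidates: Sequence[int],
    gof: Callable[[CountMatrix, np.ndarray], bool] | None = None,
    alpha: float = 0.05,
    m_entries: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> int | None:
    """Smallest candidate latent dimension whose rate fit looks Poisson.

    For each L (ascending) the model is fit and the Poissoneity battery —
    KS, over-dispersion and zero-inflation tests on aggregated entries over
    a grid of target rates — is run on the fitted rates.  The first L with
    no rejection at level *alpha* is returned; ``None`` if every candidate
    fails.  A custom battery can be supplied as ``gof(counts, lambda_hat) ->
    bool`` (True = acceptable fit).
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if gof is None:
        from .gof import battery_accepts

        def gof(counts, lam_hat):
            return battery_accepts(counts.values, lam_hat, alpha=alpha,
                                   m=m_entries, seed=seed)

    for L in sorted(set(int(c) for c in candidates)):
        fit = fit_glmpca(m, L, seed=seed, **fit_kwargs)
        if gof(m, fit.lambda_hat):
            return L
    return None
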