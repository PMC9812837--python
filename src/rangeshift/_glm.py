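"""Internal least-squares / IRLS engines.

Two maximum-likelihood solvers over an explicit design matrix:

* ``gaussian_fit`` — OLS via ``numpy.linalg.lstsq`` with the profile-sigma
  negative log-likelihood ``(n/2) * (log 2pi + log(RSS/n) + 1)``.
* ``binomial_fit`` — iteratively reweighted least squares for a Bernoulli
  response with a logit link; deviance-change convergence and explicit
  separation detection (coefficient-norm divergence).

These are deliberately small and allocation-light: the breakpoint profile
search evaluates them thousands of times per fit. Both are cross-checked
against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .errors import RankDeficiencyError

_LOG_2PI = float(np.log(2.0 * np.pi))

# Floor on the Gaussian MLE variance, km^2 scale. Keeps the likelihood finite
# on interpolating (zero-residual) fits; anything at the floor is flagged
# degenerate.
_SIGMA2_FLOOR = 1e-24

# |linear predictor| beyond this is numerically saturated; sustained growth
# of the coefficient norm past it signals complete separation.
_ETA_MAX = 30.0


@dataclass
class GLMFit:
    """Result of one maximum-likelihood solve on a fixed design."""

    coef: np.ndarray
    cov: np.ndarray          # large-sample covariance of coef
    nll: float               # exact negative log-likelihood at the optimum
    n: int
    rank: int
    sigma: float | None = None   # Gaussian MLE residual SD
    df_resid: int = 0
    converged: bool = True
    n_iter: int = 0
    separated: bool = False
    degenerate: bool = False
    fitted: np.ndarray = field(default=None, repr=False)


def gaussian_fit(X: np.ndarray, y: np.ndarray, *, check_rank: bool = True) -> GLMFit:
    """Ordinary least squares with the profile-sigma Gaussian likelihood."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if check_rank and rank < p:
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {p} columns)"
        )
    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    nll = 0.5 * n * (_LOG_2PI + np.log(sigma2) + 1.0)
    degenerate = rss / n <= _SIGMA2_FLOOR * 10
    # Unbiased variance for Wald intervals; guard the saturated case.
    df = max(n - rank, 1)
    s2_unbiased = rss / df
    # (X'X)^-1 via QR: raw-year polynomial designs make the normal
    # equations numerically singular even though X itself is fine.
    if rank == p:
        _, R = np.linalg.qr(X)
        r_inv = solve_triangular(R, np.eye(p))
        xtx_inv = r_inv @ r_inv.T
    else:
        xtx_inv = np.linalg.pinv(X.T @ X)
    cov = s2_unbiased * xtx_inv
    return GLMFit(
        coef=coef,
        cov=cov,
        nll=float(nll),
        n=n,
        rank=int(rank),
        sigma=float(np.sqrt(sigma2)),
        df_resid=n - int(rank),
        degenerate=degenerate,
        fitted=fitted,
    )


def _bernoulli_nll(y: np.ndarray, eta: np.ndarray) -> float:
    # -sum[y*eta - log(1 + e^eta)] computed stably via logaddexp.
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def binomial_fit(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
    check_rank: bool = True,
) -> GLMFit:
    """Bernoulli-logit maximum likelihood by IRLS.

    Convergence is declared when the deviance changes by less than ``tol``.
    Complete separation is reported via ``separated=True`` (and
    ``converged=False``) rather than raising, so callers can decide whether a
    flagged fit is usable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if check_rank and np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError(
            f"design matrix is rank deficient ({p} columns)"
        )
    beta = np.zeros(p)
    eta = X @ beta
    dev = 2.0 * _bernoulli_nll(y, eta)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_MAX, _ETA_MAX)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError as exc:  # weights collapsed
            raise RankDeficiencyError(str(exc)) from exc
        eta = X @ beta_new
        dev_new = 2.0 * _bernoulli_nll(y, eta)
        delta = abs(dev - dev_new)
        beta = beta_new
        dev = dev_new
        # complete separation: linear predictors diverge (coefficient norm
        # escapes on the eta scale, which is invariant to column scaling)
        if np.max(np.abs(eta)) > 4 * _ETA_MAX:
            separated = True
            break
        if delta < tol:
            converged = True
            break
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_MAX, _ETA_MAX)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return GLMFit(
        coef=beta,
        cov=cov,
        nll=0.5 * dev,
        n=n,
        rank=p,
        df_resid=n - p,
        converged=converged,
        n_iter=it,
        separated=separated,
        fitted=mu,
    )


def fit_family(X: np.ndarray, y: np.ndarray, family: str, **kw) -> GLMFit:
    if family == "gaussian":
        return gaussian_fit(X, y, **kw)
    if family == "binomial":
        return binomial_fit(X, y, **kw)
    raise ValueError(f"unknown family {family!r}")
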