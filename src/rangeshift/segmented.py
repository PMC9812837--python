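"""Trend models with an optional breakpoint, for Gaussian and binomial responses.

The candidate mean structures for a response observed over years x are

* ``constant``        mu = b0
* ``linear``          mu = b0 + b1 x
* ``quadratic``       mu = b0 + b1 x + b2 x^2
* ``left_horizontal`` mu = b0 + g (x - psi)+          (flat, then a slope)
* ``two_slope``       mu = b0 + b1 x + g (x - psi)+   (one slope, then another)

with identity link for the Gaussian family and logit link for a Bernoulli
presence/absence response. ``(x - psi)+ = max(0, x - psi)`` is the hinge term;
``psi`` is the breakpoint year, estimated jointly with the slopes. The slope
left of the breakpoint is reported as "year 1" and the right slope
``year2 = year1 + gamma``.

The breakpoint is estimated by the iterative-linearization scheme of
segmented-regression practice: the design is augmented with
``U = (x - psi)+`` and ``V = -1[x > psi]``, the working fit yields an update
``psi <- psi + coef(V)/coef(U)``, and steps are damped until the update is
below tolerance. The iteration is started from a profile grid scan and the
final estimate is polished by bounded minimization of the profile negative
log-likelihood on each interval between adjacent distinct x values, so the
reported optimum is the global profile optimum. SE(psi) comes from the
delta-method ratio of the V-term standard error to the hinge slope.

:class:`TrendRegression` is a scikit-learn style estimator (``fit`` /
``predict`` / ``get_params``); the module-level functions are thin wrappers
around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from ._glm import GLMFit, binomial_fit, fit_family, gaussian_fit
from .errors import (
    BoundaryConvergenceError,
    InsufficientDataError,
    InvalidConfigurationError,
    RankDeficiencyError,
    TestUndefinedError,
)

__all__ = [
    "TrendRegression",
    "ScoreTestResult",
    "fit_baseline",
    "fit_segmented",
    "fit_suite",
    "profile_psi",
    "pscore_test",
    "pscore_bootstrap",
    "predict_trend",
]

FORMS = ("constant", "linear", "quadratic", "left_horizontal", "two_slope")
FAMILIES = ("gaussian", "binomial")
_FAMILY_ALIASES = {
    "gaussian": "gaussian",
    "gaussian_identity": "gaussian",
    "normal": "gaussian",
    "binomial": "binomial",
    "binomial_logit": "binomial",
    "bernoulli": "binomial",
}

LABELS = {
    "constant": "Constant",
    "linear": "Linear",
    "quadratic": "Quadratic",
    "left_horizontal": "Left-horizontal",
    "two_slope": "Two-slope",
}

#: mean-structure parameter count as printed in comparison tables
#: (includes the breakpoint for segmented forms, never the Gaussian variance)
NP_PRINTED = {
    "constant": 1,
    "linear": 2,
    "quadratic": 3,
    "left_horizontal": 3,
    "two_slope": 4,
}

_SEGMENTED = ("left_horizontal", "two_slope")


def _canon_family(family: str) -> str:
    try:
        return _FAMILY_ALIASES[family]
    except KeyError:
        raise InvalidConfigurationError(f"unknown family {family!r}") from None


def _as_x(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("X must be one covariate: shape (n,) or (n, 1)")
    return x


def _design(form: str, x: np.ndarray, psi: float | None = None,
             with_v: bool = False) -> np.ndarray:
    one = np.ones_like(x)
    if form == "constant":
        return one[:, None]
    if form == "linear":
        return np.column_stack([one, x])
    if form == "quadratic":
        return np.column_stack([one, x, x * x])
    u = np.maximum(x - psi, 0.0)
    cols = [one, u] if form == "left_horizontal" else [one, x, u]
    if with_v:
        cols.append(-(x > psi).astype(float))
    return np.column_stack(cols)


def _conditional_fit(x, y, family, form, psi, with_v=False) -> GLMFit:
    X = _design(form, x, psi, with_v=with_v)
    return fit_family(X, y, family, check_rank=False)


def _admissible_range(x: np.ndarray, form: str) -> tuple[float, float]:
    # The breakpoint is confined to the closed interval
    # [2nd distinct x, 2nd-to-last distinct x]: beyond it one segment rests
    # on a single design point, where the two-slope profile is exactly flat
    # (slope and breakpoint trade off) and a hinge fit is unstable. This
    # subsumes the (min + eps, max - eps) rule with eps = half the smallest
    # gap between distinct x values.
    xs = np.unique(x)
    if len(xs) < 4:
        raise InsufficientDataError(
            f"{form} requires at least 4 distinct x values, got {len(xs)}"
        )
    lo, hi = xs[1], xs[-2]
    if not lo < hi:
        raise InsufficientDataError("no admissible breakpoint range")
    return float(lo), float(hi)


def _profile_nll(x, y, family, form):
    def nll(psi):
        return _conditional_fit(x, y, family, form, psi).nll

    return nll


def _grid_candidates(x, lo, hi, n_grid):
    qs = np.quantile(x, (np.arange(n_grid) + 1) / (n_grid + 1))
    xs = np.unique(x)
    interior = xs[(xs > lo) & (xs < hi)]
    edges = np.concatenate([[lo], interior, [hi]])
    mids = 0.5 * (edges[:-1] + edges[1:])
    return np.unique(np.clip(np.concatenate([qs, mids, [lo, hi]]), lo, hi))


def _muggeo_iterate(x, y, family, form, psi, lo, hi, tol, max_iter, damping):
    iu = 1 if form == "left_horizontal" else 2
    converged = False
    it = 0
    # keep the working psi off the closed endpoints: there U and V can be
    # exactly collinear (single design point beyond the breakpoint)
    nudge = 1e-6 * (hi - lo)
    psi = float(np.clip(psi, lo + nudge, hi - nudge))
    for it in range(1, max_iter + 1):
        try:
            f = _conditional_fit(x, y, family, form, psi, with_v=True)
        except RankDeficiencyError:
            break
        gamma, delta = f.coef[iu], f.coef[iu + 1]
        if abs(gamma) < 1e-12:
            break
        step = delta / gamma
        max_step = 0.5 * (hi - lo)
        while abs(step) > max_step:
            step *= damping
        new = float(np.clip(psi + step, lo + nudge, hi - nudge))
        if abs(new - psi) < tol:
            psi = new
            converged = True
            break
        psi = new
    return psi, it, converged


def _segmented_search(
    x, y, family, form, *, psi0="auto", tol=1e-8, max_iter=100,
    damping=0.5, n_grid=10, boundary="flag",
):
    """Locate the profile-NLL optimum over the closed admissible psi range.

    Returns ``(psi_hat, fit_at_psi, n_iter, converged, at_bound)``.
    ``boundary="raise"`` turns an endpoint optimum into
    :class:`BoundaryConvergenceError`; the default flags it.
    """
    lo, hi = _admissible_range(x, form)
    nll = _profile_nll(x, y, family, form)
    if psi0 == "auto":
        cand = _grid_candidates(x, lo, hi, n_grid)
        vals = [nll(p) for p in cand]
        psi_start = float(cand[int(np.argmin(vals))])
    else:
        psi_start = float(np.clip(psi0, lo, hi))
    psi_it, n_iter, converged = _muggeo_iterate(
        x, y, family, form, psi_start, lo, hi, tol, max_iter, damping
    )
    # Polish: bounded search on every interval between adjacent distinct x
    # (global, since the profile can be multimodal across intervals), plus
    # the closed endpoints themselves.
    xs = np.unique(x)
    interior = xs[(xs > lo) & (xs < hi)]
    edges = np.concatenate([[lo], interior, [hi]])
    intervals = list(zip(edges[:-1], edges[1:]))
    if len(intervals) > 32:
        keep = set()
        for c in (psi_it, psi_start):
            for i, (a, b) in enumerate(intervals):
                if a <= c <= b:
                    keep.add(i)
        order = np.argsort([nll(0.5 * (a + b)) for a, b in intervals])
        keep.update(order[:8])
        intervals = [intervals[i] for i in sorted(keep)]
    best_psi, best_nll = psi_it, nll(psi_it)
    for cand in (lo, hi):
        v = nll(cand)
        if v < best_nll - 1e-12:
            best_psi, best_nll = cand, v
    for a, b in intervals:
        span = b - a
        res = minimize_scalar(
            nll, bounds=(a + 1e-12 * max(1, abs(a)), b - 1e-12 * max(1, abs(b))),
            method="bounded", options={"xatol": min(1e-10, 1e-6 * span)},
        )
        if res.fun < best_nll - 1e-12 or (
            res.fun < best_nll + 1e-12 and abs(res.x - psi_it) < abs(best_psi - psi_it)
        ):
            best_psi, best_nll = float(res.x), float(res.fun)
    btol = 1e-6 * (hi - lo)
    at_bound = best_psi <= lo + btol or best_psi >= hi - btol
    if at_bound:
        best_psi = lo if best_psi <= lo + btol else hi
        if boundary == "raise":
            side = "left" if best_psi == lo else "right"
            raise BoundaryConvergenceError(side, best_psi)
    fit = _conditional_fit(x, y, family, form, best_psi)
    return best_psi, fit, n_iter, converged, at_bound


class TrendRegression(RegressorMixin, BaseEstimator):
    """One of the five candidate trend models, fitted by maximum likelihood.

    Parameters
    ----------
    form : {"constant", "linear", "quadratic", "left_horizontal", "two_slope"}
        Mean structure; the last two carry one breakpoint.
    family : {"gaussian", "binomial"}
        ``gaussian`` fits an identity-link normal model (distances);
        ``binomial`` a Bernoulli-logit model (presence/absence).
    psi0 : "auto" or float
        Breakpoint start value; "auto" uses a profile grid scan.
    tol, max_iter, damping, n_grid
        Controls of the breakpoint iteration (see module docstring).
    ci_level : float
        Level of the Wald confidence intervals (t-based for Gaussian).
    center : bool
        Fit the linear/quadratic forms on year centred at its mean for
        conditioning, back-transforming coefficients for reporting.

    Attributes (after ``fit``)
    --------------------------
    coef_, coef_names_, se_, ci_ : mean-structure estimates and Wald CIs
    psi_, psi_se_, psi_ci_ : breakpoint year (segmented forms, else None)
    sigma_ : Gaussian MLE residual SD (None for binomial)
    nll_ : exact negative log-likelihood at the optimum
    np_printed_, k_aicc_ : parameter counts (mean structure incl. psi;
        plus the variance for the Gaussian AICc count)
    n_, converged_, n_iter_, degenerate_ : bookkeeping
    """

    def __init__(self, form="linear", family="gaussian", psi0="auto",
                 tol=1e-8, max_iter=100, damping=0.5, n_grid=10,
                 ci_level=0.95, center=False, strict_interior=False):
        self.form = form
        self.family = family
        self.psi0 = psi0
        self.tol = tol
        self.max_iter = max_iter
        self.damping = damping
        self.n_grid = n_grid
        self.ci_level = ci_level
        self.center = center
        self.strict_interior = strict_interior

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        if self.form not in FORMS:
            raise InvalidConfigurationError(f"unknown form {self.form!r}")
        fam = _canon_family(self.family)
        x = _as_x(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("X and y lengths differ")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in the input")
        if fam == "binomial" and not np.isin(y, (0.0, 1.0)).all():
            raise InvalidConfigurationError("binomial response must be 0/1")
        n = len(x)
        np_printed = NP_PRINTED[self.form]
        k_aicc = np_printed + (1 if fam == "gaussian" else 0)
        if n < k_aicc + 2:
            raise InsufficientDataError(
                f"n = {n} too small for {self.form}/{fam} (need >= {k_aicc + 2})"
            )
        self.x_, self.y_, self.n_ = x, y, n
        self.family_ = fam
        self.np_printed_, self.k_aicc_ = np_printed, k_aicc
        self.n_features_in_ = 1
        if self.form in _SEGMENTED:
            self._fit_segmented(x, y, fam)
        else:
            self._fit_baseline(x, y, fam)
        self._finalize()
        return self

    def _fit_baseline(self, x, y, fam):
        # binomial polynomial designs are centred internally for IRLS
        # conditioning (raw-year quadratics are near-singular on that scale);
        # coefficients are always reported on the raw-year scale
        center = self.center or (fam == "binomial" and self.form != "constant")
        shift = float(np.mean(x)) if center else 0.0
        X = _design(self.form, x - shift)
        f = fit_family(X, y, fam)
        coef, cov = f.coef, f.cov
        if shift:
            T = self._center_jacobian(shift, len(coef))
            coef, cov = T @ coef, T @ cov @ T.T
        self._store(f, coef, cov, psi=None, aug=None, n_iter=f.n_iter,
                    converged=f.converged)

    @staticmethod
    def _center_jacobian(m, p):
        # back-transform coefficients of a polynomial in (x - m) to raw x
        T = np.eye(p)
        if p >= 2:
            T[0, 1] = -m
        if p >= 3:
            T[0, 2] = m * m
            T[1, 2] = -2 * m
        return T

    def _fit_segmented(self, x, y, fam):
        psi, f, n_iter, _, at_bound = _segmented_search(
            x, y, fam, self.form, psi0=self.psi0, tol=self.tol,
            max_iter=self.max_iter, damping=self.damping, n_grid=self.n_grid,
            boundary="raise" if self.strict_interior else "flag",
        )
        self.psi_at_bound_ = at_bound
        Xaug = _design(self.form, x, psi, with_v=True)
        aug = None
        if np.linalg.matrix_rank(Xaug) == Xaug.shape[1]:
            try:
                aug = fit_family(Xaug, y, fam, check_rank=False)
            except RankDeficiencyError:
                aug = None
        conv = True if fam == "gaussian" else (f.converged and not f.separated)
        # Coefficient covariance from the augmented working model (with the
        # V term), which propagates breakpoint uncertainty into slope SEs;
        # at an endpoint optimum the augmented design is singular and the
        # conditional covariance is reported with psi SE undefined.
        p = len(f.coef)
        cov = aug.cov[:p, :p] if aug is not None else f.cov
        self._store(f, f.coef, cov, psi=psi, aug=aug,
                    n_iter=n_iter, converged=conv)

    def _store(self, f: GLMFit, coef, cov, *, psi, aug, n_iter, converged):
        names = {
            "constant": ["intercept"],
            "linear": ["intercept", "year"],
            "quadratic": ["intercept", "year", "year2"],
            "left_horizontal": ["intercept", "gamma"],
            "two_slope": ["intercept", "year1", "gamma"],
        }[self.form]
        self.coef_names_ = names
        self.coef_ = np.asarray(coef, float)
        self.cov_ = np.asarray(cov, float)
        self.se_ = np.sqrt(np.clip(np.diag(self.cov_), 0, None))
        self.nll_ = f.nll
        self.sigma_ = f.sigma if self.family_ == "gaussian" else None
        self.degenerate_ = bool(f.degenerate)
        self.separated_ = bool(getattr(f, "separated", False))
        if self.separated_:
            warnings.warn(
                "complete separation detected; coefficients diverge",
                stacklevel=3,
            )
        self.converged_ = bool(converged)
        self.n_iter_ = int(n_iter)
        self.psi_ = psi
        if psi is not None:
            if aug is None:
                self.psi_se_ = np.inf
            else:
                iu = 1 if self.form == "left_horizontal" else 2
                gamma = aug.coef[iu]
                se_delta = float(np.sqrt(max(aug.cov[iu + 1, iu + 1], 0.0)))
                self.psi_se_ = (se_delta / abs(gamma)
                                if abs(gamma) > 1e-12 else np.inf)
        else:
            self.psi_se_ = None

    def _finalize(self):
        q = self._wald_q()
        lo = self.coef_ - q * self.se_
        hi = self.coef_ + q * self.se_
        self.ci_ = np.column_stack([lo, hi])
        if self.psi_ is not None:
            self.psi_ci_ = (self.psi_ - q * self.psi_se_,
                            self.psi_ + q * self.psi_se_)
        else:
            self.psi_ci_ = None

    def _wald_q(self) -> float:
        a = 0.5 * (1 + self.ci_level)
        if self.family_ == "gaussian":
            df = max(self.n_ - self.np_printed_, 1)
            return float(stats.t.ppf(a, df))
        return float(stats.norm.ppf(a))

    # -- derived quantities -------------------------------------------------

    @property
    def label_(self) -> str:
        return LABELS[self.form]

    def slopes_(self) -> dict:
        """"year 1"/"year 2" slopes with SEs: left and right of the breakpoint."""
        c = dict(zip(self.coef_names_, self.coef_))
        s = dict(zip(self.coef_names_, self.se_))
        if self.form == "left_horizontal":
            return {"year1": 0.0, "year1_se": None,
                    "year2": c["gamma"], "year2_se": s["gamma"]}
        if self.form == "two_slope":
            i1 = self.coef_names_.index("year1")
            ig = self.coef_names_.index("gamma")
            var2 = (self.cov_[i1, i1] + self.cov_[ig, ig]
                    + 2 * self.cov_[i1, ig])
            return {"year1": c["year1"], "year1_se": s["year1"],
                    "year2": c["year1"] + c["gamma"],
                    "year2_se": float(np.sqrt(max(var2, 0.0)))}
        return {}

    def predict(self, X):
        """Mean response at new years (probability scale for binomial)."""
        eta = self._linpred(_as_x(X))
        if self.family_ == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def _linpred(self, x):
        X = _design(self.form, x, self.psi_)
        return X @ self.coef_

    def predict_interval(self, X, level: float | None = None) -> pd.DataFrame:
        """Pointwise mean and Wald CI; binomial bounds mapped through expit."""
        x = _as_x(X)
        lo_x, hi_x = self.x_.min() - 50.0, self.x_.max() + 50.0
        if (x < lo_x).any() or (x > hi_x).any():
            warnings.warn(
                "prediction years extrapolate far beyond the observed range",
                stacklevel=2,
            )
        level = self.ci_level if level is None else level
        a = 0.5 * (1 + level)
        if self.family_ == "gaussian":
            df = max(self.n_ - self.np_printed_, 1)
            q = float(stats.t.ppf(a, df))
        else:
            q = float(stats.norm.ppf(a))
        Xd = _design(self.form, x, self.psi_)
        eta = Xd @ self.coef_
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", Xd, self.cov_, Xd), 0, None))
        lo, hi = eta - q * se, eta + q * se
        if self.family_ == "binomial":
            eta, lo, hi = (1 / (1 + np.exp(-v)) for v in (eta, lo, hi))
        return pd.DataFrame({"year": x, "mean": eta, "lower": lo, "upper": hi})

    def to_report(self) -> dict:
        """JSON-ready record of the fit: estimates, CIs, likelihood, controls."""
        rows = [
            {"parameter": nm, "estimate": float(c), "se": float(s),
             "ci_lower": float(l), "ci_upper": float(u)}
            for nm, c, s, (l, u) in zip(
                self.coef_names_, self.coef_, self.se_, self.ci_
            )
        ]
        if self.psi_ is not None:
            rows.insert(2 if self.form == "two_slope" else 1, {
                "parameter": "breakpoint_year", "estimate": float(self.psi_),
                "se": float(self.psi_se_), "ci_lower": float(self.psi_ci_[0]),
                "ci_upper": float(self.psi_ci_[1]),
            })
        return {
            "model": self.label_, "form": self.form, "family": self.family_,
            "parameters": rows,
            "slopes": self.slopes_(),
            "sigma": self.sigma_, "nll": float(self.nll_),
            "n": int(self.n_), "np": int(self.np_printed_),
            "k_aicc": int(self.k_aicc_),
            "converged": bool(self.converged_), "n_iter": int(self.n_iter_),
            "degenerate": bool(self.degenerate_),
            "control": {"tol": self.tol, "max_iter": self.max_iter,
                        "damping": self.damping, "n_grid": self.n_grid,
                        "ci_level": self.ci_level},
        }


# -- module-level wrappers --------------------------------------------------


def fit_baseline(x, y, form: str, family: str = "gaussian", **kw) -> TrendRegression:
    """Fit one of the non-breakpoint forms; returns the fitted estimator."""
    if form not in ("constant", "linear", "quadratic"):
        raise InvalidConfigurationError(f"{form!r} is not a baseline form")
    return TrendRegression(form=form, family=family, **kw).fit(x, y)


def fit_segmented(
    x, y, family: str = "gaussian", left_constrained: bool = True,
    psi0="auto", **control,
) -> TrendRegression:
    """Fit a one-breakpoint model; ``left_constrained`` fixes the left slope at 0."""
    form = "left_horizontal" if left_constrained else "two_slope"
    return TrendRegression(form=form, family=family, psi0=psi0, **control).fit(x, y)


def fit_suite(x, y, family: str = "gaussian", forms=FORMS, **kw) -> list:
    """Fit several forms to the same data; non-convergent fits are kept, flagged."""
    out = []
    for form in forms:
        est = TrendRegression(form=form, family=family, **kw)
        try:
            est.fit(x, y)
        except BoundaryConvergenceError:
            continue
        out.append(est)
    return out


def profile_psi(x, y, family="gaussian", left_constrained=True, psi_grid=None):
    """Exact conditional NLL at each candidate breakpoint of ``psi_grid``.

    Returns a DataFrame with columns ``psi`` and ``nll``. The grid minimum is
    an upper bound on the free fit's NLL; this is the oracle and initializer
    behind :func:`fit_segmented`.
    """
    if psi_grid is None or len(np.atleast_1d(psi_grid)) == 0:
        raise InvalidConfigurationError("psi_grid must be a non-empty sequence")
    fam = _canon_family(family)
    form = "left_horizontal" if left_constrained else "two_slope"
    x = _as_x(x)
    y = np.asarray(y, float)
    xs = np.unique(x)
    grid = np.atleast_1d(np.asarray(psi_grid, float))
    if (grid <= xs[0]).any() or (grid >= xs[-1]).any():
        raise InvalidConfigurationError(
            "psi_grid values must lie strictly inside the range of x"
        )
    nll = _profile_nll(x, y, fam, form)
    return pd.DataFrame({"psi": grid, "nll": [nll(p) for p in grid]})


# -- breakpoint existence test ----------------------------------------------


@dataclass(frozen=True)
class ScoreTestResult:
    """Pseudo-score test for the existence of one breakpoint."""

    statistic: float
    p_value: float
    K: int
    null_form: str
    family: str
    df: float | None = None

    def __post_init__(self):
        assert 0.0 <= self.p_value <= 1.0


def _score_covariate(x, K):
    psis = np.quantile(x, (np.arange(K) + 1) / (K + 1))
    xs = np.unique(x)
    psis = psis[(psis > xs[0]) & (psis < xs[-1])]
    if len(psis) == 0:
        raise TestUndefinedError("no interior candidate breakpoints")
    return np.mean(np.maximum(x[:, None] - psis[None, :], 0.0), axis=1), len(psis)


def pscore_test(
    x, y, family: str = "gaussian", left_constrained_null: bool = False,
    K: int = 10,
) -> ScoreTestResult:
    """Score-type test of "no breakpoint" against a one-breakpoint alternative.

    The candidate breakpoints are K quantiles of x, so their averaged hinge
    regressor is a fixed covariate; the statistic is its added-variable
    t statistic (exact under the Gaussian null) or Wald z (binomial). The null
    is the linear trend, or the constant when the alternative is the
    left-horizontal (flat-then-slope) model.
    """
    if K < 3:
        raise InvalidConfigurationError(f"K must be >= 3, got {K}")
    fam = _canon_family(family)
    x = _as_x(x)
    y = np.asarray(y, float)
    null_form = "constant" if left_constrained_null else "linear"
    s, k_used = _score_covariate(x, K)
    X0 = _design(null_form, x)
    X1 = np.column_stack([X0, s])
    if fam == "gaussian":
        f0 = gaussian_fit(X0, y)
        if f0.degenerate:
            raise TestUndefinedError("perfect null fit: residuals are zero")
        f1 = gaussian_fit(X1, y)
        if f1.degenerate:
            raise TestUndefinedError("perfect alternative fit")
        t = f1.coef[-1] / np.sqrt(f1.cov[-1, -1])
        df = f1.df_resid
        p = 2.0 * stats.t.sf(abs(t), df)
        return ScoreTestResult(float(t), float(p), k_used, null_form, fam, df)
    f1 = binomial_fit(X1, y)
    if f1.separated:
        raise TestUndefinedError("separation under the alternative")
    z = f1.coef[-1] / np.sqrt(f1.cov[-1, -1])
    p = 2.0 * stats.norm.sf(abs(z))
    return ScoreTestResult(float(z), float(p), k_used, null_form, fam, None)


def pscore_bootstrap(
    x, y, family: str = "gaussian", left_constrained: bool = True,
    n_boot: int = 999, seed: int = 0,
) -> ScoreTestResult:
    """Parametric-bootstrap likelihood-ratio test for one breakpoint.

    Simulates ``n_boot`` datasets from the fitted null (linear, or constant
    for the left-horizontal alternative), refits null and segmented models on
    each, and returns ``p = (1 + #{T* >= T}) / (n_boot + 1)``. Slower than
    :func:`pscore_test` but free of the candidate-averaging approximation.
    """
    fam = _canon_family(family)
    x = _as_x(x)
    y = np.asarray(y, float)
    form = "left_horizontal" if left_constrained else "two_slope"
    null_form = "constant" if left_constrained else "linear"
    rng = np.random.default_rng(seed)

    def lrt(yv):
        f0 = fit_family(_design(null_form, x), yv, fam, check_rank=False)
        _, f1, _, _, _ = _segmented_search(x, yv, fam, form, n_grid=8)
        return max(0.0, 2.0 * (f0.nll - f1.nll)), f0

    t_obs, f0 = lrt(y)
    if fam == "gaussian" and f0.degenerate:
        raise TestUndefinedError("perfect null fit: residuals are zero")
    mu = f0.fitted
    count = 0
    for _ in range(n_boot):
        if fam == "gaussian":
            yb = mu + f0.sigma * rng.standard_normal(len(x))
        else:
            yb = (rng.random(len(x)) < mu).astype(float)
        tb, _ = lrt(yb)
        if tb >= t_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (n_boot + 1.0)
    return ScoreTestResult(float(t_obs), float(p), n_boot, null_form, fam, None)


def predict_trend(fit: TrendRegression, x_new, level: float = 0.95) -> pd.DataFrame:
    """Mean trend with pointwise CIs at new years, from a fitted estimator."""
    if not getattr(fit, "converged_", False):
        raise InvalidConfigurationError(
            "cannot predict from a non-converged fit"
        )
    return fit.predict_interval(x_new, level=level)
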