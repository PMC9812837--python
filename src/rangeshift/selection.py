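"""Small-sample AIC model ranking.

AICc = 2*NLL + 2k + 2k(k+1)/(n - k - 1), where NLL is the negative
log-likelihood at the maximum and k the effective parameter count. The
counting convention follows the comparison-table convention of range-trend
suites: the printed "np" counts mean-structure parameters *including* the
breakpoint (constant 1, linear 2, quadratic 3, left-horizontal 3, two-slope
4); the Gaussian residual variance adds one to k for the correction but is
not printed, while the binomial family has no dispersion parameter, so
k = np. Note the likelihood column such tables label "-2LL" is numerically
the negative log-likelihood (-LL); it is labelled ``NLL`` here.

Akaike weights are w_i = exp(-dAICc_i / 2) / sum_j exp(-dAICc_j / 2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    IncomparableModelsError,
    InvalidConfigurationError,
    SmallSampleError,
)
from .segmented import FORMS, NP_PRINTED, _canon_family

__all__ = ["aicc", "effective_k", "akaike_weights", "akaike_table"]


def aicc(nll: float, k: int, n: int) -> float:
    """Second-order (small-sample corrected) Akaike information criterion."""
    if n <= k + 1:
        raise SmallSampleError(
            f"AICc undefined for n = {n}, k = {k} (need n > k + 1)"
        )
    return 2.0 * nll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def effective_k(form: str, family: str = "gaussian") -> tuple[int, int]:
    """(np_printed, k_aicc) for a model form and family.

    ``np_printed`` is the mean-structure count including the breakpoint;
    ``k_aicc`` adds 1 for the Gaussian variance and equals np for binomial.
    """
    if form not in FORMS:
        raise InvalidConfigurationError(f"unknown form {form!r}")
    np_printed = NP_PRINTED[form]
    k = np_printed + (1 if _canon_family(family) == "gaussian" else 0)
    return np_printed, k


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights from a vector of AICc values (order preserved)."""
    a = np.asarray(aicc_values, dtype=float)
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def akaike_table(fits, *, substantial_delta: float = 2.0) -> pd.DataFrame:
    """Rank fitted models by AICc with deltas and Akaike weights.

    ``fits`` are fitted :class:`~rangeshift.segmented.TrendRegression`
    estimators on identical data. Non-converged fits are retained in the
    table (``converged=False``) but excluded from the weight normalization.
    Rows are sorted by AICc, ties broken by np ascending; the ``substantial``
    flag marks dAICc <= 2 (an annotation, not a decision rule).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise InvalidConfigurationError("need at least two fitted models")
    n0 = fits[0].n_
    y0 = fits[0].y_
    for f in fits[1:]:
        if f.n_ != n0 or not np.array_equal(f.y_, y0):
            raise IncomparableModelsError(
                "models were not fitted to the same response"
            )
    rows = []
    for f in fits:
        rows.append({
            "Model": f.label_,
            "AICc": aicc(f.nll_, f.k_aicc_, f.n_),
            "NLL": f.nll_,
            "np": f.np_printed_,
            "k": f.k_aicc_,
            "converged": bool(f.converged_),
        })
    tab = pd.DataFrame(rows).sort_values(
        ["AICc", "np"], kind="mergesort"
    ).reset_index(drop=True)
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    w = np.zeros(len(tab))
    ok = tab["converged"].to_numpy()
    if ok.any():
        w[ok] = akaike_weights(tab.loc[ok, "AICc"])
    tab["w"] = w
    tab["substantial"] = tab["dAICc"] <= substantial_delta
    tab.attrs["n"] = n0
    return tab[["Model", "AICc", "dAICc", "w", "NLL", "np", "k",
                "converged", "substantial"]]
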