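"""Model-validation statistics.

The battery applied per response when validating a surrogate against
measurements: reduced chi-square, RMSE, mean bias error, mean percentage
error, sum of squared errors, absolute average relative deviation and the
coefficient of determination, plus Pearson correlation with a two-sided
t-test.

Conventions: chi-square divides the squared-error sum by N - n, where n is
the number of model constants (default 2, the value consistent with the
published per-response fit table at N = 15); MPE keeps the sign of the
deviations; MPE and AARD are reported in percent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["chi_square", "rmse", "mbe", "mpe", "sse", "aard", "r2",
           "fit_report", "pearson_r", "pearson_test"]

DEFAULT_N_CONSTANTS = 2


def _pair(x_exp, x_pre):
    x_exp = np.asarray(x_exp, dtype=float).ravel()
    x_pre = np.asarray(x_pre, dtype=float).ravel()
    if x_exp.size != x_pre.size:
        raise ValueError(f"length mismatch: {x_exp.size} vs {x_pre.size}")
    if x_exp.size == 0:
        raise ValueError("empty input")
    return x_exp, x_pre


def _require_nonzero(x_exp):
    zeros = np.flatnonzero(x_exp == 0)
    if zeros.size:
        raise ZeroDivisionError(
            f"relative metric undefined: experimental value is 0 at "
            f"index {zeros[0]}")


def sse(x_exp, x_pre) -> float:
    x_exp, x_pre = _pair(x_exp, x_pre)
    return float(np.sum((x_pre - x_exp) ** 2))


def rmse(x_exp, x_pre) -> float:
    x_exp, x_pre = _pair(x_exp, x_pre)
    return float(np.sqrt(np.mean((x_pre - x_exp) ** 2)))


def mbe(x_exp, x_pre) -> float:
    x_exp, x_pre = _pair(x_exp, x_pre)
    return float(np.mean(x_pre - x_exp))


def mpe(x_exp, x_pre) -> float:
    """Signed mean percentage error, in percent."""
    x_exp, x_pre = _pair(x_exp, x_pre)
    _require_nonzero(x_exp)
    return float(100.0 * np.mean((x_pre - x_exp) / x_exp))


def aard(x_exp, x_pre) -> float:
    """Absolute average relative deviation, in percent."""
    x_exp, x_pre = _pair(x_exp, x_pre)
    _require_nonzero(x_exp)
    return float(100.0 * np.mean(np.abs(x_exp - x_pre) / np.abs(x_exp)))


def chi_square(x_exp, x_pre, n_constants: int = DEFAULT_N_CONSTANTS) -> float:
    """Reduced chi-square: SSE / (N - n_constants)."""
    x_exp, x_pre = _pair(x_exp, x_pre)
    if x_exp.size <= n_constants:
        raise ValueError(
            f"chi-square undefined: N = {x_exp.size} <= n_constants = "
            f"{n_constants}")
    return sse(x_exp, x_pre) / (x_exp.size - n_constants)


def r2(x_exp, x_pre) -> float:
    """Coefficient of determination, 1 - SSE / SST about the mean."""
    x_exp, x_pre = _pair(x_exp, x_pre)
    sstot = float(np.sum((x_exp - x_exp.mean()) ** 2))
    if sstot == 0:
        raise ValueError("r2 undefined for a constant experimental vector")
    return 1.0 - sse(x_exp, x_pre) / sstot


def fit_report(x_exp, x_pre, n_constants: int = DEFAULT_N_CONSTANTS,
               response_names=None) -> pd.DataFrame:
    """All validation statistics, one row per response column."""
    x_exp = np.atleast_2d(np.asarray(x_exp, dtype=float))
    x_pre = np.atleast_2d(np.asarray(x_pre, dtype=float))
    if x_exp.shape != x_pre.shape:
        raise ValueError(f"shape mismatch: {x_exp.shape} vs {x_pre.shape}")
    if response_names is None:
        response_names = [f"y{j + 1}" for j in range(x_exp.shape[1])]
    rows = []
    for j, name in enumerate(response_names):
        e, p = x_exp[:, j], x_pre[:, j]
        rows.append({
            "response": name,
            "chi2": chi_square(e, p, n_constants),
            "rmse": rmse(e, p), "mbe": mbe(e, p), "mpe": mpe(e, p),
            "sse": sse(e, p), "aard": aard(e, p), "r2": r2(e, p),
            "N": e.size, "n_constants": n_constants,
        })
    return pd.DataFrame(rows).set_index("response")


def pearson_r(x, y) -> float:
    return pearson_test(x, y)[0]


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided significance.

    The p-value comes from the t-transform with len - 2 degrees of
    freedom.
    """
    x, y = _pair(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)
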