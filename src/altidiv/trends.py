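"""Altitudinal trend regressions.

Ordinary least-squares linear and quadratic fits of any per-plot metric on
altitude, with pointwise 95% confidence bands for the mean response and, for
quadratics, the vertex (the estimated optimum altitude, a maximum when the
curvature is negative and a minimum when positive).

Outlier exclusion is never automatic: callers declare the excluded plots and
the fit records them.  With the typical ten-plot gradient a quadratic leaves
seven residual degrees of freedom, so fits carry a small-sample warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["TrendFit", "fit_trend", "vertex"]

SMALL_SAMPLE_N = 12


@dataclass(frozen=True)
class TrendFit:
    """An OLS altitudinal trend fit.

    ``params`` are (intercept, slope[, curvature]); p-values are two-sided
    coefficient tests, plus the overall model F-test p.  For quadratics the
    vertex altitude −b/(2c) and fitted value there are filled in.
    """

    response: str
    degree: int
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    f_pvalue: float
    r_squared: float
    n: int
    excluded: tuple = ()
    vertex_altitude: float | None = None
    vertex_value: float | None = None
    vertex_kind: str | None = None
    _results: object = field(default=None, repr=False, compare=False)

    def predict(self, x) -> np.ndarray:
        X = _design(np.asarray(x, dtype=float), self.degree)
        return X @ self.params

    def confidence_band(self, x, alpha: float = 0.05) -> pd.DataFrame:
        """Pointwise CI of the mean response at the given altitudes."""
        X = _design(np.asarray(x, dtype=float), self.degree)
        pred = self._results.get_prediction(X).summary_frame(alpha=alpha)
        return pd.DataFrame(
            {"fit": pred["mean"].to_numpy(),
             "lo": pred["mean_ci_lower"].to_numpy(),
             "hi": pred["mean_ci_upper"].to_numpy()},
            index=np.asarray(x),
        )


def _design(x: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x, degree + 1, increasing=True)


def fit_trend(x, y, degree: int = 1, exclude=(), response: str = "y") -> TrendFit:
    """OLS fit of y on altitude x with degree 1 (linear) or 2 (quadratic).

    ``exclude`` lists positional indices of declared outliers; they are
    dropped before fitting and recorded on the result.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d arrays")
    exclude = tuple(int(i) for i in exclude)
    keep = np.ones(x.size, dtype=bool)
    for i in exclude:
        keep[i] = False
    x, y = x[keep], y[keep]

    n, k = x.size, degree + 1
    if n - k < 1:
        raise ValueError(f"need at least {k + 1} points for degree {degree}")
    X = _design(x, degree)
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient (constant x?)")
    if n < SMALL_SAMPLE_N:
        warnings.warn(
            f"trend fitted on only {n} points; inference is small-sample",
            stacklevel=2,
        )
    res = sm.OLS(y, X).fit()

    fit = TrendFit(
        response=response, degree=degree,
        params=res.params, bse=res.bse, pvalues=res.pvalues,
        f_pvalue=float(res.f_pvalue), r_squared=float(res.rsquared),
        n=n, excluded=exclude, _results=res,
    )
    if degree == 2 and fit.params[2] != 0:
        xv, yv, kind = _vertex_of(fit.params)
        object.__setattr__(fit, "vertex_altitude", xv)
        object.__setattr__(fit, "vertex_value", yv)
        object.__setattr__(fit, "vertex_kind", kind)
    return fit


def _vertex_of(params) -> tuple[float, float, str]:
    a, b, c = params
    xv = -b / (2.0 * c)
    return float(xv), float(a + b * xv + c * xv * xv), "min" if c > 0 else "max"


def vertex(fit: TrendFit) -> tuple[float, float, str]:
    """Vertex (optimum altitude, fitted value, 'min'/'max') of a quadratic fit."""
    if fit.degree != 2:
        raise ValueError("vertex requires a quadratic fit")
    if fit.params[2] == 0:
        raise ValueError("zero curvature: no vertex")
    return _vertex_of(fit.params)
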