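"""Ecological regression: area distance-to-active-facility on sociodemographics.

Ordinary least squares of each small area's distance (km) to its nearest
research-active facility on six area characteristics: mean age, % male,
% majority ethnicity, deprivation decile (1 = most deprived, one linear term),
rural flag and coastal/border flag.  Unweighted across areas with classical
standard errors; an optional population-weight column switches to WLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Regressor columns, in reporting order.
REGRESSORS = (
    "mean_age",
    "pct_male",
    "pct_ethnic_majority",
    "imd_decile",
    "rural",
    "coastal_border",
)


@dataclass
class EcoFit:
    """Fitted ecological model: coefficients, SEs, p-values and diagnostics."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    r2: float
    n: int
    response: str
    results: object = field(repr=False, default=None)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    def to_frame(self) -> pd.DataFrame:
        """Coefficient / standard error / p-value table, intercept last."""
        order = [c for c in self.params.index if c != "const"] + ["const"]
        return pd.DataFrame(
            {
                "coefficient": self.params[order],
                "standard_error": self.bse[order],
                "p_value": self.pvalues[order],
            }
        )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name columns involved in exact linear dependence (via QR)."""
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    names = ["const"] + list(X.columns)
    r = np.linalg.qr(arr, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


def fit_distance_model(
    data: pd.DataFrame,
    response: str = "d_active",
    regressors=REGRESSORS,
    weights: str | None = None,
) -> EcoFit:
    """OLS (or population-weighted WLS) of area distance on characteristics.

    ``data`` holds one row per area with the regressor columns and the
    response (km by default; pass a travel-time column for the minutes
    version).  Binary flags are coded 0/1; decile and percentages enter
    untransformed.  Raises on rank-deficient designs, naming the collinear
    columns.
    """
    regressors = list(regressors)
    missing = [c for c in regressors + [response] if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    X = data[regressors].astype(float)
    if len(X) <= len(regressors) + 1:
        raise ValueError("need more areas than regressors + intercept")
    if int(np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))) < len(regressors) + 1:
        cols = _collinear_columns(X)
        raise ValueError(f"rank-deficient design; collinear columns: {cols}")
    y = data[response].astype(float)
    Xc = sm.add_constant(X, has_constant="raise")
    if weights is None:
        model = sm.OLS(y, Xc)
    else:
        model = sm.WLS(y, Xc, weights=data[weights].astype(float))
    res = model.fit()  # classical (non-robust) covariance
    return EcoFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=res.conf_int(alpha=0.05),
        r2=float(res.rsquared),
        n=int(res.nobs),
        response=response,
        results=res,
    )
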