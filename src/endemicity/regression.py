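"""Multiple regression of per-area species richness on eight correlates.

The model is ordinary least squares of richness (optionally log-transformed)
on log(area), altitude and six bioclimatic summaries, reported as a
coefficient table plus the model-level F statistic, its p-value and the
adjusted R².  Area enters logged because species–area relationships are
conventionally modelled as richness increasing in log(area) with slope z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .incidence import COVARIATE_COLUMNS, validate_covariates

__all__ = [
    "PREDICTOR_ORDER",
    "CollinearityError",
    "build_design",
    "fit_ols",
    "RegressionResult",
    "RichnessRegression",
]

#: Predictors in reporting order; area is logged.
PREDICTOR_ORDER = ("log_area",) + COVARIATE_COLUMNS[1:]


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


def build_design(covariates: pd.DataFrame, richness, response_transform: str = "raw",
                 log_base: str = "e", drop_zero_richness: bool = False) -> pd.DataFrame:
    """Join covariates and richness into a regression design table.

    Areas present in only one of the two inputs are dropped with a warning.
    ``response_transform``: ``raw`` (counts), ``log`` (requires positive
    counts) or ``log1p``.  ``log_base``: ``e`` or ``10``, applied both to
    area and to a logged response.
    """
    cov = validate_covariates(covariates)
    rich = pd.Series(richness).astype(float)
    rich.index = rich.index.astype(str)
    if rich.index.has_duplicates:
        raise ValueError("duplicate area_id in richness")
    common = [a for a in cov.index if a in set(rich.index)]
    missing_cov = sorted(set(rich.index) - set(cov.index))
    missing_rich = sorted(set(cov.index) - set(rich.index))
    if missing_cov or missing_rich:
        warnings.warn(
            f"dropping areas without both richness and covariates "
            f"(no covariates: {missing_cov}; no richness: {missing_rich})",
            stacklevel=2)
    cov = cov.loc[common]
    y = rich.loc[common]
    if drop_zero_richness:
        keep = y > 0
        cov, y = cov[keep.to_numpy()], y[keep]
    if log_base not in ("e", "10"):
        raise ValueError("log_base must be 'e' or '10'")
    log = np.log if log_base == "e" else np.log10
    if (cov["area"] <= 0).any():
        bad = cov.index[cov["area"] <= 0].tolist()
        raise ValueError(f"cannot log non-positive area for: {bad}")
    if response_transform == "raw":
        resp = y
    elif response_transform == "log":
        if (y <= 0).any():
            raise ValueError(
                f"log response undefined for zero-richness areas: "
                f"{y.index[y <= 0].tolist()} (use log1p or drop_zero_richness)")
        resp = log(y)
    elif response_transform == "log1p":
        resp = log(1.0 + y)
    else:
        raise ValueError(f"unknown response_transform {response_transform!r}")
    design = pd.DataFrame(index=cov.index)
    design["richness"] = resp
    design["log_area"] = log(cov["area"])
    for col in COVARIATE_COLUMNS[1:]:
        design[col] = cov[col]
    return design


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit: per-predictor table plus model-level statistics.

    ``table`` rows follow :data:`PREDICTOR_ORDER` with the intercept last;
    columns are estimate, std_error, t_value, p_value.
    """

    table: pd.DataFrame
    fvalue: float
    f_pvalue: float
    rsquared: float
    rsquared_adj: float
    df_resid: int
    nobs: int
    sm_results: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = ["Species richness multiple regression", "=" * 60]
        with pd.option_context("display.float_format", "{:0.4g}".format):
            lines.append(self.table.to_string())
        lines += [
            "-" * 60,
            f"n = {self.nobs}, residual df = {self.df_resid}",
            f"F = {self.fvalue:.4g}, p = {self.f_pvalue:.3g}, "
            f"R^2 = {self.rsquared:.3f}, adjusted R^2 = {self.rsquared_adj:.3f}",
        ]
        return "\n".join(lines)


def _rank_check(X: pd.DataFrame):
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    kept = [np.ones(len(X))]
    bad = []
    for name in X.columns:
        cand = np.column_stack(kept + [X[name].to_numpy(float)])
        if np.linalg.matrix_rank(cand) == len(kept):
            bad.append(name)
        else:
            kept.append(X[name].to_numpy(float))
    raise CollinearityError(f"design matrix rank deficient; collinear columns: {bad}")


def fit_ols(design: pd.DataFrame, response: str = "richness") -> RegressionResult:
    """Ordinary least squares with an intercept.

    Standard errors use the unbiased residual variance; the model F tests
    all slopes jointly against the intercept-only model.  Rank-deficient
    designs raise :class:`CollinearityError` naming the collinear columns.
    """
    predictors = [c for c in design.columns if c != response]
    n, k = len(design), len(predictors)
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} observations, got {n}")
    X = design[predictors]
    _rank_check(X)
    res = sm.OLS(design[response].to_numpy(float),
                 sm.add_constant(X.to_numpy(float))).fit()
    names = predictors + ["(intercept)"]
    order = list(range(1, k + 1)) + [0]
    table = pd.DataFrame(
        {
            "estimate": res.params[order],
            "std_error": res.bse[order],
            "t_value": res.tvalues[order],
            "p_value": res.pvalues[order],
        },
        index=pd.Index(names, name="variable"),
    )
    return RegressionResult(table=table, fvalue=float(res.fvalue),
                            f_pvalue=float(res.f_pvalue),
                            rsquared=float(res.rsquared),
                            rsquared_adj=float(res.rsquared_adj),
                            df_resid=int(res.df_resid), nobs=int(res.nobs),
                            sm_results=res)


class RichnessRegression:
    """Model-style facade: covariates + richness in, OLS results out."""

    def __init__(self, covariates: pd.DataFrame, richness,
                 response_transform: str = "raw", log_base: str = "e",
                 drop_zero_richness: bool = False):
        self.design = build_design(covariates, richness,
                                   response_transform=response_transform,
                                   log_base=log_base,
                                   drop_zero_richness=drop_zero_richness)
        self.response_transform = response_transform
        self.log_base = log_base

    @classmethod
    def from_incidence(cls, covariates: pd.DataFrame, matrix, **kwargs):
        """Build using per-area richness counted from an incidence matrix."""
        return cls(covariates, matrix.richness(), **kwargs)

    def fit(self) -> RegressionResult:
        return fit_ols(self.design)
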