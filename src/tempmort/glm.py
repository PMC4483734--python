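"""Quasi-Poisson regression engine and design-matrix assembly.

Daily death counts Y_t are modelled with a log-link Poisson mean structure
and variance phi * mu (quasi-Poisson):

    log E[Y_t] = alpha + beta' W_t + ns(time, 7/year) + ns(rh, 3)
                 + dow dummies + holiday

where W_t is the exposure-lag cross-basis block.  Coefficients come from
IRLS (delegated to statsmodels' GLM); the dispersion phi is the Pearson
chi-square divided by the residual degrees of freedom, and the coefficient
covariance is phi * (X'WX)^-1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .basis import default_knots, ncs_basis
from .config import AnalysisConfig
from .crossbasis import CrossBasis
from .data_io import CalendarCovariates, MortalityTimeSeries

__all__ = [
    "FitResult",
    "RankDeficiencyError",
    "ConvergenceError",
    "assemble_design",
    "fit_quasipoisson",
    "fit_poisson_loglik",
    "deviance_explained",
    "qaic",
]


class RankDeficiencyError(ValueError):
    """Design matrix is not of full column rank."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class FitResult:
    """One fitted model: coefficients, scaled covariance and fit statistics."""

    params: np.ndarray
    cov: np.ndarray
    dispersion: float
    deviance: float
    null_deviance: float
    loglik: float
    df_residual: int
    rank: int
    n_obs: int
    column_names: list
    block_slices: dict = field(default_factory=dict)
    family: str = "quasipoisson"
    fitted: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def block_params(self, name: str) -> np.ndarray:
        return self.params[self.block_slices[name]]

    def block_cov(self, name: str) -> np.ndarray:
        s = self.block_slices[name]
        return self.cov[s, :][:, s]

    def to_json(self) -> str:
        return json.dumps({
            "family": self.family,
            "coefficients": dict(zip(self.column_names, map(float, self.params))),
            "se": dict(zip(self.column_names, map(float, self.se))),
            "dispersion": float(self.dispersion),
            "deviance": float(self.deviance),
            "null_deviance": float(self.null_deviance),
            "df_residual": int(self.df_residual),
            "n_obs": int(self.n_obs),
            "meta": self.meta,
        }, indent=2)


def _collinear_columns(X: np.ndarray, names) -> list:
    """Name columns beyond the numerical rank, via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in piv[rank:]]


def assemble_design(
    series: MortalityTimeSeries,
    cb: CrossBasis,
    covariates: CalendarCovariates,
    config: AnalysisConfig | None = None,
):
    """Assemble the Eq-style design: intercept | cross-basis | trend spline |
    humidity spline | day-of-week dummies | holiday flag.

    Rows are restricted to ``cb.usable_rows``.  Returns
    ``(X, column_names, block_slices, rows)``.  Zero-variance blocks (constant
    humidity, no holidays) are dropped with a warning rather than producing a
    rank-deficient design.
    """
    config = config or AnalysisConfig()
    rows = cb.usable_rows
    n_rows = len(rows)

    blocks: list[tuple[str, np.ndarray, list]] = []
    blocks.append(("intercept", np.ones((n_rows, 1)), ["intercept"]))
    cb_names = [f"cb_{j}_{k}" for j, k in cb.column_index]
    blocks.append(("crossbasis", cb.matrix, cb_names))

    # long-term trend: 7 df per year (rounded, floor 3), NCS in the day index
    trend_df = max(3, int(round(config.trend_df_per_year * series.n_years)))
    t = covariates.time_index.astype(float)
    trend_spec = default_knots(t, trend_df, equally_spaced=True)
    blocks.append((
        "trend", ncs_basis(t, trend_spec)[rows],
        [f"trend_{i}" for i in range(trend_df)],
    ))

    if np.ptp(series.rh) == 0:
        warnings.warn("constant humidity: rh spline dropped", stacklevel=2)
    else:
        rh_spec = default_knots(series.rh, config.rh_df)
        blocks.append((
            "rh", ncs_basis(series.rh, rh_spec)[rows],
            [f"rh_{i}" for i in range(config.rh_df)],
        ))

    dow = covariates.dow[rows]
    dummies = np.column_stack([(dow == d).astype(float) for d in range(1, 7)])
    blocks.append(("dow", dummies, [f"dow_{d}" for d in range(1, 7)]))

    hod = covariates.hod[rows].astype(float)
    if hod.any():
        blocks.append(("hod", hod[:, None], ["hod"]))

    X = np.hstack([b for _, b, _ in blocks])
    names: list[str] = []
    block_slices: dict[str, slice] = {}
    start = 0
    for name, mat, colnames in blocks:
        block_slices[name] = slice(start, start + mat.shape[1])
        names.extend(colnames)
        start += mat.shape[1]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise RankDeficiencyError(f"design is rank deficient; collinear columns: {bad}")
    return X, names, block_slices, rows


def fit_poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood (the quasi-likelihood kernel up to scaling)."""
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def fit_quasipoisson(
    y,
    X,
    column_names=None,
    block_slices=None,
    maxiter: int = 50,
    tol: float = 1e-9,
) -> FitResult:
    """Fit a log-link quasi-Poisson GLM by IRLS.

    Dispersion is the Pearson statistic over residual df; the covariance is
    ``phi * (X'WX)^-1``.  Convergence: relative deviance change below ``tol``
    within ``maxiter`` iterations, else :class:`ConvergenceError` with the
    deviance trace.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must contain non-negative integer counts")
    if column_names is None:
        column_names = [f"x{i}" for i in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"design is rank deficient; collinear columns: {_collinear_columns(X, column_names)}"
        )

    model = sm.GLM(y, X, family=sm.families.Poisson())
    # converge on RELATIVE deviance change < tol
    res = model.fit(scale="X2", maxiter=maxiter, atol=0.0, rtol=tol,
                    tol_criterion="deviance")
    if not getattr(res, "converged", True):
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations",
            trace=res.fit_history.get("deviance"),
        )
    mu = res.fittedvalues
    if np.any(mu < 1e-10) or np.any(mu > 1e10):
        raise ConvergenceError("separation: fitted means collapsed to 0 or infinity")

    return FitResult(
        params=np.asarray(res.params, float),
        cov=np.asarray(res.cov_params(), float),
        dispersion=float(res.scale),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        loglik=fit_poisson_loglik(y, mu),
        df_residual=int(res.df_resid),
        rank=int(rank),
        n_obs=len(y),
        column_names=list(column_names),
        block_slices=block_slices or {},
        family="quasipoisson",
        fitted=np.asarray(mu, float),
    )


def deviance_explained(fit: FitResult) -> float:
    """Fraction of null deviance explained: 1 - deviance/null_deviance."""
    if fit.null_deviance <= 0:
        raise ValueError("null deviance is zero (constant response)")
    return 1.0 - fit.deviance / fit.null_deviance


def qaic(fit: FitResult, phi_reference: float) -> float:
    """Quasi-AIC: -2 * loglik / phi_ref + 2 * rank, with a shared reference
    dispersion so that nested quasi-Poisson fits are comparable."""
    if phi_reference <= 0:
        raise ValueError("phi_reference must be positive")
    return -2.0 * fit.loglik / phi_reference + 2.0 * fit.rank
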