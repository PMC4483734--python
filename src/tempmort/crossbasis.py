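"""Exposure-lag cross-basis: the bidimensional design block of a DLNM.

A distributed-lag nonlinear model represents the delayed effect of an
exposure series x_t through the tensor product of a predictor-space basis
b_1..b_vx and a lag-space basis c_1..c_vl over lags 0..L:

    w[t, (j, k)] = sum_{l=0}^{L} b_j(x_{t-l}) * c_k(l)

Contracting a fitted coefficient vector with the contrast vectors produced by
:func:`crossbasis_contrast` yields cumulative or lag-specific log relative
risks between any temperature and a reference.

Rows with incomplete lag history (t < L) are dropped, not zero-padded, and
the indices of the usable rows are recorded so the response and covariates
can be subset consistently.

The lag basis follows the standard cross-basis convention of including an
intercept column in lag space; a lag spec's ``df`` counts total lag columns
including that intercept, and lag-spline interior knots are equally spaced on
the lag scale by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSpec, basis_matrix, ncs_basis

__all__ = [
    "CrossBasis",
    "make_lag_spec",
    "lag_basis_matrix",
    "build_crossbasis",
    "crossbasis_contrast",
    "contrast_matrix",
]


def make_lag_spec(df: int, max_lag: int, log_spacing: bool = False) -> BasisSpec:
    """Lag-space NCS spec over lags 0..max_lag with ``df`` total columns.

    Column 1 is the lag-space intercept; the remaining df-1 columns are a
    natural cubic spline in the lag value with interior knots equally spaced
    on the lag scale (or on log(1+lag) with ``log_spacing``).
    """
    if df < 1:
        raise ValueError("lag df must be >= 1")
    if max_lag == 0 and df > 1:
        raise ValueError("max_lag=0 admits only df=1 (intercept)")
    if df == 1:
        return BasisSpec(kind="linear", df=None)  # marker; only intercept used
    n_interior = df - 2
    if log_spacing:
        grid = np.expm1(np.linspace(0, np.log1p(max_lag), n_interior + 2))
    else:
        grid = np.linspace(0, max_lag, n_interior + 2)
    return BasisSpec(kind="ncs", knots=tuple(grid[1:-1]), boundary=(0.0, float(max_lag)))


def lag_basis_matrix(lag_spec: BasisSpec, max_lag: int) -> np.ndarray:
    """(max_lag+1) × vl lag basis: intercept column plus spline columns."""
    lags = np.arange(max_lag + 1, dtype=float)
    ones = np.ones((max_lag + 1, 1))
    if lag_spec.kind == "ncs":
        return np.hstack([ones, ncs_basis(lags, lag_spec)])
    if lag_spec.kind == "linear":
        return ones
    raise ValueError(f"unsupported lag basis kind '{lag_spec.kind}'")


@dataclass
class CrossBasis:
    """Realized cross-basis design block plus the frozen specs that built it."""

    matrix: np.ndarray            # n_usable × (vx * vl)
    pred_spec: BasisSpec
    lag_spec: BasisSpec
    max_lag: int
    column_index: list            # column -> (j, k)
    usable_rows: np.ndarray       # indices t >= max_lag into the source series

    @property
    def vx(self) -> int:
        return int(self.pred_spec.df)

    @property
    def vl(self) -> int:
        return lag_basis_matrix(self.lag_spec, self.max_lag).shape[1]

    @property
    def ncols(self) -> int:
        return self.matrix.shape[1]


def build_crossbasis(x, pred_spec: BasisSpec, lag_spec: BasisSpec, max_lag: int) -> CrossBasis:
    """Build the n_usable × (vx·vl) cross-basis of an exposure series."""
    x = np.asarray(x, float)
    n = len(x)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if max_lag >= n:
        raise ValueError(f"max_lag={max_lag} >= series length {n}")
    B = basis_matrix(x, pred_spec)                      # n × vx
    C = lag_basis_matrix(lag_spec, max_lag)             # (L+1) × vl
    usable = np.arange(max_lag, n)
    # lagged predictor-basis stack: Bl[t, l, j] = b_j(x_{t-l})
    idx = usable[:, None] - np.arange(max_lag + 1)[None, :]
    Bl = B[idx]                                         # n_u × (L+1) × vx
    M = np.einsum("tlj,lk->tjk", Bl, C)
    vx, vl = B.shape[1], C.shape[1]
    matrix = M.reshape(len(usable), vx * vl)
    column_index = [(j, k) for j in range(vx) for k in range(vl)]
    return CrossBasis(matrix, pred_spec, lag_spec, max_lag, column_index, usable)


def contrast_matrix(
    pred_spec: BasisSpec,
    lag_spec: BasisSpec,
    max_lag: int,
    temps,
    ref: float,
    mode: str = "cumulative",
    lag: int | None = None,
) -> np.ndarray:
    """Contrast rows for many temperatures at once: len(temps) × (vx·vl)."""
    temps = np.atleast_1d(np.asarray(temps, float))
    C = lag_basis_matrix(lag_spec, max_lag)
    if mode == "cumulative":
        c = C.sum(axis=0)
    elif mode == "lag_specific":
        if lag is None or not 0 <= lag <= max_lag:
            raise ValueError(f"lag must be in [0, {max_lag}] for lag_specific mode")
        c = C[lag]
    else:
        raise ValueError(f"unknown mode '{mode}'")
    Bt = basis_matrix(temps, pred_spec)
    Br = basis_matrix(np.array([ref]), pred_spec)
    db = Bt - Br                                        # len(temps) × vx
    return np.einsum("tj,k->tjk", db, c).reshape(len(temps), -1)


def crossbasis_contrast(
    pred_spec: BasisSpec,
    lag_spec: BasisSpec,
    max_lag: int,
    temp: float,
    ref: float,
    mode: str = "cumulative",
    lag: int | None = None,
) -> np.ndarray:
    """Coefficient-contrast vector of length vx·vl.

    In cumulative mode element (j, k) is (b_j(temp) - b_j(ref)) * sum_l c_k(l);
    in lag_specific mode the sum is replaced by c_k(lag).  The inner product
    of this vector with the fitted cross-basis coefficients is the log-RR of
    ``temp`` versus ``ref``.
    """
    return contrast_matrix(pred_spec, lag_spec, max_lag, [temp], ref, mode, lag)[0]
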