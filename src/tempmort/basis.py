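"""Predictor-space basis functions: natural cubic splines and thresholds.

Four basis kinds cover the predictor parameterizations used in the analysis:

``ncs``
    Natural (restricted) cubic spline — cubic between knots, C²-continuous,
    linear beyond the boundary knots.  ``df`` columns, interior knots at
    equally spaced quantiles by default.  No constant column (the model
    supplies the intercept).
``sthr``
    Single-high-threshold "hockey stick": one column ``max(0, x - high)``.
``dthr``
    Double threshold: cold arm ``max(0, low - x)`` and heat arm
    ``max(0, x - high)``; both identically zero on the closed null region
    ``[low, high]``, so the relative risk is exactly 1 between the thresholds.
``linear``
    A single identity column.

The same machinery builds lag-space spline bases (see
:mod:`tempmort.crossbasis`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BasisSpec",
    "default_knots",
    "ncs_basis",
    "sthr_basis",
    "dthr_basis",
    "basis_matrix",
    "spec_ncols",
]


@dataclass(frozen=True)
class BasisSpec:
    """Frozen, serializable description of a one-dimensional basis.

    Once constructed, a spec fully determines the basis: evaluating it on new
    data uses the frozen knots/thresholds (prediction-time consistency).
    """

    kind: str  # "ncs" | "sthr" | "dthr" | "linear"
    df: int | None = None
    knots: tuple = ()          # interior knots (ncs)
    boundary: tuple | None = None
    thresholds: tuple = ()     # (high,) for sthr, (low, high) for dthr

    def __post_init__(self):
        if self.kind not in ("ncs", "sthr", "dthr", "linear"):
            raise ValueError(f"unknown basis kind '{self.kind}'")
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        if self.thresholds:
            object.__setattr__(
                self, "thresholds", tuple(float(t) for t in self.thresholds)
            )
        if self.kind == "ncs":
            if self.boundary is None:
                raise ValueError("ncs spec requires boundary knots")
            lo, hi = map(float, self.boundary)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("boundary knots must be finite with lo < hi")
            object.__setattr__(self, "boundary", (lo, hi))
            if any(k <= lo or k >= hi for k in self.knots):
                raise ValueError("interior knots must lie strictly inside boundary")
            if list(self.knots) != sorted(self.knots):
                raise ValueError("interior knots must be sorted")
            df = len(self.knots) + 1
            if self.df is not None and self.df != df:
                raise ValueError(f"df={self.df} inconsistent with {len(self.knots)} interior knots")
            object.__setattr__(self, "df", df)
        elif self.kind == "sthr":
            if len(self.thresholds) != 1:
                raise ValueError("sthr requires exactly one (high) threshold")
            object.__setattr__(self, "df", 1)
        elif self.kind == "dthr":
            if len(self.thresholds) != 2:
                raise ValueError("dthr requires (low, high) thresholds")
            lo, hi = self.thresholds
            if not lo < hi:
                raise ValueError(f"dthr thresholds require low < high, got {lo} >= {hi}")
            object.__setattr__(self, "df", 2)
        else:  # linear
            object.__setattr__(self, "df", 1)

    @property
    def all_knots(self) -> np.ndarray:
        """Boundary + interior knots, sorted (ncs only)."""
        return np.array([self.boundary[0], *self.knots, self.boundary[1]])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "df": self.df,
            "knots": list(self.knots),
            "boundary": list(self.boundary) if self.boundary else None,
            "thresholds": list(self.thresholds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            kind=d["kind"],
            df=d.get("df"),
            knots=tuple(d.get("knots") or ()),
            boundary=tuple(d["boundary"]) if d.get("boundary") else None,
            thresholds=tuple(d.get("thresholds") or ()),
        )


def default_knots(x, df: int, equally_spaced: bool = False) -> BasisSpec:
    """NCS spec with ``df`` columns: df-1 interior knots at equally spaced
    quantiles of ``x`` (or equally spaced values), boundary at min/max."""
    x = np.asarray(x, float)
    if df < 1:
        raise ValueError("df must be >= 1")
    distinct = np.unique(x)
    if len(distinct) <= df:
        raise ValueError(f"df={df} requires more than {df} distinct values")
    lo, hi = float(x.min()), float(x.max())
    n_interior = df - 1
    if n_interior == 0:
        knots = ()
    elif equally_spaced:
        knots = tuple(np.linspace(lo, hi, n_interior + 2)[1:-1])
    else:
        probs = 100.0 * np.arange(1, n_interior + 1) / (n_interior + 1)
        knots = tuple(np.percentile(x, probs))
    if len(set(knots)) != len(knots):
        raise ValueError("tied interior knots; reduce df or use equally_spaced")
    return BasisSpec(kind="ncs", knots=knots, boundary=(lo, hi))


def ncs_basis(x, spec: BasisSpec) -> np.ndarray:
    """Natural cubic spline basis, n × df.

    Restricted-cubic construction: column 1 is ``x`` itself; columns 2..df are
    differences of scaled truncated cubics that cancel the cubic and quadratic
    terms beyond the upper boundary, giving linear tails on both sides.
    """
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in x")
    if spec.kind != "ncs":
        raise ValueError("spec.kind must be 'ncs'")
    knots = spec.all_knots
    K = len(knots)
    cols = [x]
    if K > 2:
        last = knots[-1]
        cube = np.maximum(x[:, None] - knots[None, :], 0.0) ** 3
        # d_j(x) = [(x - k_j)+^3 - (x - k_K)+^3] / (k_K - k_j)
        d = (cube[:, :-1] - cube[:, -1:]) / (last - knots[:-1])
        for j in range(K - 2):
            cols.append(d[:, j] - d[:, K - 2])
    return np.column_stack(cols)


def sthr_basis(x, threshold_high: float) -> np.ndarray:
    """Hockey-stick heat arm, n × 1: ``max(0, x - high)``.

    The threshold itself contributes 0 (closed null region), so the relative
    risk is exactly 1 at the threshold.
    """
    x = np.asarray(x, float)
    if not np.isfinite(threshold_high):
        raise ValueError("threshold must be finite")
    return np.maximum(0.0, x - threshold_high)[:, None]


def dthr_basis(x, t_low: float, t_high: float) -> np.ndarray:
    """Double-threshold basis, n × 2: cold arm ``max(0, low - x)`` and heat
    arm ``max(0, x - high)``; both zero on the closed null region."""
    if not t_low < t_high:
        raise ValueError(f"require t_low < t_high, got {t_low} >= {t_high}")
    x = np.asarray(x, float)
    return np.column_stack([np.maximum(0.0, t_low - x), np.maximum(0.0, x - t_high)])


def basis_matrix(x, spec: BasisSpec) -> np.ndarray:
    """Evaluate any basis spec on ``x`` (dispatch on ``spec.kind``)."""
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in x")
    if spec.kind == "ncs":
        return ncs_basis(x, spec)
    if spec.kind == "sthr":
        return sthr_basis(x, spec.thresholds[0])
    if spec.kind == "dthr":
        return dthr_basis(x, *spec.thresholds)
    return x[:, None]  # linear


def spec_ncols(spec: BasisSpec) -> int:
    return int(spec.df)
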