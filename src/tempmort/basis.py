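"""Natural cubic splines and the exposure x lag cross-basis of the DLNM.

The distributed lag non-linear model represents risk as a bidimensional
surface over exposure intensity and lag. Its design matrix — the cross-basis
— has one column per pair (j, k) of an exposure-basis column b_j and a
lag-basis column c_k, with entry

    W[t, (j, k)] = sum_{l=0..L} b_j(x_{t-l}) * c_k(l)

so each observation day carries its whole L-day temperature history. Columns
are ordered exposure-major: (j=0,k=0), (j=0,k=1), ..., an ordering the
curve-reduction contrasts must honour.

Natural cubic splines are built from the cubic B-spline basis with the
natural constraints (zero second derivative at the boundary knots) projected
out, and extrapolate linearly beyond the boundaries by first-order Taylor
expansion from the boundary knot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .exposure import TemperatureSeries, ValidationError

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "ns_basis",
    "lag_basis",
    "cross_basis",
    "log_lag_knots",
]


@dataclass(frozen=True)
class SplineSpec:
    """One marginal natural-cubic-spline basis.

    ``transform`` applies to the evaluation axis: "identity" for the exposure
    dimension, "log" for the lag dimension (lags evaluated at log(l+1)).
    Basis dimension is ``len(internal_knots) + 1 + intercept``.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept: bool = False
    transform: str = "identity"

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.internal_knots)
        object.__setattr__(self, "internal_knots", ik)
        a, b = (float(x) for x in self.boundary_knots)
        object.__setattr__(self, "boundary_knots", (a, b))
        if not a < b:
            raise ValidationError(f"boundary knots must be distinct and ordered: {a}, {b}")
        if any(not (a < k < b) for k in ik):
            raise ValidationError(
                f"internal knots {ik} must lie strictly inside boundary ({a}, {b})"
            )
        if list(ik) != sorted(ik) or len(set(ik)) != len(ik):
            raise ValidationError(f"internal knots must be strictly increasing: {ik}")
        if self.transform not in ("identity", "log", "constant"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.transform == "constant" and (ik or not self.intercept):
            raise ValidationError(
                "constant basis requires intercept=True and no internal knots"
            )

    @property
    def dim(self) -> int:
        if self.transform == "constant":
            return 1
        return len(self.internal_knots) + 1 + (1 if self.intercept else 0)


def _bspline_design(x: np.ndarray, knots_full: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Dense cubic B-spline design matrix (or its deriv-th derivative)."""
    ncol = len(knots_full) - 4
    out = np.empty((len(x), ncol))
    for i in range(ncol):
        coef = np.zeros(ncol)
        coef[i] = 1.0
        spl = BSpline(knots_full, coef, 3, extrapolate=True)
        if deriv:
            spl = spl.derivative(deriv)
        out[:, i] = spl(x)
    return out


def _ns_design_raw(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Natural-spline design before evaluation transform; x already on eval axis."""
    a, b = spec.boundary_knots
    t = np.concatenate([[a] * 4, spec.internal_knots, [b] * 4])

    inside = np.clip(x, a, b)
    B = _bspline_design(inside, t)
    below, above = x < a, x > b
    if np.any(below) or np.any(above):
        # linear (first-order Taylor) continuation past the boundary knots
        for mask, edge in ((below, a), (above, b)):
            if np.any(mask):
                B0 = _bspline_design(np.array([edge]), t)
                B1 = _bspline_design(np.array([edge]), t, deriv=1)
                B[mask] = B0 + np.outer(x[mask] - edge, B1[0])

    const = _bspline_design(np.array([a, b]), t, deriv=2)
    if not spec.intercept:
        B = B[:, 1:]
        const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    Z = q[:, 2:]
    return B @ Z


def ns_basis(values, spec: SplineSpec, hard_range: tuple[float, float] | None = None) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``values``.

    The basis is cubic between knots, has zero second derivative at the
    boundary knots and continues linearly beyond them. With ``hard_range``
    set, values outside it trigger a warning (extrapolation is linear by
    construction, never an error).
    """
    x = np.atleast_1d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values passed to ns_basis")
    if hard_range is not None:
        lo, hi = hard_range
        if np.any((x < lo) | (x > hi)):
            warnings.warn(
                f"values outside configured range [{lo}, {hi}]; "
                "spline extrapolates linearly",
                stacklevel=2,
            )
    if spec.transform == "log":
        if np.any(x < 0):
            raise ValidationError("log-transform axis requires non-negative values")
        x = np.log1p(x)
    return _ns_design_raw(x, spec)


def log_lag_knots(max_lag: int, n_knots: int) -> tuple[float, ...]:
    """Interior knots equally spaced on the log(l+1) scale over lags 0..max_lag."""
    u = np.linspace(0.0, np.log1p(max_lag), n_knots + 2)[1:-1]
    return tuple(u)


def default_lag_spec(max_lag: int, n_knots: int = 3) -> SplineSpec:
    """Natural spline on log(l+1), equally spaced interior knots, with intercept."""
    if max_lag == 0:
        # degenerate single-lag model: intercept-only column
        return SplineSpec((), (0.0, 1.0), intercept=True, transform="constant")
    if n_knots >= 1 and max_lag < n_knots + 2:
        raise ValidationError(
            f"max_lag={max_lag} too short for {n_knots} lag knots (unidentifiable)"
        )
    return SplineSpec(
        log_lag_knots(max_lag, n_knots) if n_knots else (),
        (0.0, float(np.log1p(max_lag))),
        intercept=True,
        transform="log",
    )


def lag_basis(spec: SplineSpec, max_lag: int) -> np.ndarray:
    """Rows l = 0..max_lag of the lag basis c_k(l); shape (max_lag+1, dim)."""
    if max_lag < 0:
        raise ValidationError("max_lag must be >= 0")
    n_knots = len(spec.internal_knots)
    if n_knots >= 1 and max_lag < n_knots + 2:
        raise ValidationError(
            f"max_lag={max_lag} < n_knots+2={n_knots + 2}: lag basis unidentifiable"
        )
    lags = np.arange(max_lag + 1, dtype=float)
    if spec.transform == "constant":
        return np.ones((max_lag + 1, 1))
    if max_lag == 0:
        raise ValidationError("max_lag=0 requires the constant (intercept-only) lag spec")
    if spec.transform == "log":
        u = np.log1p(lags)
        return _ns_design_raw(u, replace(spec, transform="identity"))
    return _ns_design_raw(lags, spec)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure spline (no intercept) x lag spline (with intercept), lags 0..max_lag."""

    exposure_spec: SplineSpec
    lag_spec: SplineSpec
    max_lag: int = 21
    label: str = ""

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValidationError("max_lag must be >= 0")
        if self.exposure_spec.intercept:
            raise ValidationError("exposure basis must not carry an intercept")
        if not self.lag_spec.intercept:
            raise ValidationError("lag basis must carry an intercept")

    @property
    def n_columns(self) -> int:
        return self.exposure_spec.dim * self.lag_spec.dim

    @property
    def column_labels(self) -> list[str]:
        return [
            f"b{j + 1}.c{k + 1}"
            for j in range(self.exposure_spec.dim)
            for k in range(self.lag_spec.dim)
        ]

    def lag_matrix(self) -> np.ndarray:
        return lag_basis(self.lag_spec, self.max_lag)

    def to_dict(self) -> dict:
        return {
            "exposure_knots": list(self.exposure_spec.internal_knots),
            "exposure_boundary": list(self.exposure_spec.boundary_knots),
            "lag_knots": list(self.lag_spec.internal_knots),
            "lag_boundary": list(self.lag_spec.boundary_knots),
            "lag_transform": self.lag_spec.transform,
            "max_lag": self.max_lag,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            SplineSpec(
                tuple(d["exposure_knots"]),
                tuple(d["exposure_boundary"]),
                intercept=False,
            ),
            SplineSpec(
                tuple(d["lag_knots"]),
                tuple(d["lag_boundary"]),
                intercept=True,
                transform=d.get("lag_transform", "log"),
            ),
            max_lag=int(d["max_lag"]),
            label=d.get("label", ""),
        )


def spec_from_percentiles(
    dist,
    knot_percentiles: Sequence[float] = (0.10, 0.75, 0.90),
    max_lag: int = 21,
    lag_knots: int = 3,
    label: str = "",
) -> CrossBasisSpec:
    """Build a cross-basis spec with exposure knots at distribution percentiles.

    Default exposure knots sit at the 10th, 75th and 90th percentiles of the
    regional temperature distribution, boundary knots at the observed range —
    the placement standard in the Brazilian temperature-mortality literature.
    """
    knots = tuple(float(dist.percentile(p)) for p in knot_percentiles)
    expo = SplineSpec(knots, (dist.min, dist.max), intercept=False)
    return CrossBasisSpec(
        expo,
        default_lag_spec(max_lag, lag_knots),
        max_lag=max_lag,
        label=label or f"knots@{','.join(f'{100 * p:g}' for p in knot_percentiles)}",
    )


@dataclass
class CrossBasisMatrix:
    """Cross-basis rows for the observation days that have a full lag history."""

    spec: CrossBasisSpec
    municipality_id: str
    dates: pd.DatetimeIndex
    values: np.ndarray = field(repr=False)
    n_dropped_burn_in: int = 0

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.dates), self.spec.n_columns):
            raise ValidationError(
                f"cross-basis shape {self.values.shape} inconsistent with "
                f"{len(self.dates)} days x {self.spec.n_columns} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite cross-basis entries")


def cross_basis(
    series: TemperatureSeries,
    spec: CrossBasisSpec,
    history: np.ndarray | None = None,
) -> CrossBasisMatrix:
    """Construct the cross-basis matrix for one municipal temperature series.

    Lags are physical history on the continuous municipal series (windows may
    cross stratum or month boundaries). Days without a full ``max_lag``-day
    history are dropped unless ``history`` supplies the ``max_lag`` values
    preceding the series start (most recent last).
    """
    L = spec.max_lag
    x = series.tmean
    dates = series.dates
    dropped = 0
    if history is not None:
        history = np.asarray(history, dtype=float)
        if len(history) < L:
            raise ValidationError(
                f"history of length {len(history)} shorter than max_lag={L}"
            )
        if L and not np.all(np.isfinite(history[-L:])):
            raise ValidationError("non-finite temperature inside required lag window")
        x = np.concatenate([history[-L:] if L else history[:0], x])
    else:
        dropped = min(L, len(x))
    if len(x) < L + 1:
        raise ValidationError(
            f"series of {len(series)} days has no day with a full {L}-day history"
        )

    B = ns_basis(x, spec.exposure_spec)  # (T, J)
    C = spec.lag_matrix()  # (L+1, K)
    J, K = B.shape[1], C.shape[1]
    # W[t,(j,k)] = sum_l B[t-l, j] C[l, k]; windows run oldest->newest, so C flips
    windows = np.lib.stride_tricks.sliding_window_view(B, L + 1, axis=0)  # (T-L, J, L+1)
    W = np.einsum("tjl,lk->tjk", windows, C[::-1]).reshape(-1, J * K)
    out_dates = dates if history is not None else dates[L:]
    return CrossBasisMatrix(spec, series.municipality_id, out_dates, np.ascontiguousarray(W), dropped)
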