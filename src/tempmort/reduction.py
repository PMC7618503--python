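"""Overall cumulative exposure-response curves, MMT location, and RR contrasts.

Summing the fitted cross-basis over lags collapses the exposure-lag surface
to the overall cumulative association: the log relative risk of sustained
exposure at temperature x across the whole lag window, relative to a
reference. The contrast vector for temperature x against reference r is

    z(x) = (b(x) - b(r)) (x) C,        C_k = sum_{l=0..L} c_k(l)

(Kronecker product, exposure-major ordering, matching the cross-basis), so
log RR(x) = z(x)' theta_hat and var = z(x)' V z(x). The minimum mortality
temperature (MMT) is the argmin of the cumulative curve over a percentile
window of the regional temperature distribution; cold and heat relative
risks are the curve evaluated at the 1st and 99th percentiles against the
MMT. MMT-location uncertainty is not propagated into the confidence
intervals (inference is conditional on the located MMT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .basis import CrossBasisSpec, ns_basis
from .conditional import ConditionalFit
from .exposure import RegionalDistribution, ValidationError

__all__ = [
    "CumulativeCurve",
    "RREstimate",
    "MMTResult",
    "cumulative_contrast",
    "overall_curve",
    "find_mmt",
    "rr_at",
]


@dataclass
class CumulativeCurve:
    """Cumulative log-RR and pointwise SE on a temperature grid, vs. a reference."""

    grid: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    reference: float
    alpha: float = 0.05

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def ci_low(self) -> np.ndarray:
        z = norm.ppf(1 - self.alpha / 2)
        return np.exp(self.log_rr - z * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        z = norm.ppf(1 - self.alpha / 2)
        return np.exp(self.log_rr + z * self.se)

    def to_frame(self, region: str = "", subgroup: str = "all") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": region,
                "subgroup": subgroup,
                "temperature": self.grid,
                "rr": self.rr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "reference": self.reference,
            }
        )


@dataclass
class RREstimate:
    """Relative risk at a percentile contrast temperature versus the MMT."""

    contrast: str  # "cold" or "heat"
    percentile: float
    temperature: float
    reference: float
    rr: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    mmt_fallback: bool = False


@dataclass
class MMTResult:
    temperature: float
    percentile: float
    fallback: bool = False


def cumulative_contrast(x: float, ref: float, spec: CrossBasisSpec) -> np.ndarray:
    """Contrast vector z(x) over cross-basis columns (exposure-major order)."""
    bx = ns_basis([x], spec.exposure_spec)[0]
    br = ns_basis([ref], spec.exposure_spec)[0]
    Csum = spec.lag_matrix().sum(axis=0)
    return np.kron(bx - br, Csum)


def _curve_arrays(fit: ConditionalFit, spec: CrossBasisSpec, grid, ref):
    grid = np.asarray(grid, dtype=float)
    B = ns_basis(grid, spec.exposure_spec) - ns_basis([ref], spec.exposure_spec)
    Csum = spec.lag_matrix().sum(axis=0)
    Z = np.einsum("gj,k->gjk", B, Csum).reshape(len(grid), -1)
    if Z.shape[1] != len(fit.theta):
        raise ValidationError(
            f"contrast dimension {Z.shape[1]} does not match fitted "
            f"coefficients ({len(fit.theta)}): ordering/spec mismatch"
        )
    log_rr = Z @ fit.theta
    var = np.einsum("gi,ij,gj->g", Z, fit.vcov, Z)
    return grid, log_rr, np.sqrt(np.maximum(var, 0.0))


def overall_curve(
    fit: ConditionalFit,
    spec: CrossBasisSpec,
    grid,
    ref: float,
    alpha: float = 0.05,
) -> CumulativeCurve:
    """Cumulative exposure-response curve on a temperature grid, centred at ``ref``."""
    grid, log_rr, se = _curve_arrays(fit, spec, grid, ref)
    return CumulativeCurve(grid, log_rr, se, float(ref), alpha)


def find_mmt(
    curve_fn,
    dist: RegionalDistribution,
    search: tuple[float, float] = (0.01, 0.99),
    fallback_percentile: float | None = None,
) -> MMTResult:
    """Locate the minimum mortality temperature on the cumulative curve.

    ``curve_fn`` maps temperature (deg C) to cumulative log-RR under any fixed
    reference (the argmin is reference-invariant). The curve is evaluated at
    0.1-percentile steps of the regional distribution over ``search``. If the
    minimum sits at the upper search boundary and ``fallback_percentile`` is
    given, the MMT is instead the regional temperature at that percentile
    (the national-MMT-percentile rule) and the result is flagged.
    """
    lo, hi = search
    if not (0 <= lo < hi <= 1):
        raise ValidationError(f"invalid MMT search interval ({lo}, {hi})")
    probs = np.arange(lo, hi + 1e-12, 0.001)
    temps = np.atleast_1d(dist.percentile(probs))
    utemps = np.unique(temps)
    try:  # vectorised evaluation when the curve function supports it
        vals = np.asarray(curve_fn(utemps), dtype=float)
        if vals.shape != utemps.shape:
            raise TypeError
    except (TypeError, ValueError):
        vals = np.asarray([float(curve_fn(t)) for t in utemps])
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite curve values in MMT search")
    i = int(np.argmin(vals))
    at_upper = utemps[i] >= utemps[-1] - 1e-12
    if at_upper and fallback_percentile is not None:
        t = float(dist.percentile(fallback_percentile))
        return MMTResult(t, float(fallback_percentile), fallback=True)
    return MMTResult(float(utemps[i]), float(dist.percentile_rank(float(utemps[i]))))


def rr_at(
    fit: ConditionalFit,
    spec: CrossBasisSpec,
    x: float,
    mmt: float,
    alpha: float = 0.05,
    contrast: str = "",
    percentile: float = np.nan,
    mmt_fallback: bool = False,
) -> RREstimate:
    """Cumulative RR (with CI) at temperature ``x`` versus the MMT reference."""
    z = cumulative_contrast(x, mmt, spec)
    if len(z) != len(fit.theta):
        raise ValidationError("contrast/coefficient dimension mismatch")
    est = float(z @ fit.theta)
    se = float(np.sqrt(max(z @ fit.vcov @ z, 0.0)))
    zcrit = norm.ppf(1 - alpha / 2)
    return RREstimate(
        contrast=contrast or ("cold" if x < mmt else "heat"),
        percentile=float(percentile),
        temperature=float(x),
        reference=float(mmt),
        rr=float(np.exp(est)),
        ci_low=float(np.exp(est - zcrit * se)),
        ci_high=float(np.exp(est + zcrit * se)),
        alpha=alpha,
        mmt_fallback=mmt_fallback,
    )
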