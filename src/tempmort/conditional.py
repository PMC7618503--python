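"""Conditional quasi-Poisson regression with stratum intercepts profiled out.

The space-time-stratified case-crossover model is a Poisson regression with
one intercept per municipality x year x month x weekday stratum. Rather than
materialising thousands of indicator columns, the stratum intercepts are
profiled analytically: at any coefficient vector theta the optimal intercept
for stratum s is

    alpha_s(theta) = log( Y_s / sum_{t in s} exp(w_t' theta) ),

which reduces the problem to the conditional (multinomial) likelihood given
stratum totals. The profiled likelihood is concave; Newton iterations with
step-halving converge in a handful of steps. Overdispersion is handled
quasi-style: phi_hat = Pearson chi-square / (n - p - S) with stratum
intercepts counted as estimated parameters, and the covariance of theta is
the inverse observed information of the profiled likelihood scaled by
phi_hat. Model comparison uses qAIC = -2 loglik + 2 p phi_hat with the full
Poisson log-likelihood evaluated at (theta_hat, alpha_hat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exposure import ValidationError

__all__ = [
    "ConditionalFit",
    "FitDiagnostics",
    "FitError",
    "fit_conditional_quasipoisson",
    "qaic",
    "select_spec",
]


class FitError(RuntimeError):
    """Raised when the conditional fit cannot be computed."""


@dataclass
class FitDiagnostics:
    converged: bool
    iterations: int
    max_coef_step: float
    dropped_strata_reasons: pd.Series


@dataclass
class ConditionalFit:
    """Profiled-likelihood quasi-Poisson fit over cross-basis columns."""

    theta: np.ndarray
    vcov: np.ndarray = field(repr=False)
    dispersion: float
    loglik: float
    qaic: float
    n_obs_used: int
    n_strata_used: int
    n_strata_dropped: int
    diagnostics: FitDiagnostics = field(repr=False, default=None)
    fitted_mu: np.ndarray = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def summary(self, names=None) -> pd.DataFrame:
        names = names or [f"x{i + 1}" for i in range(len(self.theta))]
        return pd.DataFrame(
            {"term": names, "estimate": self.theta, "std_error": self.se}
        )

    def model_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_obs": [self.n_obs_used],
                "n_strata": [self.n_strata_used],
                "dispersion": [self.dispersion],
                "loglik": [self.loglik],
                "qaic": [self.qaic],
            }
        )


def _prepare(y, W, strata):
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float)
    strata = np.asarray(strata)
    if not (len(y) == W.shape[0] == len(strata)):
        raise ValidationError(
            f"misaligned rows: y={len(y)}, design={W.shape[0]}, strata={len(strata)}"
        )
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValidationError("counts must be finite and non-negative")
    codes, _ = pd.factorize(strata, sort=True)
    order = np.argsort(codes, kind="stable")
    return y[order], W[order], codes[order]


def fit_conditional_quasipoisson(
    y,
    design,
    strata,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ConditionalFit:
    """Fit the stratum-eliminated quasi-Poisson model.

    ``y``: daily death counts; ``design``: cross-basis rows aligned with y;
    ``strata``: stratum label per row. Strata with zero total deaths or no
    variation in any design column are dropped before fitting (they carry no
    information about theta) and logged in the diagnostics.
    """
    y, W, codes = _prepare(y, design, strata)
    n_all = len(y)
    p = W.shape[1]

    # stratum bookkeeping on sorted codes
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    Ytot = np.add.reduceat(y, starts)
    sizes = np.diff(np.r_[starts, n_all])

    no_var = np.ones(len(starts), dtype=bool)
    for j in range(p):
        col_max = np.maximum.reduceat(W[:, j], starts)
        col_min = np.minimum.reduceat(W[:, j], starts)
        no_var &= (col_max - col_min) < 1e-12
    zero_tot = Ytot == 0

    drop = zero_tot | no_var
    reasons = {}
    if zero_tot.any():
        reasons["zero_total_deaths"] = int(zero_tot.sum())
    if (no_var & ~zero_tot).any():
        reasons["no_design_variation"] = int((no_var & ~zero_tot).sum())
    drop_log = pd.Series(reasons, dtype=int, name="count")
    drop_log.index.name = "reason"

    keep_rows = ~np.repeat(drop, sizes)
    if not np.any(keep_rows):
        raise FitError("no informative strata: every stratum empty or constant")
    y, W, codes = y[keep_rows], W[keep_rows], codes[keep_rows]
    codes = pd.factorize(codes, sort=True)[0]
    n = len(y)
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    Ytot = np.add.reduceat(y, starts)
    S = len(starts)

    # collinearity of the stratum-centred design (what the profiled model sees)
    means = np.add.reduceat(W, starts, axis=0) / np.diff(np.r_[starts, n])[:, None]
    Wc = W - means[codes]
    rank = np.linalg.matrix_rank(Wc)
    if rank < p:
        raise FitError(
            f"design is collinear within strata: null-space dimension {p - rank}"
        )

    def profile_parts(theta):
        eta = W @ theta
        mx = np.maximum.reduceat(eta, starts)
        lse = mx + np.log(np.add.reduceat(np.exp(eta - mx[codes]), starts))
        logp = eta - lse[codes]
        mu = Ytot[codes] * np.exp(logp)
        # conditional (multinomial) log-likelihood up to a theta-free constant
        ll = float(np.sum(y * logp))
        return mu, ll

    theta = np.zeros(p)
    mu, ll = profile_parts(theta)
    converged = False
    it = 0
    max_step = np.inf
    for it in range(1, max_iter + 1):
        grad = W.T @ (y - mu)
        muW = mu[:, None] * W
        M = np.add.reduceat(muW, starts, axis=0)
        H = W.T @ muW - (M / Ytot[:, None]).T @ M
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FitError(f"singular information matrix at iteration {it}") from exc
        # step-halving keeps the profiled log-likelihood monotone
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            mu_c, ll_c = profile_parts(cand)
            if ll_c >= ll - 1e-12:
                break
            scale /= 2.0
        theta, mu, ll = cand, mu_c, ll_c
        denom = np.maximum(np.abs(theta), 1.0)
        max_step = float(np.max(np.abs(scale * step) / denom))
        if max_step < tol or float(np.linalg.norm(W.T @ (y - mu))) < tol:
            converged = True
            break
    if not converged:
        raise FitError(
            f"no convergence in {max_iter} iterations "
            f"(last relative step {max_step:.3g})"
        )

    grad = W.T @ (y - mu)
    M = np.add.reduceat(mu[:, None] * W, starts, axis=0)
    H = W.T @ (mu[:, None] * W) - (M / Ytot[:, None]).T @ M
    Hinv = np.linalg.inv(H)

    df = n - p - S
    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = pearson / df if df > 0 else 1.0
    vcov = dispersion * 0.5 * (Hinv + Hinv.T)

    # full Poisson log-likelihood at (theta_hat, alpha_hat)
    loglik = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    q = -2.0 * loglik + 2.0 * p * dispersion

    return ConditionalFit(
        theta=theta,
        vcov=vcov,
        dispersion=dispersion,
        loglik=loglik,
        qaic=q,
        n_obs_used=n,
        n_strata_used=S,
        n_strata_dropped=int(drop.sum()),
        diagnostics=FitDiagnostics(converged, it, max_step, drop_log),
        fitted_mu=mu,
    )


def qaic(fit: ConditionalFit, p: int | None = None) -> float:
    """Quasi-AIC: -2 loglik + 2 p phi_hat (reduces to AIC at phi_hat = 1)."""
    if fit.diagnostics is not None and not fit.diagnostics.converged:
        raise FitError("qAIC requested for a non-converged fit")
    if p is None:
        p = len(fit.theta)
    return -2.0 * fit.loglik + 2.0 * p * fit.dispersion


def select_spec(candidates, builder):
    """Fit every candidate cross-basis spec and pick the qAIC minimiser.

    ``builder(spec)`` must return the aligned ``(y, design, strata)`` triple
    for that spec (designs may differ in row count when lag lengths differ).
    Ties (within 1e-9) break on fewer parameters, then on candidate order.
    Returns (best spec, best fit, comparison table).
    """
    rows = []
    fits = []
    errors = []
    for i, spec in enumerate(candidates):
        try:
            counts_y, design, strata = builder(spec)
            fit = fit_conditional_quasipoisson(counts_y, design, strata)
            fits.append(fit)
            rows.append(
                {
                    "candidate": i,
                    "label": getattr(spec, "label", "") or f"spec{i}",
                    "n_params": design.shape[1],
                    "dispersion": fit.dispersion,
                    "qaic": fit.qaic,
                    "error": "",
                }
            )
        except (FitError, ValidationError) as exc:
            fits.append(None)
            errors.append(f"candidate {i}: {exc}")
            rows.append(
                {
                    "candidate": i,
                    "label": getattr(spec, "label", "") or f"spec{i}",
                    "n_params": np.nan,
                    "dispersion": np.nan,
                    "qaic": np.nan,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    ok = table["qaic"].notna()
    if not ok.any():
        raise FitError("all candidate specs failed: " + "; ".join(errors))
    sub = table[ok].sort_values(
        ["qaic", "n_params", "candidate"], kind="stable"
    )
    # exact qAIC ties resolved by parameter count then candidate order
    best_q = sub["qaic"].iloc[0]
    tied = sub[np.abs(sub["qaic"] - best_q) < 1e-9]
    best_i = int(tied.sort_values(["n_params", "candidate"]).iloc[0]["candidate"])
    table["selected"] = table["candidate"] == best_i
    return candidates[best_i], fits[best_i], table
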