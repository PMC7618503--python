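"""Synthetic municipal temperature and mortality generator with known truth.

The generator emulates the structure of the real analysis inputs without any
restricted data: municipal daily mean temperature with seasonality and AR(1)
autocorrelation, and overdispersed daily death counts whose log-rate carries
exactly the confounding the space-time strata are meant to absorb (long-term
trend, seasonality, weekly cycle) plus a known exposure-lag-response surface.

The true surface is deliberately V-shaped (piecewise linear in temperature,
hinged at the true MMT) with geometric lag weights w_l proportional to q^l and
normalised to sum to one over lags 0..L. Because the weights sum to one, the
cumulative log-RR of sustained exposure at x versus ref has the closed form
f(x) - f(ref) with

    f(x) = slope_cold * max(0, mmt - x) + slope_heat * max(0, x - mmt),

which makes parameter recovery an honest approximation test: the truth is
outside the fitted spline family. Overdispersion comes from negative-binomial
sampling (Poisson available for calibration checks). Dates are real calendar
dates so strata have genuine month and weekday structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exposure import TemperatureSeries, ValidationError
from .outcomes import DeathCountSeries

__all__ = [
    "TrueSurface",
    "SimConfig",
    "simulate_temperature",
    "simulate_deaths",
    "true_cumulative_rr",
    "simulate_inputs",
    "counts_to_records",
]

# ICD-10 three-character codes used when expanding counts into record rows;
# all fall in the non-accidental chapters A..R.
_NONACCIDENTAL_CODES = ("A41", "C34", "E11", "I21", "I64", "J18", "J44", "N18", "R99")


@dataclass(frozen=True)
class TrueSurface:
    """Known exposure-lag-response truth: V-shaped in temperature, geometric in lag."""

    mmt_true: float = 24.0
    slope_cold: float = 0.03  # cumulative log-RR per deg C below the true MMT
    slope_heat: float = 0.01  # cumulative log-RR per deg C above the true MMT
    lag_decay: float = 0.6  # geometric ratio q of the lag weights
    max_lag: int = 21

    def __post_init__(self) -> None:
        if self.slope_cold < 0 or self.slope_heat < 0:
            raise ValidationError("surface slopes must be non-negative")
        if not (0 < self.lag_decay < 1):
            raise ValidationError("lag_decay must lie in (0, 1)")
        if self.max_lag < 0:
            raise ValidationError("max_lag must be >= 0")

    @property
    def lag_weights(self) -> np.ndarray:
        w = self.lag_decay ** np.arange(self.max_lag + 1)
        return w / w.sum()

    def f(self, x) -> np.ndarray:
        """Cumulative log-RR at sustained exposure x (up to an additive constant)."""
        x = np.asarray(x, dtype=float)
        return self.slope_cold * np.maximum(0.0, self.mmt_true - x) + (
            self.slope_heat * np.maximum(0.0, x - self.mmt_true)
        )


def true_cumulative_rr(surface: TrueSurface, x: float, ref: float) -> float:
    """True cumulative RR at x vs ref; exact because the lag weights sum to 1."""
    return float(np.exp(surface.f(x) - surface.f(ref)))


@dataclass
class SimConfig:
    """Generator settings; defaults emulate mid-size Brazilian municipalities.

    Temperature: warm mean level with moderate seasonal swing and day-to-day
    AR(1) persistence. Deaths: baseline ~2/day per municipality with seasonal,
    weekly and slow-trend confounding on the log scale; negative-binomial
    dispersion by default.
    """

    n_municipalities: int = 10
    n_years: int = 5
    start: str = "2010-01-01"
    temp_level: float = 24.0  # deg C, mean daily temperature
    temp_level_sd: float = 2.0  # between-municipality level jitter
    seasonal_amplitude: float = 5.0  # deg C
    phase: float = 0.0
    phase_jitter_sd: float = 0.2
    ar_rho: float = 0.7
    innovation_sd: float = 1.5  # deg C
    baseline_log_rate: float = float(np.log(2.0))  # ~2 deaths/day
    season_confounder: float = 0.10  # log-scale seasonal amplitude in mortality
    weekly_confounder: float = 0.05  # log-scale weekday effect amplitude
    trend_confounder: float = 0.10  # total log-scale drift over the whole window
    dispersion: float | str = 5.0  # NB size parameter, or "poisson"
    seed: int = 0

    @property
    def dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.start)
        end = start + pd.DateOffset(years=self.n_years) - pd.Timedelta(days=1)
        return pd.date_range(start, end, freq="D")


def simulate_temperature(cfg: SimConfig) -> list[TemperatureSeries]:
    """Municipal daily mean temperature: seasonal sinusoid + AR(1) noise.

    Each municipality draws its own mean level and seasonal phase jitter, so
    regional pooling mixes distinct local climates; series are independent
    across municipalities (no spatial correlation).
    """
    rng = np.random.default_rng(cfg.seed)
    dates = cfg.dates
    t = np.arange(len(dates), dtype=float)
    out = []
    for m in range(cfg.n_municipalities):
        level = cfg.temp_level + rng.normal(0.0, cfg.temp_level_sd)
        phase = cfg.phase + rng.normal(0.0, cfg.phase_jitter_sd)
        seasonal = cfg.seasonal_amplitude * np.sin(2 * np.pi * t / 365.25 + phase)
        innov = rng.normal(0.0, cfg.innovation_sd, size=len(t))
        if cfg.ar_rho == 0 or cfg.innovation_sd == 0:
            eps = innov
        else:
            innov[0] /= np.sqrt(1 - cfg.ar_rho**2)  # stationary start
            eps = lfilter([1.0], [1.0, -cfg.ar_rho], innov)
        out.append(TemperatureSeries(f"m{m:03d}", dates, level + seasonal + eps))
    return out


def _confounders(
    cfg: SimConfig, dates: pd.DatetimeIndex, rng, season_phase: float | None = None
) -> np.ndarray:
    t = np.arange(len(dates), dtype=float)
    if season_phase is None:
        season_phase = rng.uniform(0, 2 * np.pi)
    season = cfg.season_confounder * np.sin(2 * np.pi * t / 365.25 + season_phase)
    dow_effects = cfg.weekly_confounder * np.sin(2 * np.pi * np.arange(7) / 7.0)
    dow = dow_effects[dates.dayofweek]
    trend = cfg.trend_confounder * (t / max(len(t) - 1, 1))
    return season + dow + trend


def simulate_deaths(
    series: TemperatureSeries,
    surface: TrueSurface,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    season_phase: float | None = None,
) -> DeathCountSeries:
    """Daily death counts under the known surface with stratum-level confounding.

    log mu_t = baseline + season_t + weekday_t + trend_t
               + sum_l w_l * f(x_{t-l});
    counts are negative-binomial (size = cfg.dispersion) or Poisson. The first
    ``max_lag`` days serve as exposure burn-in history and emit no counts.
    The mortality-season phase is drawn per call unless ``season_phase`` pins
    it — pin it when simulating subgroups of one population, which share
    their confounder realisation.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    L = surface.max_lag
    if len(series) <= L:
        raise ValidationError(f"series shorter than max_lag={L}")
    fx = surface.f(series.tmean)
    w = surface.lag_weights
    # distributed-lag exposure term: sum_l w_l f(x_{t-l}) for t >= L
    lagged = np.convolve(fx, w, mode="full")[L : len(fx)]
    dates = series.dates[L:]
    eta = cfg.baseline_log_rate + _confounders(cfg, dates, rng, season_phase) + lagged
    if np.any(eta > 30):
        raise ValidationError("rate overflow: reduce baseline_log_rate or slopes")
    mu = np.exp(eta)
    if cfg.dispersion == "poisson":
        counts = rng.poisson(mu)
    else:
        size = float(cfg.dispersion)
        if size <= 0:
            raise ValidationError("negative-binomial size must be positive")
        counts = rng.negative_binomial(size, size / (size + mu))
    return DeathCountSeries(series.municipality_id, "all", dates, counts)


def counts_to_records(
    counts: DeathCountSeries,
    rng: np.random.Generator,
    modifiers: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] | None = None,
) -> pd.DataFrame:
    """Expand a daily count series into one death-record row per death.

    Each record gets a random non-accidental ICD-10 code; ``modifiers`` maps a
    column name to (levels, probabilities) for independent categorical draws.
    """
    n = counts.total
    reps = np.repeat(np.arange(len(counts.dates)), counts.counts)
    df = pd.DataFrame(
        {
            "municipality_id": counts.municipality_id,
            "date": counts.dates[reps].strftime("%Y-%m-%d"),
            "icd10": rng.choice(_NONACCIDENTAL_CODES, size=n),
        }
    )
    if modifiers:
        for col, (levels, probs) in modifiers.items():
            df[col] = rng.choice(levels, size=n, p=probs)
    return df


def simulate_inputs(
    cfg: SimConfig,
    surface: TrueSurface,
    outdir,
    modifiers=None,
) -> dict:
    """Write temperature and death-record tables in the ingest formats.

    Produces ``temperature.csv`` (municipality_id,date,tmean),
    ``deaths.csv`` (record-level), and ``truth.json`` (surface parameters,
    config and seed) for recovery tests. Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    temps = simulate_temperature(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    record_frames = []
    for s in temps:
        counts = simulate_deaths(s, surface, cfg, rng)
        record_frames.append(counts_to_records(counts, rng, modifiers))
    pd.concat([s.to_frame() for s in temps], ignore_index=True).to_csv(
        outdir / "temperature.csv", index=False
    )
    pd.concat(record_frames, ignore_index=True).to_csv(outdir / "deaths.csv", index=False)
    truth = {
        "surface": asdict(surface),
        "config": {k: (v if not isinstance(v, np.floating) else float(v)) for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
    return truth
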