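"""Municipal daily mean-temperature series and regional temperature distributions.

Exposure inputs arrive either as municipal daily min/max (or mean) temperature
tables, or as gridded daily values plus a municipality-to-cell area-fraction
weight table (the tabular extract of a 0.1-degree gridded weather product).
This module turns both into per-municipality ``TemperatureSeries`` and builds
the pooled regional temperature distributions whose percentiles anchor the
cold (1st percentile) and heat (99th percentile) risk contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "RegionalDistribution",
    "ValidationError",
    "daily_mean_from_minmax",
    "area_weighted_series",
    "regional_percentiles",
    "read_municipal_temperature",
    "read_grid_temperature",
    "write_temperature_table",
]


class ValidationError(ValueError):
    """Raised when an input table violates the module's contracts."""


@dataclass
class TemperatureSeries:
    """Daily mean temperature (deg C) for one municipality on a contiguous calendar."""

    municipality_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    tmin: np.ndarray | None = None
    tmax: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        if len(self.dates) != len(self.tmean):
            raise ValidationError(
                f"municipality {self.municipality_id}: dates ({len(self.dates)}) "
                f"and tmean ({len(self.tmean)}) lengths differ"
            )
        if len(self.dates) == 0:
            raise ValidationError(f"municipality {self.municipality_id}: empty series")
        diffs = np.diff(self.dates.values.astype("datetime64[D]").astype(int))
        if len(diffs) and not np.all(diffs == 1):
            bad = self.dates[1:][diffs != 1][0]
            raise ValidationError(
                f"municipality {self.municipality_id}: date index not contiguous "
                f"around {bad.date()}"
            )
        if not np.all(np.isfinite(self.tmean)):
            bad = self.dates[~np.isfinite(self.tmean)][0]
            raise ValidationError(
                f"municipality {self.municipality_id}: missing tmean on {bad.date()}"
            )
        for name in ("tmin", "tmax"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.tmin is not None and self.tmax is not None:
            bad = (self.tmean < self.tmin - 1e-9) | (self.tmean > self.tmax + 1e-9)
            if np.any(bad):
                d = self.dates[bad][0]
                raise ValidationError(
                    f"municipality {self.municipality_id}: tmean outside "
                    f"[tmin, tmax] on {d.date()}"
                )

    def __len__(self) -> int:
        return len(self.dates)

    def window(self, start, end) -> "TemperatureSeries":
        """Restrict to [start, end] inclusive."""
        mask = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        return TemperatureSeries(self.municipality_id, self.dates[mask], self.tmean[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "municipality_id": self.municipality_id,
                "date": self.dates.strftime("%Y-%m-%d"),
                "tmean": self.tmean,
            }
        )


def daily_mean_from_minmax(tmin, tmax):
    """Daily mean temperature as the midpoint of the daily minimum and maximum.

    Accepts scalars or aligned arrays. Raises ``ValidationError`` on non-finite
    values or tmin > tmax, naming the offending position.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    bad = ~(np.isfinite(tmin) & np.isfinite(tmax))
    if np.any(bad):
        idx = int(np.flatnonzero(np.atleast_1d(bad))[0])
        raise ValidationError(f"non-finite tmin/tmax at record {idx}")
    inverted = tmin > tmax
    if np.any(inverted):
        idx = int(np.flatnonzero(np.atleast_1d(inverted))[0])
        raise ValidationError(
            f"tmin > tmax at record {idx} "
            f"(tmin={np.atleast_1d(tmin)[idx]}, tmax={np.atleast_1d(tmax)[idx]})"
        )
    out = (tmin + tmax) / 2.0
    return float(out) if out.ndim == 0 else out


def _validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    required = {"municipality_id", "cell_id", "weight"}
    missing = required - set(weights.columns)
    if missing:
        raise ValidationError(f"weight table missing columns: {sorted(missing)}")
    if weights.duplicated(["municipality_id", "cell_id"]).any():
        raise ValidationError("duplicate (municipality_id, cell_id) pairs in weight table")
    if (weights["weight"] < 0).any():
        raise ValidationError("negative weights in weight table")
    return weights


def area_weighted_series(
    grid_values: pd.DataFrame,
    weights: pd.DataFrame,
    municipality_id: str,
) -> TemperatureSeries:
    """Area-weighted average of grid-cell daily means for one municipality.

    ``grid_values`` has columns ``cell_id, date, tmean`` (or ``tmin``/``tmax``
    from which the mean is computed); ``weights`` has
    ``municipality_id, cell_id, weight`` with weight the fraction of the
    municipality's area covered by that cell. Weights are renormalised to sum
    to one, so truncated weight files (coastlines) are tolerated.
    """
    weights = _validate_weights(weights)
    w = weights.loc[weights["municipality_id"].astype(str) == str(municipality_id)]
    if w.empty:
        raise ValidationError(f"no weights for municipality {municipality_id}")
    total = w["weight"].sum()
    if total <= 0:
        raise ValidationError(f"zero total weight for municipality {municipality_id}")

    gv = grid_values.copy()
    if "tmean" not in gv.columns:
        gv["tmean"] = daily_mean_from_minmax(gv["tmin"].values, gv["tmax"].values)
    gv = gv.loc[gv["cell_id"].isin(w["cell_id"])]

    wide = gv.pivot_table(index="date", columns="cell_id", values="tmean", aggfunc="first")
    missing_cells = set(w["cell_id"]) - set(wide.columns)
    if missing_cells:
        raise ValidationError(
            f"municipality {municipality_id}: no grid values at all for cells "
            f"{sorted(map(str, missing_cells))}"
        )
    wide = wide[list(w["cell_id"])]
    if wide.isna().any().any():
        holes = [
            (str(c), str(d))
            for c in wide.columns
            for d in wide.index[wide[c].isna()][:3]
        ]
        raise ValidationError(
            f"municipality {municipality_id}: missing (cell, date) values, e.g. {holes[:5]}"
        )
    wvec = w["weight"].values / total
    tmean = wide.values @ wvec
    dates = pd.DatetimeIndex(pd.to_datetime(wide.index)).sort_values()
    order = np.argsort(pd.to_datetime(wide.index).values)
    return TemperatureSeries(str(municipality_id), dates, tmean[order])


@dataclass
class RegionalDistribution:
    """Pooled municipality-day temperature distribution for one region."""

    region_id: str
    pooled_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.pooled_values, dtype=float)
        if v.size == 0:
            raise ValidationError(f"region {self.region_id}: empty temperature pool")
        self.pooled_values = np.sort(v)

    def percentile(self, p) -> np.ndarray | float:
        """Quantile under the linear-interpolation convention (rank 1+(n-1)p)."""
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("probabilities must lie in [0, 1]")
        out = np.quantile(self.pooled_values, p, method="linear")
        return float(out) if out.ndim == 0 else out

    def percentile_rank(self, x: float) -> float:
        """Empirical probability p such that percentile(p) ~= x (inverse map)."""
        v = self.pooled_values
        n = len(v)
        if n == 1:
            return 0.5
        # fractional rank of x on the sorted pool, inverse of the linear quantile
        i = np.searchsorted(v, x, side="right")
        if i <= 0:
            return 0.0
        if i >= n:
            return 1.0
        lo, hi = v[i - 1], v[i]
        frac = 0.0 if hi == lo else (x - lo) / (hi - lo)
        return ((i - 1) + frac) / (n - 1)

    @property
    def min(self) -> float:
        return float(self.pooled_values[0])

    @property
    def max(self) -> float:
        return float(self.pooled_values[-1])


def regional_percentiles(
    series: Iterable[TemperatureSeries],
    probs: Sequence[float],
    region_id: str = "region",
) -> np.ndarray:
    """Percentiles of the pooled municipality-day temperature distribution.

    All daily values of all series in the region are pooled unweighted (each
    municipality-day counts once) and quantiles are taken with linear
    interpolation between order statistics.
    """
    series = list(series)
    if not series:
        raise ValidationError("regional_percentiles: no series supplied")
    pooled = np.concatenate([s.tmean for s in series])
    dist = RegionalDistribution(region_id, pooled)
    return np.atleast_1d(dist.percentile(np.asarray(probs, dtype=float)))


def pool_distribution(
    series: Iterable[TemperatureSeries], region_id: str = "region"
) -> RegionalDistribution:
    """Build the pooled ``RegionalDistribution`` for a set of series."""
    series = list(series)
    if not series:
        raise ValidationError("pool_distribution: no series supplied")
    return RegionalDistribution(region_id, np.concatenate([s.tmean for s in series]))


def read_municipal_temperature(path) -> dict[str, TemperatureSeries]:
    """Read a municipal temperature table.

    Columns: ``municipality_id, date, tmin, tmax`` or
    ``municipality_id, date, tmean``; dates ISO-8601.
    """
    df = pd.read_csv(path, dtype={"municipality_id": str})
    if "tmean" not in df.columns:
        if not {"tmin", "tmax"} <= set(df.columns):
            raise ValidationError(
                "temperature table needs either a tmean column or tmin and tmax"
            )
        df["tmean"] = daily_mean_from_minmax(df["tmin"].values, df["tmax"].values)
    df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    out: dict[str, TemperatureSeries] = {}
    for muni, g in df.groupby("municipality_id", sort=True):
        g = g.sort_values("date")
        out[str(muni)] = TemperatureSeries(
            str(muni),
            pd.DatetimeIndex(g["date"]),
            g["tmean"].values,
            tmin=g["tmin"].values if "tmin" in g.columns else None,
            tmax=g["tmax"].values if "tmax" in g.columns else None,
        )
    return out


def read_grid_temperature(grid_path, weights_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read gridded values (``cell_id,date,tmin,tmax``) and the weight table."""
    grid = pd.read_csv(grid_path, dtype={"cell_id": str})
    grid["date"] = pd.to_datetime(grid["date"], format="%Y-%m-%d")
    weights = pd.read_csv(weights_path, dtype={"municipality_id": str, "cell_id": str})
    return grid, _validate_weights(weights)


def write_temperature_table(series: Iterable[TemperatureSeries], path) -> None:
    """Write municipal series as a round-trippable ``municipality_id,date,tmean`` table."""
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)
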