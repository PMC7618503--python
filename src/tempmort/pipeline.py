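"""End-to-end orchestration: regional model selection, fits, MMT/RR reporting.

One-stage pooled analysis: all municipalities of a region enter a single
stratified dataset (strata are municipality x year x month x weekday, so
pooling adds strata, not shared intercepts), the cross-basis specification is
selected per region by qAIC, and cold/heat relative risks are reported at the
1st/99th percentiles of the regional temperature distribution against the
region-specific MMT. Subgroup models refit the same selected specification on
the subgroup's own count series, keeping the overall contrasts. Sensitivity
replays the regional models with a 6-day lag and with alternative knot
placements.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .basis import (
    CrossBasisMatrix,
    CrossBasisSpec,
    cross_basis,
    default_lag_spec,
    spec_from_percentiles,
)
from .conditional import ConditionalFit, FitError, fit_conditional_quasipoisson, select_spec
from .exposure import (
    RegionalDistribution,
    TemperatureSeries,
    ValidationError,
    pool_distribution,
)
from .outcomes import DeathCountSeries, assign_strata
from .reduction import MMTResult, RREstimate, cumulative_contrast, find_mmt, overall_curve

__all__ = ["RunConfig", "RegionResult", "ResultsBundle", "run_region", "run_subgroups", "run_sensitivity", "run_all"]

DEFAULT_KNOT_CANDIDATES = (
    (0.10, 0.75, 0.90),
    (0.25, 0.50, 0.75),
    (0.10, 0.50, 0.90),
    (0.50, 0.90),
)


@dataclass
class RunConfig:
    """Run configuration; serialisable to/from a flat YAML mapping."""

    region_map: Mapping[str, str] = field(default_factory=dict)
    window: tuple[str, str] | None = None
    max_lag: int = 21
    sensitivity_lag: int = 6
    lag_knots: int = 3
    knot_candidates: tuple = DEFAULT_KNOT_CANDIDATES
    cold_percentile: float = 0.01
    heat_percentile: float = 0.99
    mmt_search: tuple[float, float] = (0.01, 0.99)
    mmt_fallback: str | float | None = "national"  # percentile, "national", or None
    subgroups: tuple[str, ...] = ()
    subgroup_min_events: int = 100
    alpha: float = 0.05
    curve_points: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "region_map", "window", "max_lag", "sensitivity_lag", "lag_knots",
            "knot_candidates", "cold_percentile", "heat_percentile", "mmt_search",
            "mmt_fallback", "subgroups", "subgroup_min_events", "alpha",
            "curve_points", "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("knot_candidates",):
            if key in kwargs:
                kwargs[key] = tuple(tuple(k) for k in kwargs[key])
        for key in ("window", "mmt_search"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "subgroups" in kwargs:
            kwargs["subgroups"] = tuple(kwargs["subgroups"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = {
            "region_map": dict(self.region_map),
            "window": list(self.window) if self.window else None,
            "max_lag": self.max_lag,
            "sensitivity_lag": self.sensitivity_lag,
            "lag_knots": self.lag_knots,
            "knot_candidates": [list(k) for k in self.knot_candidates],
            "cold_percentile": self.cold_percentile,
            "heat_percentile": self.heat_percentile,
            "mmt_search": list(self.mmt_search),
            "mmt_fallback": self.mmt_fallback,
            "subgroups": list(self.subgroups),
            "subgroup_min_events": self.subgroup_min_events,
            "alpha": self.alpha,
            "curve_points": self.curve_points,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class RegionResult:
    region: str
    spec: CrossBasisSpec
    fit: ConditionalFit
    qaic_table: pd.DataFrame
    dist: RegionalDistribution
    mmt: MMTResult
    rr_cold: RREstimate
    rr_heat: RREstimate
    curve: pd.DataFrame
    subgroup: str = "all"

    def rr_frame(self) -> pd.DataFrame:
        rows = []
        for rr in (self.rr_cold, self.rr_heat):
            rows.append(
                {
                    "region": self.region,
                    "subgroup": self.subgroup,
                    "contrast": rr.contrast,
                    "percentile": rr.percentile,
                    "temperature": rr.temperature,
                    "mmt": rr.reference,
                    "mmt_fallback": rr.mmt_fallback,
                    "rr": rr.rr,
                    "ci_low": rr.ci_low,
                    "ci_high": rr.ci_high,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ResultsBundle:
    """Collected output tables of a run, writable as delimited text."""

    qaic_tables: pd.DataFrame = field(default_factory=pd.DataFrame)
    fit_summaries: pd.DataFrame = field(default_factory=pd.DataFrame)
    curves: pd.DataFrame = field(default_factory=pd.DataFrame)
    rr_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    logs: pd.DataFrame = field(default_factory=pd.DataFrame)
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.qaic_tables.to_csv(outdir / "qaic_tables.csv", index=False)
        self.fit_summaries.to_csv(outdir / "fit_summaries.csv", index=False)
        self.curves.to_csv(outdir / "curves.csv", index=False)
        self.rr_table.to_csv(outdir / "rr_table.csv", index=False)
        self.logs.to_csv(outdir / "logs.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)


def _stack_region(
    temps: Mapping[str, TemperatureSeries],
    counts: Iterable[DeathCountSeries],
    spec: CrossBasisSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align counts with cross-basis rows per municipality and stack."""
    ys, Ws, strata = [], [], []
    for c in counts:
        if c.municipality_id not in temps:
            raise ValidationError(f"no temperature series for municipality {c.municipality_id}")
        xb = cross_basis(temps[c.municipality_id], spec)
        common = xb.dates.intersection(c.dates)
        if len(common) == 0:
            raise ValidationError(
                f"municipality {c.municipality_id}: no overlap between counts and "
                "cross-basis days"
            )
        ys.append(c.counts[c.dates.get_indexer(common)])
        Ws.append(xb.values[xb.dates.get_indexer(common)])
        strata.append(assign_strata(common, c.municipality_id).values)
    return np.concatenate(ys), np.vstack(Ws), np.concatenate(strata)


def _mmt_and_rrs(
    fit: ConditionalFit,
    spec: CrossBasisSpec,
    dist: RegionalDistribution,
    cfg: RunConfig,
    fallback_percentile: float | None,
    mmt_override: MMTResult | None = None,
) -> tuple[MMTResult, RREstimate, RREstimate]:
    from .reduction import rr_at

    if mmt_override is None:
        ref0 = float(dist.percentile(0.5))

        def curve_fn(x):
            from .reduction import _curve_arrays

            _, log_rr, _ = _curve_arrays(fit, spec, np.atleast_1d(x), ref0)
            return log_rr if np.ndim(x) else float(log_rr[0])

        mmt = find_mmt(curve_fn, dist, search=cfg.mmt_search, fallback_percentile=fallback_percentile)
    else:
        mmt = mmt_override
    t_cold = float(dist.percentile(cfg.cold_percentile))
    t_heat = float(dist.percentile(cfg.heat_percentile))
    rr_cold = rr_at(
        fit, spec, t_cold, mmt.temperature, alpha=cfg.alpha, contrast="cold",
        percentile=cfg.cold_percentile, mmt_fallback=mmt.fallback,
    )
    rr_heat = rr_at(
        fit, spec, t_heat, mmt.temperature, alpha=cfg.alpha, contrast="heat",
        percentile=cfg.heat_percentile, mmt_fallback=mmt.fallback,
    )
    return mmt, rr_cold, rr_heat


def run_region(
    region: str,
    temps: Mapping[str, TemperatureSeries],
    counts: Iterable[DeathCountSeries],
    cfg: RunConfig,
    fallback_percentile: float | None = None,
    spec_override: CrossBasisSpec | None = None,
) -> RegionResult:
    """Select, fit and summarise the model for one region's pooled data.

    ``fallback_percentile`` (if given) is the percentile rank used for the MMT
    when the curve minimum sits at the upper search boundary — the rule the
    analysis applies with the national MMT percentile.
    """
    counts = list(counts)
    if not counts:
        raise ValidationError(f"region {region}: no count series")
    munis = {c.municipality_id for c in counts}
    dist = pool_distribution([temps[m] for m in sorted(munis)], region)

    if spec_override is not None:
        candidates = [spec_override]
    else:
        candidates = [
            spec_from_percentiles(dist, kp, max_lag=cfg.max_lag, lag_knots=cfg.lag_knots)
            for kp in cfg.knot_candidates
        ]
    try:
        spec, fit, qtable = select_spec(
            candidates, lambda s: _stack_region(temps, counts, s)
        )
    except FitError as exc:
        raise FitError(f"region {region}: {exc}") from exc
    qtable.insert(0, "region", region)

    mmt, rr_cold, rr_heat = _mmt_and_rrs(fit, spec, dist, cfg, fallback_percentile)
    grid = np.linspace(dist.min, dist.max, cfg.curve_points)
    curve = overall_curve(fit, spec, grid, mmt.temperature, alpha=cfg.alpha).to_frame(
        region=region
    )
    return RegionResult(region, spec, fit, qtable, dist, mmt, rr_cold, rr_heat, curve)


def run_subgroups(
    overall: RegionResult,
    temps: Mapping[str, TemperatureSeries],
    subgroup_counts: Mapping[str, list[DeathCountSeries]],
    cfg: RunConfig,
) -> tuple[list[RegionResult], pd.DataFrame]:
    """Fit one independent model per subgroup level.

    Subgroup fits reuse the overall model's selected cross-basis spec and the
    overall regional percentile contrasts and MMT (effect modification is
    assessed on a common reference). Levels with fewer total events than
    ``cfg.subgroup_min_events`` are skipped with a log entry.
    """
    results = []
    log_rows = []
    for level in sorted(subgroup_counts):
        counts = subgroup_counts[level]
        total = sum(c.total for c in counts)
        if total < cfg.subgroup_min_events:
            log_rows.append(
                {"region": overall.region, "subgroup": level, "event": "skipped_low_events", "count": total}
            )
            continue
        y, W, st = _stack_region(temps, counts, overall.spec)
        fit = fit_conditional_quasipoisson(y, W, st)
        mmt, rr_cold, rr_heat = _mmt_and_rrs(
            fit, overall.spec, overall.dist, cfg, None, mmt_override=overall.mmt
        )
        grid = np.linspace(overall.dist.min, overall.dist.max, cfg.curve_points)
        curve = overall_curve(fit, overall.spec, grid, mmt.temperature, alpha=cfg.alpha).to_frame(
            region=overall.region, subgroup=level
        )
        results.append(
            RegionResult(
                overall.region, overall.spec, fit, overall.qaic_table, overall.dist,
                mmt, rr_cold, rr_heat, curve, subgroup=level,
            )
        )
    return results, pd.DataFrame(log_rows)


def run_sensitivity(
    overall: RegionResult,
    temps: Mapping[str, TemperatureSeries],
    counts: Iterable[DeathCountSeries],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Shorter-lag and knot-variant reruns; side-by-side RR comparison table."""
    counts = list(counts)
    rows = []

    def row_from(result: RegionResult, variant: str) -> None:
        for rr in (result.rr_cold, result.rr_heat):
            rows.append(
                {
                    "region": result.region,
                    "variant": variant,
                    "contrast": rr.contrast,
                    "rr": rr.rr,
                    "ci_low": rr.ci_low,
                    "ci_high": rr.ci_high,
                    "mmt": rr.reference,
                    "qaic": result.fit.qaic,
                }
            )

    row_from(overall, f"lag{cfg.max_lag}-main")

    # shorter lag period, same exposure knots
    short = CrossBasisSpec(
        overall.spec.exposure_spec,
        default_lag_spec(
            cfg.sensitivity_lag, min(cfg.lag_knots, max(cfg.sensitivity_lag - 2, 0))
        ),
        max_lag=cfg.sensitivity_lag,
        label=f"lag{cfg.sensitivity_lag}",
    )
    res_short = run_region(
        overall.region, temps, counts, cfg, spec_override=short
    )
    row_from(res_short, f"lag{cfg.sensitivity_lag}")

    # knot-placement variants at the main lag
    for kp in cfg.knot_candidates:
        spec_v = spec_from_percentiles(
            overall.dist, kp, max_lag=cfg.max_lag, lag_knots=cfg.lag_knots
        )
        if spec_v.to_dict() == overall.spec.to_dict():
            continue
        res_v = run_region(overall.region, temps, counts, cfg, spec_override=spec_v)
        row_from(res_v, f"knots-{spec_v.label}")
    return pd.DataFrame(rows)


def run_all(
    temps: Mapping[str, TemperatureSeries],
    counts: Iterable[DeathCountSeries],
    cfg: RunConfig,
    subgroup_counts: Mapping[str, Mapping[str, list[DeathCountSeries]]] | None = None,
) -> ResultsBundle:
    """National fit, then per-region fits with the national-MMT-percentile fallback.

    ``counts`` are overall (subgroup "all") series; ``subgroup_counts`` maps
    region -> subgroup level -> series list. Regions come from
    ``cfg.region_map`` (default: one national region).
    """
    counts = list(counts)
    region_of = dict(cfg.region_map) or {c.municipality_id: "all" for c in counts}
    missing = {c.municipality_id for c in counts} - set(region_of)
    if missing:
        raise ValidationError(f"municipalities not in region map: {sorted(missing)}")

    national = run_region("national", temps, counts, cfg, fallback_percentile=None)
    national_pct = national.mmt.percentile

    if cfg.mmt_fallback == "national":
        fallback = national_pct
    elif cfg.mmt_fallback is None:
        fallback = None
    else:
        fallback = float(cfg.mmt_fallback)

    results = [national]
    sub_logs = []
    regions = sorted(set(region_of.values()))
    for region in regions:
        rc = [c for c in counts if region_of[c.municipality_id] == region]
        if not rc:
            continue
        res = run_region(region, temps, rc, cfg, fallback_percentile=fallback)
        results.append(res)
        if subgroup_counts and region in subgroup_counts:
            sres, slog = run_subgroups(res, temps, subgroup_counts[region], cfg)
            results.extend(sres)
            if len(slog):
                sub_logs.append(slog)

    bundle = ResultsBundle(
        qaic_tables=pd.concat(
            [r.qaic_table.assign(subgroup=r.subgroup) for r in results], ignore_index=True
        ),
        fit_summaries=pd.concat(
            [
                r.fit.model_row().assign(region=r.region, subgroup=r.subgroup)
                for r in results
            ],
            ignore_index=True,
        ),
        curves=pd.concat([r.curve for r in results], ignore_index=True),
        rr_table=pd.concat([r.rr_frame() for r in results], ignore_index=True),
        logs=pd.concat(sub_logs, ignore_index=True) if sub_logs else pd.DataFrame(
            columns=["region", "subgroup", "event", "count"]
        ),
    )
    cfg_text = json.dumps(
        {"max_lag": cfg.max_lag, "knot_candidates": [list(k) for k in cfg.knot_candidates],
         "cold": cfg.cold_percentile, "heat": cfg.heat_percentile, "seed": cfg.seed},
        sort_keys=True,
    )
    bundle.manifest = {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "seed": cfg.seed,
        "national_mmt": national.mmt.temperature,
        "national_mmt_percentile": national_pct,
        "regions": regions,
    }
    return bundle
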