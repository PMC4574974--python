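"""End-to-end orchestration: simulate → kill series → AFT → rates →
home ranges → spatial risk, with a JSON run log.

`RunConfig` defaults carry the analysis constants (censoring at 9 d roe /
12 d red, 365 / 182.5-day horizons, 5,000 bootstrap replicates, 95% MCP,
500 m cells, winter from 1 Nov to 31 Mar); every override is recorded in
the run log so a run is reproducible from the log alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lynxkill import aftmodel, homerange, io, killrate, killseries, \
    spatialrisk, synthio

FEMALE_STATUSES = {"single_adult_female", "subadult_female", "family_group"}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "lynxkill_run"
    seed: int = 0
    simulate: bool = True
    fixes_path: str | None = None
    kills_path: str | None = None
    grid_path: str | None = None
    censor_thresholds: dict = field(
        default_factory=lambda: dict(killseries.CENSOR_THRESHOLDS))
    horizons: tuple[float, float] = (365.0, 182.5)
    n_boot: int = 5000
    mcp_level: float = 0.95
    cell_size: float = 500.0
    distribution: str = "weibull"
    risk_stage: bool = True
    sim: dict = field(default_factory=dict)   # overrides for synthio.SimConfig

    def to_log(self) -> dict:
        d = asdict(self)
        d["horizons"] = list(self.horizons)
        return d


def _season_mixed_sampler(fit: aftmodel.AftFit, status: str, species: str,
                          p_summer: float = 214.0 / 365.0):
    """Inter-kill-time sampler that draws each interval's season from the
    calendar share of summer vs winter days."""

    def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
        summer = rng.uniform(size=size) < p_summer
        out = np.empty(size)
        n_s = int(summer.sum())
        if n_s:
            out[summer] = fit.model.sample(
                {"status": status, "species": species, "season": "summer"},
                n_s, rng)
        if size - n_s:
            out[~summer] = fit.model.sample(
                {"status": status, "species": species, "season": "winter"},
                size - n_s, rng)
        return out

    return sampler


def report_rate_table(
    fit: aftmodel.AftFit | None = None,
    shares: dict[tuple[str, str], float] | None = None,
    mcp_means: dict[str, float] | None = None,
    prey_times: dict[tuple[str, str], float] | None = None,
    horizon: float = 365.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Kill-rate report table: one row per lynx status × deer species.

    Either a fitted AFT model (``fit``) supplies the prey times — the
    season-weighted model prediction — and a parametric bootstrap supplies
    predicted rates, or printed ``prey_times`` are used directly (then the
    predicted-rate columns are NaN).  ``shares`` maps (status, species) to
    the kill-series percentage; ``mcp_means`` maps "male"/"female" to the
    mean 95% MCP area in km².  Strata absent from ``shares`` are reported
    with NaN rates rather than imputed.
    """
    if (fit is None) == (prey_times is None):
        raise ValueError("supply exactly one of fit or prey_times")
    shares = shares or {}
    statuses = ["adult_male", "single_adult_female", "subadult_female",
                "family_group"]
    w_summer = 214.0 / 365.0
    rows = []
    for species in ("roe", "red"):
        for status in statuses:
            if prey_times is not None:
                pt = prey_times.get((status, species), np.nan)
                pred = (np.nan, np.nan, np.nan)
            else:
                t_summer = aftmodel.predict_mean_time(
                    fit, {"status": status, "species": species,
                          "season": "summer"})
                t_winter = aftmodel.predict_mean_time(
                    fit, {"status": status, "species": species,
                          "season": "winter"})
                pt = w_summer * t_summer + (1.0 - w_summer) * t_winter
                est = killrate.bootstrap_rate_from_sampler(
                    _season_mixed_sampler(fit, status, species),
                    horizon=horizon, n_boot=n_boot, seed=seed)
                pred = (est.lo, est.median_kills, est.hi)
            share = shares.get((status, species), np.nan)
            actual = (killrate.actual_rate(pt, share, horizon)
                      if np.isfinite(pt) and np.isfinite(share) else np.nan)
            sex = "male" if status == "adult_male" else "female"
            area = (mcp_means or {}).get(sex, np.nan)
            per_km2 = (killrate.per_area_rate(actual, area)
                       if np.isfinite(actual) and np.isfinite(area)
                       else np.nan)
            rows.append({
                "status": status, "species": species, "prey_time": pt,
                "predicted_lo": pred[0], "predicted_median": pred[1],
                "predicted_hi": pred[2], "share_pct": share,
                "actual_rate": actual, "mcp_km2": area,
                "per_km2_rate": per_km2,
            })
    return pd.DataFrame(rows)


def _shares_from_summary(summary: killseries.SeriesSummary) -> dict:
    shares = {}
    for rec in summary.by_status.itertuples():
        shares[(rec.status, rec.species)] = rec.share_pct
    return shares


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the map of written artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "configure"
    try:
        stage = "inputs"
        if config.simulate:
            sim_cfg = synthio.SimConfig(seed=config.seed, **config.sim)
            paths = synthio.write_fixtures(sim_cfg, outdir / "fixtures")
            fixes = io.read_fixes(paths["fixes"])
            kills = io.read_kills(paths["kills"])
            grid = io.read_grid(paths["grid"])
            artifacts.update(paths)
        else:
            if config.risk_stage and config.grid_path is None:
                raise ValueError("risk stage enabled but no grid supplied")
            fixes = io.read_fixes(config.fixes_path)
            kills = io.read_kills(config.kills_path)
            grid = (io.read_grid(config.grid_path)
                    if config.grid_path else None)

        stage = "killseries"
        analysis_kills = killseries.filter_analysis_kills(kills)
        intervals = killseries.build_intervals(analysis_kills)
        intervals = killseries.censor_intervals(
            intervals, config.censor_thresholds)
        artifacts["intervals"] = io.write_table(
            intervals, outdir / "intervals.csv", io.INTERVALS_COLUMNS)
        summary = killseries.summarize_series(analysis_kills)
        artifacts["summary"] = io.write_table(
            summary.by_status, outdir / "summary.csv")

        stage = "aft"
        spec = aftmodel.AftSpec(distribution=config.distribution)
        fit = aftmodel.fit_aft(intervals, spec)
        artifacts["aft_summary"] = io.write_table(
            fit.summary(), outdir / "aft_summary.csv")

        stage = "homerange"
        hr_table = homerange.mcp_table(fixes, level=config.mcp_level)
        artifacts["homeranges"] = io.write_table(
            hr_table, outdir / "homeranges.csv",
            ["lynx_id", "level", "n_fixes", "area_km2"])
        ranges = [homerange.mcp(fixes[fixes["lynx_id"] == lid],
                                level=config.mcp_level, lynx_id=str(lid))
                  for lid in hr_table["lynx_id"]]
        hull_path = outdir / "homeranges.geojson"
        hull_path.write_text(json.dumps(homerange.hulls_geojson(ranges)))
        artifacts["hulls"] = hull_path
        male_ids = set(kills.loc[kills["status"] == "adult_male", "lynx_id"]
                       .astype(str))
        is_male = hr_table["lynx_id"].astype(str).isin(male_ids)
        mcp_means = {
            "male": float(hr_table.loc[is_male, "area_km2"].mean()),
            "female": float(hr_table.loc[~is_male, "area_km2"].mean()),
        }

        stage = "rates"
        rates = report_rate_table(fit=fit, shares=_shares_from_summary(summary),
                              mcp_means=mcp_means, horizon=config.horizons[0],
                              n_boot=config.n_boot, seed=config.seed)
        artifacts["rates"] = io.write_table(rates, outdir / "rates.csv")

        if config.risk_stage:
            stage = "spatialrisk"
            grid_counts, n_outside = spatialrisk.rasterize_kills(
                kills, grid, cell_size=config.cell_size)
            risk_frames, zone_rows = [], []
            for season in ("summer", "winter"):
                if (grid_counts[f"kills_{season}"] >= 1).sum() < 10:
                    continue
                s1 = spatialrisk.fit_presence(grid_counts, season)
                s2 = spatialrisk.fit_conditional_count(grid_counts, season)
                surface = spatialrisk.combine_hurdle(
                    s1, s2, grid_counts, season=season)
                partial = spatialrisk.partial_risk(
                    s1, s2, grid_counts, season=season)
                tab = surface.table.copy()
                tab["season"] = season
                tab["partial_expected"] = partial.table["expected"]
                risk_frames.append(tab)
                zc = spatialrisk.compare_zones(surface, grid_counts)
                zt = zc.table.copy()
                zt["season"] = season
                zt["altitude_correlation"] = zc.altitude_correlation
                zone_rows.append(zt)
            if risk_frames:
                artifacts["risk"] = io.write_table(
                    pd.concat(risk_frames, ignore_index=True),
                    outdir / "risk.csv",
                    ["quad_id", "season", "p", "mu_cond", "expected",
                     "partial_expected"])
                artifacts["zones"] = io.write_table(
                    pd.concat(zone_rows, ignore_index=True),
                    outdir / "zones.csv")

        stage = "log"
        log = {
            "config": config.to_log(),
            "n_kills": int(len(kills)),
            "n_intervals": int(len(intervals)),
            "n_censored": int((~intervals["event"]).sum()),
            "kills_outside_grid": (int(n_outside)
                                   if config.risk_stage else None),
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        (outdir / "run.json").write_text(json.dumps(log, indent=2))
        artifacts["log"] = outdir / "run.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
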