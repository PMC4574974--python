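"""Kill rates: bootstrap renewal estimates, the actual-rate formula,
per-km² predation pressure, and cross-study recalculations.

Two rate notions coexist:

* the *predicted* rate — a parametric bootstrap of the fitted inter-kill
  time model: draw consecutive prey times, count how many fit into the
  horizon (365 d annual, 182.5 d seasonal), summarize over replicates;
* the *actual* rate — the deterministic formula

      rate = horizon * (species share in the kill series / 100) / prey time

  which scales the single-species renewal rate by the observed share of
  that species in the lynx's kill series.

Dividing an annual rate by the mean 95% MCP home-range area gives the
predation pressure in kills / year / km².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from lynxkill.aftmodel import AftFit


@dataclass
class RateEstimate:
    """Bootstrap kill-count distribution over one horizon."""

    horizon: float
    median_kills: float
    lo: float                  # 2.5% percentile
    hi: float                  # 97.5% percentile
    n_boot: int

    def __post_init__(self) -> None:
        if not self.lo <= self.median_kills <= self.hi:
            raise ValueError("percentiles must bracket the median")


def _count_renewals(times: np.ndarray, horizon: float,
                    rule: str) -> np.ndarray:
    """Kills per replicate: rows of inter-kill times vs a horizon.

    ``rule="within"`` counts intervals whose cumulative time stays <= the
    horizon; ``rule="crossing"`` counts up to and including the interval
    that first crosses it.
    """
    cum = np.cumsum(times, axis=1)
    if rule == "within":
        return (cum <= horizon).sum(axis=1)
    if rule == "crossing":
        return np.minimum((cum < horizon).sum(axis=1) + 1, times.shape[1])
    raise ValueError(f"unknown counting rule {rule!r}")


def bootstrap_rate_from_sampler(
    sampler: Callable[[np.random.Generator, int], np.ndarray],
    horizon: float,
    n_boot: int = 5000,
    seed: int = 0,
    rule: str = "within",
) -> RateEstimate:
    """Bootstrap the number of kills in a horizon from an inter-kill-time
    sampler ``sampler(rng, size) -> durations``.

    Each replicate stacks independent draws until their cumulative sum
    exceeds the horizon and counts the completed intervals.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed)
    probe = np.asarray(sampler(rng, 64), float)
    if np.any(probe <= 0):
        raise ValueError("sampler must return positive durations")
    mean_t = float(probe.mean())
    m = int(np.ceil(horizon / mean_t * 1.5 + 10 * np.sqrt(horizon / mean_t) + 5))

    draws = np.asarray(sampler(rng, n_boot * m), float).reshape(n_boot, m)
    total = draws.sum(axis=1)
    while np.any(total <= horizon):          # extend short replicates
        extra = np.asarray(sampler(rng, n_boot * m), float).reshape(n_boot, m)
        draws = np.hstack([draws, extra])
        total = draws.sum(axis=1)
        m = draws.shape[1]

    counts = _count_renewals(draws, horizon, rule)
    lo, med, hi = np.percentile(counts, [2.5, 50.0, 97.5])
    return RateEstimate(horizon=horizon, median_kills=float(med),
                        lo=float(lo), hi=float(hi), n_boot=n_boot)


def bootstrap_rate(fit: AftFit, setting: dict[str, str], horizon: float,
                   n_boot: int = 5000, seed: int = 0,
                   rule: str = "within") -> RateEstimate:
    """Parametric bootstrap of the kill count at one covariate setting of a
    fitted AFT model (median and 2.5/97.5 percentiles over replicates)."""
    return bootstrap_rate_from_sampler(
        lambda rng, size: fit.model.sample(setting, size, rng),
        horizon=horizon, n_boot=n_boot, seed=seed, rule=rule)


def bootstrap_rate_nonparametric(prey_times, horizon: float,
                                 n_boot: int = 5000, seed: int = 0,
                                 rule: str = "within") -> RateEstimate:
    """Nonparametric variant: resample observed per-stratum prey times."""
    times = np.asarray(prey_times, float)
    if len(times) == 0 or np.any(times <= 0):
        raise ValueError("need positive observed prey times")
    return bootstrap_rate_from_sampler(
        lambda rng, size: rng.choice(times, size=size, replace=True),
        horizon=horizon, n_boot=n_boot, seed=seed, rule=rule)


def actual_rate(prey_time: float, share_pct: float,
                horizon: float = 365.0) -> float:
    """Actual kill rate: ``horizon * (share_pct / 100) / prey_time``."""
    if prey_time <= 0:
        raise ValueError("prey_time must be positive")
    if not 0.0 <= share_pct <= 100.0:
        raise ValueError("share_pct must be in [0, 100]")
    return horizon * (share_pct / 100.0) / prey_time


def per_area_rate(actual: float, mcp_km2: float) -> float:
    """Kills / year / km²: an annual rate over a mean 95% MCP area."""
    if mcp_km2 <= 0:
        raise ValueError("home-range area must be positive")
    return actual / mcp_km2


def crossstudy_rate(mean_prey_time: float | None = None,
                    share_pct: float | None = None,
                    kills: float | None = None,
                    per_days: float | None = None) -> float:
    """Recalculate a published kill rate to kills / 365 days.

    Either from a reported mean prey time and species share
    (``365 * share/100 / prey_time``), or from a reported count per period
    (``kills * 365 / per_days``).  Exactly one form must be supplied.
    """
    form1 = mean_prey_time is not None and share_pct is not None
    form2 = kills is not None and per_days is not None
    if form1 == form2:
        raise ValueError(
            "supply either (mean_prey_time, share_pct) or (kills, per_days)")
    if form1:
        return actual_rate(mean_prey_time, share_pct, horizon=365.0)
    if per_days <= 0:
        raise ValueError("per_days must be positive")
    return kills * 365.0 / per_days


def combine_local_impact(per_km2_rates) -> float:
    """Summed local predation pressure where territories overlap (e.g. a
    male's range overlapping one or more female ranges)."""
    rates = np.asarray(list(per_km2_rates), float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    return float(rates.sum())
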