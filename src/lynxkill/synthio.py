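"""Synthetic landscapes, lynx, kill processes, and GPS fixes.

The generator emulates the data-generating structure the analysis assumes,
so that every downstream module can be exercised and validated end to end:

* a quadrant landscape (500 m cells) with a high-altitude protected core,
  forest cover, and distance-to-civilization covariates;
* per-lynx kill processes whose log inter-kill (prey) times follow a
  log-normal accelerated-failure-time structure with lynx-status, prey
  species and season effects, species shares per status, and a winter
  concentration of kills at low altitude;
* a collar schedule with two daily fixes (00:00, 12:00) plus night fixes
  clustered at kill sites on handling nights;
* a configurable carcass miss rate producing "virtual kills".

All randomness flows from one seed via per-lynx child streams, so output is
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lynxkill import io
from lynxkill.killseries import assign_season

#: Log-days effects of the default prey-time structure (reference levels:
#: single adult female, red deer, summer).
DEFAULT_AFT_COEFFICIENTS: dict[str, float] = {
    "intercept": 2.516,
    "status_adult_male": -0.157,
    "status_family_group": -0.386,
    "status_subadult_female": -0.086,
    "species_roe": -0.518,
    "season_winter": -0.219,
}

#: Roe-deer share of deer kills per lynx status (remainder is red deer).
DEFAULT_SPECIES_SHARES: dict[str, dict[str, float]] = {
    "adult_male": {"roe": 0.751, "red": 0.249},
    "single_adult_female": {"roe": 0.923, "red": 0.077},
    "subadult_female": {"roe": 0.957, "red": 0.043},
    "family_group": {"roe": 0.967, "red": 0.033},
}


@dataclass
class SimConfig:
    """Configuration of one synthetic study.

    ``aft_scale`` is the log-normal σ of log prey times (the field study does
    not report a dispersion; 0.55 gives a realistic spread around ~6-day
    means).  ``miss_rate`` is the probability that a kill's carcass is never
    found, producing a virtual kill.  ``winter_altitude_bias`` scales the
    softmax pull of winter kills toward low altitude.
    """

    n_lynx: dict[str, int] = field(default_factory=lambda: {
        "adult_male": 3, "single_adult_female": 2,
        "subadult_female": 2, "family_group": 2,
    })
    monitoring_days: int = 365
    start_date: str = "2010-04-01"
    aft_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AFT_COEFFICIENTS))
    aft_scale: float = 0.55
    species_shares: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_SPECIES_SHARES.items()})
    miss_rate: float = 0.30
    handling_beta: tuple[float, float] = (4.0, 3.0)
    winter_altitude_bias: float = 3.0
    n_x: int = 30
    n_y: int = 30
    cell_size: float = 500.0
    cluster_radius_m: float = 100.0
    step_sd_m: float = 1500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_x < 4 or self.n_y < 4:
            raise ValueError("grid dimensions must be at least 4x4")
        if self.aft_scale <= 0:
            raise ValueError("aft_scale must be positive")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must be in [0, 1]")
        for status, shares in self.species_shares.items():
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ValueError(f"species shares for {status} must sum to 1")

    def lynx_rngs(self) -> list[tuple[str, str, np.random.Generator]]:
        """One independent child stream per lynx, split from the seed."""
        labels = [(f"{status[:2].upper()}{i + 1}", status)
                  for status in sorted(self.n_lynx)
                  for i in range(self.n_lynx[status])]
        children = np.random.SeedSequence(self.seed).spawn(len(labels) + 1)
        return [(lid, status, np.random.default_rng(ss))
                for (lid, status), ss in zip(labels, children[1:])]


@dataclass
class Landscape:
    """Quadrant grid with covariates; a ridge-shaped protected core."""

    n_x: int
    n_y: int
    cell_size: float
    altitude: np.ndarray    # meters a.s.l., length n_x*n_y
    forest: np.ndarray      # proportion in [0, 1]
    dist_civ: np.ndarray    # meters to nearest town cell
    np_mask: np.ndarray     # True inside the national park

    @property
    def n_quadrants(self) -> int:
        return self.n_x * self.n_y

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        ix, iy = np.meshgrid(np.arange(self.n_x), np.arange(self.n_y),
                             indexing="ij")
        cx = (ix.ravel() + 0.5) * self.cell_size
        cy = (iy.ravel() + 0.5) * self.cell_size
        return cx, cy

    def to_frame(self) -> pd.DataFrame:
        cx, cy = self.centroids()
        return pd.DataFrame({
            "quad_id": np.arange(self.n_quadrants),
            "cx_m": cx, "cy_m": cy,
            "forest": self.forest,
            "altitude_m": self.altitude,
            "dist_civ_m": self.dist_civ,
            "in_np": self.np_mask.astype(int),
        })


def make_landscape(config: SimConfig) -> Landscape:
    """Build a landscape whose altitude ridge sits inside the park mask and
    declines outward, with towns (``dist_civ = 0``) outside the park."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    nx, ny = config.n_x, config.n_y
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ix, iy = ix.ravel().astype(float), iy.ravel().astype(float)

    # Ridge running through the upper-middle of the grid.
    ridge_x, ridge_y = 0.5 * (nx - 1), 0.68 * (ny - 1)
    d_ridge = np.hypot((ix - ridge_x) / nx, (iy - ridge_y) / ny)
    altitude = 1300.0 - 900.0 * d_ridge + rng.normal(0.0, 15.0, ix.size)

    # Park: contiguous block around the ridge (highest cells).
    np_mask = d_ridge <= np.quantile(d_ridge, 0.35)

    # Heavily forested landscape throughout; forest cover varies cell to cell
    # but is not tied to altitude, so the protected (high-altitude) core and
    # its surroundings offer comparable habitat.
    forest = np.clip(0.62 + rng.normal(0.0, 0.15, ix.size), 0.0, 1.0)

    # Towns: a few low-altitude cells outside the park.
    outside = np.flatnonzero(~np_mask)
    order = outside[np.argsort(altitude[outside])]
    towns = order[:max(1, len(order) // 80)]
    cx = (ix + 0.5) * config.cell_size
    cy = (iy + 0.5) * config.cell_size
    dist_civ = np.min(
        np.hypot(cx[:, None] - cx[towns][None, :],
                 cy[:, None] - cy[towns][None, :]), axis=1)

    return Landscape(n_x=nx, n_y=ny, cell_size=config.cell_size,
                     altitude=altitude, forest=forest, dist_civ=dist_civ,
                     np_mask=np_mask)


def linear_predictor(coefs: dict[str, float], status: str, species: str,
                     season: str) -> float:
    """Log-days location of the prey-time distribution at one covariate cell."""
    lp = coefs["intercept"]
    lp += coefs.get(f"status_{status}", 0.0)
    if species == "roe":
        lp += coefs["species_roe"]
    if season == "winter":
        lp += coefs["season_winter"]
    return lp


def _kill_cell_weights(landscape: Landscape, season: str,
                       bias: float) -> np.ndarray:
    # Kills sit in forested habitat in both seasons; winter adds a softmax
    # pull toward low altitude (bias 0 makes the seasons indistinguishable).
    w = (landscape.forest > 0.5).astype(float) + 1e-3
    if season == "winter":
        z = (landscape.altitude - landscape.altitude.mean())
        z /= max(landscape.altitude.std(), 1e-12)
        w = w * np.exp(-bias * z)
    return w / w.sum()


def simulate_killseries(config: SimConfig,
                        landscape: Landscape) -> pd.DataFrame:
    """Simulate the kill record of every lynx over its monitoring period.

    Prey times are log-normal draws at the covariate cell of each kill;
    species are drawn from the status-specific shares; winter kills are
    placed with probability proportional to a softmax over −bias·altitude,
    summer kills near-uniformly over forested cells.  Handling is a
    Beta(4, 3) fraction of prey time; carcasses are missed (virtual kills)
    with probability ``miss_rate``.
    """
    config.validate()
    start = pd.Timestamp(config.start_date)
    cx, cy = landscape.centroids()
    a, b = config.handling_beta

    rows = []
    for lynx_id, status, rng in config.lynx_rngs():
        t = float(rng.uniform(0.0, 3.0))   # days since collar start
        while t < config.monitoring_days:
            kill_date = start + pd.Timedelta(days=t)
            season = assign_season(kill_date)
            species = ("roe" if rng.uniform()
                       < config.species_shares[status]["roe"] else "red")
            lp = linear_predictor(config.aft_coefficients, status, species,
                                  season)
            prey_time = float(np.exp(rng.normal(lp, config.aft_scale)))
            handling = float(rng.beta(a, b)) * prey_time
            weights = _kill_cell_weights(landscape, season,
                                         config.winter_altitude_bias)
            cell = int(rng.choice(landscape.n_quadrants, p=weights))
            jitter = rng.uniform(-0.4, 0.4, 2) * landscape.cell_size
            rows.append({
                "lynx_id": lynx_id,
                "status": status,
                "species": species,
                "kill_date": kill_date,
                "left_date": kill_date + pd.Timedelta(days=handling),
                "x_m": cx[cell] + jitter[0],
                "y_m": cy[cell] + jitter[1],
                "found": int(rng.uniform() >= config.miss_rate),
            })
            t += prey_time
    kills = pd.DataFrame(rows, columns=io.KILLS_COLUMNS)
    return kills.sort_values(["lynx_id", "kill_date"],
                             kind="stable").reset_index(drop=True)


def simulate_gps(kills: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Emit the collar schedule: 00:00 and 12:00 fixes every monitored day
    along a correlated random walk, with every midnight fix during a kill's
    handling window relocated to within ``cluster_radius_m`` of its site."""
    config.validate()
    start = pd.Timestamp(config.start_date).normalize()
    rows = []
    for lynx_id, status, rng in config.lynx_rngs():
        own = kills[kills["lynx_id"] == lynx_id]
        k_start = own["kill_date"].to_numpy()
        k_left = own["left_date"].to_numpy()
        kx = own["x_m"].to_numpy(float)
        ky = own["y_m"].to_numpy(float)
        pos = np.array([kx[0], ky[0]]) if len(own) else np.array([0.0, 0.0])
        heading = rng.uniform(0.0, 2.0 * np.pi)
        for d in range(config.monitoring_days):
            for hour in (0, 12):
                ts = start + pd.Timedelta(days=d, hours=hour)
                heading += rng.normal(0.0, 0.6)
                step = abs(rng.normal(0.0, config.step_sd_m))
                pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
                x, y = pos
                if hour == 0 and len(own):
                    ts64 = np.datetime64(ts)
                    at_kill = (k_start <= ts64) & (ts64 <= k_left)
                    if at_kill.any():
                        i = int(np.flatnonzero(at_kill)[0])
                        r = config.cluster_radius_m * np.sqrt(rng.uniform())
                        th = rng.uniform(0.0, 2.0 * np.pi)
                        x = kx[i] + r * np.cos(th)
                        y = ky[i] + r * np.sin(th)
                        pos = np.array([x, y])
                rows.append({"lynx_id": lynx_id, "timestamp": ts,
                             "x_m": x, "y_m": y})
    return pd.DataFrame(rows, columns=io.FIXES_COLUMNS)


def write_fixtures(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate one study and write fixes.csv, kills.csv, grid.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape = make_landscape(config)
    kills = simulate_killseries(config, landscape)
    fixes = simulate_gps(kills, config)
    paths = {
        "fixes": io.write_table(fixes, outdir / "fixes.csv", io.FIXES_COLUMNS),
        "kills": io.write_table(kills, outdir / "kills.csv", io.KILLS_COLUMNS),
        "grid": io.write_table(landscape.to_frame(), outdir / "grid.csv",
                               io.GRID_COLUMNS),
    }
    return paths
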