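"""Kill series: prey intervals, censoring, seasons, and kill-site clusters.

The unit of analysis is the *prey interval* of a collared lynx:

* handling time — nights the lynx revisited the same carcass;
* searching time — time from leaving that carcass to the next kill;
* prey time — handling + searching, the inter-kill interval.

Virtual kills (GPS-cluster patterns with no carcass found) reset the
searching clock but are excluded from species-share summaries.  Implausibly
long prey times are right-censored per species (roe deer > 9 d, red deer
> 12 d): the duration is retained, the event flag is cleared.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

#: Right-censoring thresholds in days, per prey species.
CENSOR_THRESHOLDS: dict[str, float] = {"roe": 9.0, "red": 12.0}

#: Months belonging to the winter season (1 November – 31 March).
WINTER_MONTHS = frozenset({11, 12, 1, 2, 3})


class LynxStatus(str, enum.Enum):
    """Demographic status of a collared lynx; the stratification unit.

    Females switch between ``single_adult_female`` and ``family_group``
    (female with two kittens) over a monitoring period, so status is a
    property of each kill record, not of the animal.
    """

    ADULT_MALE = "adult_male"
    SINGLE_ADULT_FEMALE = "single_adult_female"
    SUBADULT_FEMALE = "subadult_female"
    FAMILY_GROUP = "family_group"


#: Statuses dropped from analysis sets for insufficient sample size.
EXCLUDED_STATUSES = frozenset(
    {"juvenile", "subadult_male", "family_group_one_kitten"}
)

ANALYSIS_STATUSES = frozenset(s.value for s in LynxStatus)


@dataclass(frozen=True)
class PreyInterval:
    """One inter-kill record.  ``prey_time == handling_time + searching_time``."""

    lynx_id: str
    status: str
    species: str
    season: str
    handling_time: float
    searching_time: float
    prey_time: float
    event: bool = True
    involves_virtual: bool = False

    def __post_init__(self) -> None:
        if self.handling_time < 0 or self.searching_time < 0:
            raise ValueError("times must be non-negative")
        if abs(self.prey_time - (self.handling_time + self.searching_time)) > 1e-9:
            raise ValueError("prey_time must equal handling + searching")


def assign_season(date) -> str:
    """Label a calendar date ``"winter"`` (1 Nov – 31 Mar) or ``"summer"``.

    Accepts anything :func:`pandas.Timestamp` can parse.
    """
    ts = pd.Timestamp(date)
    if pd.isna(ts):
        raise ValueError(f"unparseable date: {date!r}")
    return "winter" if ts.month in WINTER_MONTHS else "summer"


def _night_key(timestamps: pd.Series, night_end_hour: int) -> pd.Series:
    # A "night" spans evening to the following morning; shifting back by the
    # morning cutoff maps every fix of one night onto a single calendar date.
    return (timestamps - pd.Timedelta(hours=night_end_hour)).dt.date


def detect_kill_clusters(
    fixes: pd.DataFrame,
    radius_m: float = 200.0,
    min_night_fixes: int = 2,
    night_start_hour: int = 18,
    night_end_hour: int = 8,
) -> pd.DataFrame:
    """Detect candidate kill sites as single-linkage clusters of night fixes.

    Night fixes (between ``night_start_hour`` and ``night_end_hour`` local
    time) within ``radius_m`` of each other are chained into clusters per
    animal.  Clusters with fewer than ``min_night_fixes`` member fixes are
    discarded.  ``handling_nights`` is the number of distinct nights with at
    least one member fix; the site is the centroid of member fixes.
    """
    out_cols = ["lynx_id", "x_m", "y_m", "n_fixes", "handling_nights",
                "first_night", "last_night"]
    if len(fixes) == 0:
        return pd.DataFrame(columns=out_cols)

    ts = pd.to_datetime(fixes["timestamp"])
    hours = ts.dt.hour
    night = (hours >= night_start_hour) | (hours < night_end_hour)
    nf = fixes.loc[night.values].copy()
    nf["_night"] = _night_key(pd.to_datetime(nf["timestamp"]), night_end_hour)

    sites = []
    for lynx_id, grp in nf.groupby("lynx_id", sort=True):
        xy = grp[["x_m", "y_m"]].to_numpy(float)
        n = len(xy)
        pairs = cKDTree(xy).query_pairs(radius_m, output_type="ndarray")
        if len(pairs):
            adj = coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
            )
        else:
            adj = coo_matrix((n, n))
        _, labels = connected_components(adj, directed=False)
        for lab in np.unique(labels):
            member = grp.iloc[np.flatnonzero(labels == lab)]
            if len(member) < min_night_fixes:
                continue
            nights = member["_night"]
            sites.append({
                "lynx_id": lynx_id,
                "x_m": member["x_m"].mean(),
                "y_m": member["y_m"].mean(),
                "n_fixes": len(member),
                "handling_nights": nights.nunique(),
                "first_night": nights.min(),
                "last_night": nights.max(),
            })
    return pd.DataFrame(sites, columns=out_cols)


def filter_analysis_kills(kills: pd.DataFrame) -> pd.DataFrame:
    """Drop records with excluded statuses (juveniles, subadult males, one-kitten
    family groups) and prey species outside {roe, red}."""
    keep = kills["status"].isin(ANALYSIS_STATUSES)
    keep &= kills["species"].isin(CENSOR_THRESHOLDS)
    return kills.loc[keep].copy()


def build_intervals(
    kills: pd.DataFrame,
    gaps: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build prey intervals from a chronological kill table (virtual kills included).

    Each consecutive pair of kills of one lynx yields an interval attributed
    to the earlier (focal) kill: handling is the nights between its
    ``kill_date`` and ``left_date``, searching runs from ``left_date`` to the
    next kill.  A virtual kill resets the searching clock like a found kill;
    intervals with a virtual endpoint carry ``involves_virtual=True``.
    Intervals overlapping a collar gap (rows of ``gaps`` with ``lynx_id``,
    ``gap_start``, ``gap_end``) are dropped.

    Raises ``ValueError`` on ``left_date < kill_date`` or on a kill table that
    is not chronologically consistent within an animal.
    """
    kills = kills.copy()
    kills["kill_date"] = pd.to_datetime(kills["kill_date"])
    kills["left_date"] = pd.to_datetime(kills["left_date"])
    if (kills["left_date"] < kills["kill_date"]).any():
        raise ValueError("left_date precedes kill_date in at least one record")

    day = pd.Timedelta(days=1)
    rows = []
    for lynx_id, grp in kills.groupby("lynx_id", sort=True):
        grp = grp.sort_values("kill_date", kind="stable")
        if (grp["left_date"].to_numpy()[:-1]
                > grp["kill_date"].to_numpy()[1:]).any():
            raise ValueError(
                f"lynx {lynx_id}: a prey was left after the next kill was made"
            )
        for cur, nxt in zip(grp.iloc[:-1].itertuples(), grp.iloc[1:].itertuples()):
            handling = (cur.left_date - cur.kill_date) / day
            searching = (nxt.kill_date - cur.left_date) / day
            if gaps is not None:
                g = gaps[gaps["lynx_id"] == lynx_id]
                overlap = (
                    (pd.to_datetime(g["gap_start"]) < nxt.kill_date)
                    & (pd.to_datetime(g["gap_end"]) > cur.kill_date)
                )
                if overlap.any():
                    continue
            rows.append({
                "lynx_id": lynx_id,
                "status": cur.status,
                "species": cur.species,
                "season": assign_season(cur.kill_date),
                "handling_time": handling,
                "searching_time": searching,
                "prey_time": handling + searching,
                "event": True,
                "involves_virtual": bool(not cur.found or not nxt.found),
            })
    return pd.DataFrame(rows, columns=[
        "lynx_id", "status", "species", "season", "handling_time",
        "searching_time", "prey_time", "event", "involves_virtual",
    ])


def censor_intervals(
    intervals: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Apply right-censoring: ``event=False`` iff prey time is strictly longer
    than the species threshold (9 d roe, 12 d red).  Durations are kept."""
    thresholds = CENSOR_THRESHOLDS if thresholds is None else thresholds
    unknown = set(intervals["species"]) - set(thresholds)
    if unknown:
        raise ValueError(f"no censoring threshold for species {sorted(unknown)}")
    out = intervals.copy()
    thr = out["species"].map(thresholds)
    out["event"] = ~(out["prey_time"] > thr)
    return out


@dataclass
class SeriesSummary:
    """Counts and percentage shares of prey species in a kill series."""

    total: int
    by_species: pd.DataFrame           # species, count, share_pct (overall)
    by_status: pd.DataFrame            # status, species, count, share_pct
    by_status_season: pd.DataFrame     # status, season, species, count

    def share(self, species: str, status: str | None = None) -> float:
        """Percentage share of ``species``, overall or within one status."""
        if status is None:
            tab, mask = self.by_species, self.by_species["species"] == species
        else:
            tab = self.by_status
            mask = (tab["species"] == species) & (tab["status"] == status)
        sel = tab.loc[mask, "share_pct"]
        if sel.empty:
            raise KeyError(f"no share for species={species!r} status={status!r}")
        return float(sel.iloc[0])


def summarize_series(kills: pd.DataFrame) -> SeriesSummary:
    """Summarize found kills: species counts and shares, overall and by
    status × season.  Virtual kills (``found == 0``) are excluded."""
    if "found" in kills.columns:
        kills = kills[kills["found"].astype(bool)]
    total = len(kills)

    def _shares(counts: pd.Series) -> pd.DataFrame:
        df = counts.rename("count").reset_index()
        denom = df["count"].sum()
        df["share_pct"] = 100.0 * df["count"] / denom if denom else np.nan
        return df

    by_species = _shares(kills.groupby("species").size())

    parts = []
    for status, grp in kills.groupby("status"):
        part = _shares(grp.groupby("species").size())
        part.insert(0, "status", status)
        parts.append(part)
    by_status = (pd.concat(parts, ignore_index=True) if parts
                 else pd.DataFrame(columns=["status", "species", "count",
                                            "share_pct"]))

    if total:
        kills = kills.copy()
        kills["season"] = kills["kill_date"].map(assign_season)
        by_ss = (kills.groupby(["status", "season", "species"]).size()
                 .rename("count").reset_index())
    else:
        by_ss = pd.DataFrame(columns=["status", "season", "species", "count"])

    return SeriesSummary(total=total, by_species=by_species,
                         by_status=by_status, by_status_season=by_ss)
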