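"""Percentile minimum convex polygon (MCP) home ranges.

The 95% MCP discards the 5% of fixes farthest from the arithmetic centroid
of all fixes (computed once; ties broken by input order), then takes the
convex hull of the remainder.  Areas are reported in km².  The study area
of a multi-animal project is the union of the individual MCPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import unary_union
from sklearn.base import BaseEstimator


@dataclass
class HomeRange:
    """A fitted percentile MCP for one animal."""

    lynx_id: str
    level: float
    n_fixes: int               # retained fixes
    hull: Polygon
    area_km2: float

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.hull.exterior.coords)


class MinimumConvexPolygon(BaseEstimator):
    """Scikit-learn style percentile MCP estimator.

    Parameters
    ----------
    level : float
        Fraction of fixes retained (default 0.95).  ``ceil((1 - level) * n)``
        fixes farthest from the centroid are removed.

    Attributes (after ``fit``)
    --------------------------
    hull_ : shapely.Polygon
    area_km2_ : float
    retained_ : ndarray of bool — which input fixes were kept
    """

    def __init__(self, level: float = 0.95):
        self.level = level

    def fit(self, X, y=None):
        xy = np.asarray(X, float)
        if not 0.0 < self.level <= 1.0:
            raise ValueError("level must be in (0, 1]")
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("fixes must be an (n, 2) array of meters")
        n = len(xy)
        n_remove = int(np.ceil((1.0 - self.level) * n))
        centroid = xy.mean(axis=0)
        dist = np.hypot(*(xy - centroid).T)
        # stable sort keeps input order among ties
        order = np.argsort(dist, kind="stable")
        keep_idx = order[: n - n_remove]
        retained = np.zeros(n, bool)
        retained[keep_idx] = True
        if retained.sum() < 3:
            raise ValueError("fewer than 3 fixes retained")
        hull = MultiPoint(xy[retained]).convex_hull
        if hull.geom_type != "Polygon" or hull.area <= 0:
            raise ValueError("retained fixes are collinear or degenerate")
        self.retained_ = retained
        self.hull_ = hull
        self.area_km2_ = hull.area / 1e6
        return self


def mcp(fixes, level: float = 0.95, lynx_id: str = "") -> HomeRange:
    """Percentile MCP of one animal's fixes.

    ``fixes`` may be an (n, 2) array of meters or a fixes table with
    ``x_m`` / ``y_m`` columns.
    """
    if isinstance(fixes, pd.DataFrame):
        if not lynx_id and "lynx_id" in fixes.columns:
            ids = fixes["lynx_id"].unique()
            if len(ids) == 1:
                lynx_id = str(ids[0])
        fixes = fixes[["x_m", "y_m"]].to_numpy(float)
    est = MinimumConvexPolygon(level=level).fit(fixes)
    return HomeRange(lynx_id=lynx_id, level=level,
                     n_fixes=int(est.retained_.sum()),
                     hull=est.hull_, area_km2=est.area_km2_)


def mcp_table(fixes: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Per-animal MCP summary (lynx_id, level, n_fixes, area_km2)."""
    rows = []
    for lynx_id, grp in fixes.groupby("lynx_id", sort=True):
        hr = mcp(grp, level=level, lynx_id=str(lynx_id))
        rows.append({"lynx_id": hr.lynx_id, "level": hr.level,
                     "n_fixes": hr.n_fixes, "area_km2": hr.area_km2})
    return pd.DataFrame(rows)


def study_area(home_ranges, grid: pd.DataFrame | None = None,
               cell_size: float = 500.0):
    """Union of home-range hulls; optionally per-zone overlap fractions.

    Returns ``(polygon, area_km2)`` or, when a quadrant ``grid`` with an
    ``in_np`` flag is given, ``(polygon, area_km2, fractions)`` where
    ``fractions`` maps zone name to the fraction of the union's area lying
    in that zone's cells.
    """
    hulls = [hr.hull if isinstance(hr, HomeRange) else hr
             for hr in home_ranges]
    if not hulls:
        raise ValueError("need at least one home range")
    union = unary_union(hulls)
    area_km2 = union.area / 1e6
    if grid is None:
        return union, area_km2

    fractions = {}
    for zone, flag in (("inside_np", 1), ("outside_np", 0)):
        cells = grid[grid["in_np"] == flag]
        boxes = [box(cx - cell_size / 2, cy - cell_size / 2,
                     cx + cell_size / 2, cy + cell_size / 2)
                 for cx, cy in zip(cells["cx_m"], cells["cy_m"])]
        zone_poly = unary_union(boxes) if boxes else Polygon()
        inter = union.intersection(zone_poly).area
        fractions[zone] = inter / union.area if union.area else 0.0
    return union, area_km2, fractions


def hulls_geojson(home_ranges) -> dict:
    """GeoJSON FeatureCollection of hull polygons (planar meters)."""
    features = []
    for hr in home_ranges:
        features.append({
            "type": "Feature",
            "properties": {"lynx_id": hr.lynx_id, "level": hr.level,
                           "n_fixes": hr.n_fixes, "area_km2": hr.area_km2},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(c) for c in hr.hull.exterior.coords]],
            },
        })
    return {"type": "FeatureCollection", "features": features}
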