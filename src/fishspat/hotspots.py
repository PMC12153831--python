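"""Getis-Ord Gi* hot/coldspot analysis of gridded CPUE.

For unit i with weights w_ij that include the focal unit (w_ii = 1), with
x̄ and S the mean and population standard deviation over all n units and
W_i = Σ_j w_ij:

    Gi* z_i = (Σ_j w_ij x_j - x̄ W_i)
              / ( S * sqrt[ (n Σ_j w_ij² - W_i²) / (n - 1) ] )

The z-score is mapped onto confidence tiers at the conventional cutpoints
±1.65 (90%), ±1.96 (95%) and ±2.58 (99%): values above classify hotspots
(clusters of high CPUE), below the negatives coldspots, and anything inside
(-1.65, 1.65) is consistent with a random arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gridding import CpueGrid, cell_area_km2
from .weights import SpatialWeights

#: tier labels from strongly cold to strongly hot
TIER_ORDER = (
    "coldspot-99", "coldspot-95", "coldspot-90",
    "random",
    "hotspot-90", "hotspot-95", "hotspot-99",
)

_CUTS = (-2.58, -1.96, -1.65, 1.65, 1.96, 2.58)


def classify_z(z) -> np.ndarray:
    """Map Gi* z-scores to confidence-tier labels (pure function of z)."""
    z = np.asarray(z, dtype=float)
    idx = np.digitize(z, _CUTS, right=True)
    labels = np.array(TIER_ORDER, dtype=object)[idx]
    labels[~np.isfinite(z)] = "unscored"
    return labels


@dataclass
class GiStarField:
    """Per-unit Gi* z-scores and tiers for one period.

    ``table`` columns: the unit descriptors passed in (grid cells carry
    i, j, lon_c, lat_c), value, z, tier. Units flagged ``unscored`` had no
    neighbors under the chosen weights.
    """

    table: pd.DataFrame
    period: str | None = None
    meta: dict = field(default_factory=dict)

    def tier_counts(self) -> pd.Series:
        scored = self.table[self.table["tier"] != "unscored"]
        return scored["tier"].value_counts().reindex(TIER_ORDER, fill_value=0)


def gi_star_scores(values, weights: SpatialWeights) -> np.ndarray:
    """Gi* z-score per unit; NaN for units with an all-zero weight row."""
    x = np.asarray(values, dtype=float)
    if x.size != weights.n:
        raise ValueError("values length does not match weights")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 units")
    if not weights.self_included:
        weights = weights.with_self()
    xbar = x.mean()
    s = x.std()  # population sd, ddof=0
    if s == 0:
        raise ValueError("values are constant; Gi* is undefined (S = 0)")
    w = weights.matrix
    wx = np.asarray(w @ x).ravel()
    wi = np.asarray(w.sum(axis=1)).ravel()
    wi2 = np.asarray(w.multiply(w).sum(axis=1)).ravel()
    var = (n * wi2 - wi**2) / (n - 1)
    z = np.full(n, np.nan)
    ok = (wi > 0) & (var > 0)
    z[ok] = (wx[ok] - xbar * wi[ok]) / (s * np.sqrt(var[ok]))
    return z


def gi_star(
    grid: CpueGrid,
    weights: SpatialWeights,
    value_column: str = "cpue",
    period: str | None = None,
) -> GiStarField:
    """Score a CPUE grid's cells and classify them into tiers."""
    values = grid.values(value_column)
    z = gi_star_scores(values, weights)
    table = grid.cells[["i", "j", "lon_c", "lat_c"]].copy()
    table["value"] = values
    table["z"] = z
    table["tier"] = classify_z(z)
    return GiStarField(
        table=table,
        period=period if period is not None else grid.period,
        meta={"value_column": value_column, **weights.meta},
    )


def classify_tiers(field: GiStarField, cell_area: np.ndarray | None = None) -> pd.DataFrame:
    """Tier summary: counts and area fractions per tier.

    ``cell_area`` (same length as the table) defaults to 1 per cell, so the
    fraction is then a cell-count fraction.
    """
    scored = field.table["tier"] != "unscored"
    if cell_area is None:
        area = np.ones(len(field.table))
    else:
        area = np.asarray(cell_area, dtype=float)
    total = float(area[scored].sum())
    rows = []
    for tier in TIER_ORDER:
        sel = scored & (field.table["tier"] == tier).to_numpy()
        rows.append(
            {
                "tier": tier,
                "count": int(sel.sum()),
                "area": float(area[sel].sum()),
                "area_fraction": float(area[sel].sum()) / total if total else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "period", field.period)
    return out


def hotspot_centroid(field: GiStarField, min_tier: str = "hotspot-90") -> tuple:
    """Unweighted centroid (lon, lat) of cells at or above a hotspot tier."""
    order = {t: k for k, t in enumerate(TIER_ORDER)}
    lvl = order[min_tier]
    sel = field.table["tier"].map(lambda t: order.get(t, -1) >= lvl)
    if not sel.any():
        return (np.nan, np.nan)
    sub = field.table[sel]
    return (float(sub["lon_c"].mean()), float(sub["lat_c"].mean()))


def gi_star_geojson(field: GiStarField, cell_size: float) -> dict:
    """Closed cell polygons with z and tier properties, for mapping."""
    feats = []
    for row in field.table.itertuples(index=False):
        w, s = row.i * cell_size, row.j * cell_size
        e, n = w + cell_size, s + cell_size
        ring = [[w, s], [e, s], [e, n], [w, n], [w, s]]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "period": field.period,
                    "z": None if not np.isfinite(row.z) else float(row.z),
                    "tier": row.tier,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def gi_star_summary(fields: list, grids: dict | None = None) -> pd.DataFrame:
    """Stack tier summaries over periods, with spherical cell areas if
    matching grids are supplied."""
    frames = []
    for f in fields:
        area = None
        if grids is not None and f.period in grids:
            area = cell_area_km2(grids[f.period])
        frames.append(classify_tiers(f, cell_area=area))
    return pd.concat(frames, ignore_index=True)
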