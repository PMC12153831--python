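"""Yield-weighted gravity centers and standard deviational ellipses.

The center of gravity of a period's fishing activity is the yield-weighted
mean position

    X_w = Σ C_i X_i / Σ C_i,   Y_w = Σ C_i Y_i / Σ C_i

with X longitude, Y latitude and C_i the catch of haul i. The weighted
standard deviational ellipse (SDE) summarizes the dispersion of the same
point pattern: its azimuth θ (degrees clockwise from north, in [0, 180))
solves

    tan θ = [ (A - B) + sqrt( (A - B)^2 + 4 C^2 ) ] / (2 C)

where A = Σ w x̃², B = Σ w ỹ², C = Σ w x̃ỹ over deviations (x̃, ỹ) from the
weighted center, and the 1-SD axes are the weighted standard deviations of
the coordinates rotated into the ellipse frame. The positive root puts θ on
the axis of maximum dispersion (the major axis); oblateness is the
major/minor axis ratio. All computations are in lon/lat degrees on a plane:
over a study area ~10° wide this matches how the field's GIS tools report
SDE axes (in degrees), and keeps ground truth and output in the same units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: relative axis-ratio margin under which an ellipse is flagged isotropic
ISOTROPY_EPS = 1e-9


@dataclass
class GravityCenter:
    x: float  # lon °E
    y: float  # lat °N
    total_weight: float
    period: str | None = None


@dataclass
class SdeParams:
    """Weighted 1-SD standard deviational ellipse for one period."""

    center_x: float
    center_y: float
    azimuth_deg: float  # clockwise from north, [0, 180)
    sigma_major: float  # degrees
    sigma_minor: float  # degrees
    period: str | None = None
    isotropic: bool = False
    degenerate: bool = False  # collinear input: sigma_minor == 0

    @property
    def oblateness(self) -> float:
        """Major/minor axis ratio; NaN when the minor axis is zero."""
        if self.sigma_minor == 0:
            return float("nan")
        return self.sigma_major / self.sigma_minor

    @property
    def area(self) -> float:
        """Ellipse area in square degrees, π σ_major σ_minor."""
        return math.pi * self.sigma_major * self.sigma_minor


def center_of_gravity(lons, lats, weights=None, period=None) -> GravityCenter:
    """Weighted mean position. Weights must be nonnegative with positive sum."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size == 0:
        raise ValueError("need at least one point")
    w = np.ones_like(lons) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    tot = float(w.sum())
    if tot <= 0:
        raise ValueError("total weight must be positive")
    return GravityCenter(
        x=float((w * lons).sum() / tot),
        y=float((w * lats).sum() / tot),
        total_weight=tot,
        period=period,
    )


def standard_deviational_ellipse(lons, lats, weights=None, period=None) -> SdeParams:
    """Weighted 1-SD ellipse of a point pattern (see module docstring).

    Collinear points give sigma_minor = 0 and are flagged ``degenerate``;
    an axis ratio within ``ISOTROPY_EPS`` of 1 is flagged ``isotropic`` and
    reports azimuth 0 (the orientation is then meaningless).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 3:
        raise ValueError("need at least 3 points for an ellipse")
    w = np.ones_like(lons) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    tot = float(w.sum())
    if tot <= 0:
        raise ValueError("total weight must be positive")

    cog = center_of_gravity(lons, lats, w, period=period)
    xt = lons - cog.x
    yt = lats - cog.y
    a = float((w * xt * xt).sum())
    b = float((w * yt * yt).sum())
    c = float((w * xt * yt).sum())

    if c == 0.0:
        theta = 0.0 if b >= a else 0.5 * math.pi
    else:
        root = math.sqrt((a - b) ** 2 + 4.0 * c * c)
        theta = math.atan(((a - b) + root) / (2.0 * c))
    # deviations rotated into the ellipse frame; axis 1 at azimuth theta
    s1 = math.sqrt(float((w * (xt * math.sin(theta) + yt * math.cos(theta)) ** 2).sum()) / tot)
    s2 = math.sqrt(float((w * (xt * math.cos(theta) - yt * math.sin(theta)) ** 2).sum()) / tot)
    if s1 >= s2:
        major, minor, az = s1, s2, theta
    else:  # the other root carries the larger dispersion
        major, minor, az = s2, s1, theta + 0.5 * math.pi
    az_deg = math.degrees(az) % 180.0

    if major > 0 and minor / major < 1e-12:  # numerically collinear input
        minor = 0.0
    degenerate = minor == 0.0
    isotropic = (not degenerate) and (major / minor - 1.0) < ISOTROPY_EPS
    if isotropic:
        az_deg = 0.0
    return SdeParams(
        center_x=cog.x,
        center_y=cog.y,
        azimuth_deg=az_deg,
        sigma_major=major,
        sigma_minor=minor,
        period=period,
        isotropic=isotropic,
        degenerate=degenerate,
    )


def _period_groups(hauls: pd.DataFrame, grouping: str):
    if grouping == "year":
        for y, g in hauls.groupby("year", sort=True):
            yield str(y), g
    elif grouping in ("year-month", "year_month"):
        for (y, m), g in hauls.groupby(["year", "month"], sort=True):
            yield f"{y}-{m:02d}", g
    else:
        raise ValueError(f"unknown grouping {grouping!r}")


def cog_trajectory(
    hauls: pd.DataFrame, grouping: str = "year", weight_column: str = "catch_t"
) -> pd.DataFrame:
    """Chronological yield-weighted centers with step vectors.

    Columns: period, xw, yw, total_weight, dlon, dlat, bearing_deg (step from
    the previous period, degrees clockwise from north; NaN on the first row).
    """
    rows = []
    for label, g in _period_groups(hauls, grouping):
        c = center_of_gravity(
            g["lon"].to_numpy(), g["lat"].to_numpy(),
            g[weight_column].to_numpy(), period=label,
        )
        rows.append({"period": label, "xw": c.x, "yw": c.y, "total_weight": c.total_weight})
    out = pd.DataFrame(rows)
    out["dlon"] = out["xw"].diff()
    out["dlat"] = out["yw"].diff()
    out["bearing_deg"] = (np.degrees(np.arctan2(out["dlon"], out["dlat"]))) % 360.0
    out.loc[out["dlon"].isna(), "bearing_deg"] = np.nan
    return out


def sde_series(
    hauls: pd.DataFrame, grouping: str = "year", weight_column: str = "catch_t"
) -> pd.DataFrame:
    """One weighted SDE per period, in the shape of the field's SDE tables.

    Columns: period, xw, yw, rotation_deg, major, minor, oblateness,
    area_deg2, isotropic, degenerate.
    """
    rows = []
    for label, g in _period_groups(hauls, grouping):
        p = standard_deviational_ellipse(
            g["lon"].to_numpy(), g["lat"].to_numpy(),
            g[weight_column].to_numpy(), period=label,
        )
        rows.append(
            {
                "period": label,
                "xw": p.center_x,
                "yw": p.center_y,
                "rotation_deg": p.azimuth_deg,
                "major": p.sigma_major,
                "minor": p.sigma_minor,
                "oblateness": p.oblateness,
                "area_deg2": p.area,
                "isotropic": p.isotropic,
                "degenerate": p.degenerate,
            }
        )
    return pd.DataFrame(rows)


def ellipse_polygon(params: SdeParams, n_segments: int = 64) -> list:
    """Closed lon/lat ring approximating the 1-SD ellipse (for GeoJSON)."""
    t = np.linspace(0.0, 2.0 * np.pi, n_segments + 1)
    az = math.radians(params.azimuth_deg)
    u = params.sigma_major * np.cos(t)  # along major axis
    v = params.sigma_minor * np.sin(t)
    lon = params.center_x + u * math.sin(az) + v * math.cos(az)
    lat = params.center_y + u * math.cos(az) - v * math.sin(az)
    ring = np.column_stack([lon, lat])
    ring[-1] = ring[0]
    return ring.tolist()


def sde_geojson(series: pd.DataFrame, n_segments: int = 64) -> dict:
    """FeatureCollection of per-period SDE polygons plus COG points."""
    feats = []
    for row in series.itertuples(index=False):
        p = SdeParams(
            center_x=row.xw, center_y=row.yw, azimuth_deg=row.rotation_deg,
            sigma_major=row.major, sigma_minor=row.minor, period=row.period,
        )
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ellipse_polygon(p, n_segments)]},
                "properties": {
                    "period": row.period,
                    "rotation_deg": row.rotation_deg,
                    "major": row.major,
                    "minor": row.minor,
                    "oblateness": None if not np.isfinite(row.oblateness) else row.oblateness,
                },
            }
        )
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row.xw, row.yw]},
                "properties": {"period": row.period, "kind": "center_of_gravity"},
            }
        )
    return {"type": "FeatureCollection", "features": feats}
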