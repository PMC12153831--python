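"""Haul-log I/O and aggregation into unit fishing areas (CPUE grids).

A haul record is one fishing-net deployment: date, position, catch (tons),
effort (number of nets). Hauls are aggregated onto a regular lon/lat grid
(default 0.1 degree, the unit fishing area) and each occupied cell gets

    CPUE = C / E

with C the summed catch and E the summed effort of the hauls in the cell —
a ratio of sums, not a mean of per-haul ratios. Cells without hauls are
absent from the grid rather than zero-filled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical haul CSV schema
HAUL_COLUMNS = ["year", "month", "day", "lon", "lat", "catch_t", "effort_nets"]


class SchemaError(ValueError):
    """A haul or grid table is missing required columns or has bad rows."""


@dataclass
class CpueGrid:
    """Occupied cells of a regular lon/lat grid with aggregated CPUE.

    Cells are anchored at integer multiples of ``cell_size`` from (0°E, 0°N)
    so that grids from different runs align. Indexing is half-open: a point
    with lon equal to a cell's west edge belongs to that cell; a point on
    the east edge belongs to the next cell (same for latitude).

    ``cells`` columns: i, j (integer cell indices), lon_c, lat_c (centroid),
    catch_t (C), effort_nets (E), cpue (C/E).
    """

    cell_size: float
    cells: pd.DataFrame
    period: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def total_catch(self) -> float:
        return float(self.cells["catch_t"].sum())

    @property
    def total_effort(self) -> float:
        return float(self.cells["effort_nets"].sum())

    def values(self, column: str = "cpue") -> np.ndarray:
        return self.cells[column].to_numpy(dtype=float)


def cell_index(coord, cell_size: float) -> np.ndarray:
    """Half-open cell index: floor(coord / cell_size), west/south inclusive.

    Computed on a coordinate rescaled by the cell size with rounding to
    12 decimals first, so that positions that are exact multiples of the
    cell size (cell corners) land on the intended integer.
    """
    scaled = np.round(np.asarray(coord, dtype=float) / cell_size, 12)
    return np.floor(scaled).astype(int)


def grid_hauls(
    hauls: pd.DataFrame, cell_size: float = 0.1, period: str | None = None
) -> CpueGrid | dict:
    """Aggregate hauls into a CPUE grid.

    Parameters
    ----------
    hauls
        Table with at least lon, lat, catch_t, effort_nets (year, month
        needed when ``period`` is set).
    cell_size
        Grid resolution in degrees, > 0.
    period
        ``None`` pools all hauls into one grid; ``"year"`` or
        ``"year-month"`` returns a dict keyed by period label.

    Raises
    ------
    SchemaError
        If any haul has effort <= 0 (the offending row indices are named).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    needed = {"lon", "lat", "catch_t", "effort_nets"}
    missing = needed - set(hauls.columns)
    if missing:
        raise SchemaError(f"haul table missing columns: {sorted(missing)}")
    bad = hauls.index[hauls["effort_nets"] <= 0]
    if len(bad):
        raise SchemaError(f"effort must be >= 1; offending record index(es): {list(bad[:10])}")

    if period is not None:
        if period == "year":
            groups = hauls.groupby("year", sort=True)
            labels = [str(k) for k in groups.groups]
        elif period in ("year-month", "year_month"):
            groups = hauls.groupby(["year", "month"], sort=True)
            labels = [f"{y}-{m:02d}" for (y, m) in groups.groups]
        else:
            raise ValueError(f"unknown period grouping: {period!r}")
        out = {}
        for lab, (_, g) in zip(labels, groups):
            sub = grid_hauls(g, cell_size=cell_size, period=None)
            sub.period = lab
            out[lab] = sub
        return out

    if hauls.empty:
        cells = pd.DataFrame(
            columns=["i", "j", "lon_c", "lat_c", "catch_t", "effort_nets", "cpue"]
        )
        return CpueGrid(cell_size=cell_size, cells=cells)

    i = cell_index(hauls["lon"].to_numpy(), cell_size)
    j = cell_index(hauls["lat"].to_numpy(), cell_size)
    agg = (
        pd.DataFrame(
            {
                "i": i,
                "j": j,
                "catch_t": hauls["catch_t"].to_numpy(dtype=float),
                "effort_nets": hauls["effort_nets"].to_numpy(dtype=float),
            }
        )
        .groupby(["i", "j"], sort=True)
        .sum()
        .reset_index()
    )
    agg["lon_c"] = (agg["i"] + 0.5) * cell_size
    agg["lat_c"] = (agg["j"] + 0.5) * cell_size
    agg["cpue"] = agg["catch_t"] / agg["effort_nets"]
    cells = agg[["i", "j", "lon_c", "lat_c", "catch_t", "effort_nets", "cpue"]]
    return CpueGrid(cell_size=cell_size, cells=cells)


def read_hauls(path) -> pd.DataFrame:
    """Read a haul CSV, validating the schema and basic invariants.

    Unparseable rows and missing columns raise :class:`SchemaError` naming
    the column or the (1-based, header-inclusive) line number.
    """
    df = pd.read_csv(path)
    missing = [c for c in HAUL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"haul CSV {path} missing column(s): {missing}")
    for col in HAUL_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"haul CSV {path}: unparseable value in column {col!r}, "
                f"line {int(bad[0]) + 2}"
            )
        df[col] = coerced
    if df[HAUL_COLUMNS].isna().any().any():
        row = int(df.index[df[HAUL_COLUMNS].isna().any(axis=1)][0])
        raise SchemaError(f"haul CSV {path}: missing value at line {row + 2}")
    for col in ("year", "month", "day", "effort_nets"):
        df[col] = df[col].astype(int)
    return df[HAUL_COLUMNS]


def write_hauls(hauls: pd.DataFrame, path) -> None:
    hauls.to_csv(path, index=False, columns=HAUL_COLUMNS)


def write_grid(grid: CpueGrid, path, fmt: str = "csv") -> None:
    """Write a grid as CSV (one row per cell) or as GeoJSON cell polygons."""
    if fmt == "csv":
        grid.cells.to_csv(path, index=False)
    elif fmt == "geojson":
        with open(path, "w") as fh:
            json.dump(grid_to_geojson(grid), fh)
    else:
        raise ValueError(f"unknown grid format {fmt!r}")


def read_grid(path, cell_size: float, period: str | None = None) -> CpueGrid:
    cells = pd.read_csv(path)
    missing = {"i", "j", "lon_c", "lat_c", "catch_t", "effort_nets", "cpue"} - set(
        cells.columns
    )
    if missing:
        raise SchemaError(f"grid CSV {path} missing column(s): {sorted(missing)}")
    return CpueGrid(cell_size=cell_size, cells=cells, period=period)


def grid_to_geojson(grid: CpueGrid, extra: dict | None = None) -> dict:
    """GeoJSON FeatureCollection of closed cell polygons with cell properties."""
    cs = grid.cell_size
    features = []
    for row in grid.cells.itertuples(index=False):
        w, s = row.i * cs, row.j * cs
        e, n = w + cs, s + cs
        ring = [[w, s], [e, s], [e, n], [w, n], [w, s]]  # closed: first == last
        props = {
            "i": int(row.i),
            "j": int(row.j),
            "catch_t": float(row.catch_t),
            "effort_nets": float(row.effort_nets),
            "cpue": float(row.cpue),
        }
        if extra:
            props.update(extra)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def cell_area_km2(grid: CpueGrid) -> np.ndarray:
    """Approximate area (km^2) of each occupied cell on the sphere."""
    km_per_deg = 2 * math.pi * 6371.0 / 360.0
    lat = grid.cells["lat_c"].to_numpy(dtype=float)
    return (grid.cell_size * km_per_deg) ** 2 * np.cos(np.radians(lat))
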