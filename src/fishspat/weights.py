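"""Spatial neighbor structures for lattice and distance-band analyses.

Weights are the w_ij of global/local autocorrelation statistics: binary
contiguity on the occupied cells of a CPUE grid (rook/queen), or great-circle
distance bands between cell centroids. Moran's I uses weights with a zero
diagonal; the Getis-Ord Gi* statistic uses the same structure with the focal
unit included (``with_self``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import scipy.sparse as sp

if TYPE_CHECKING:  # pragma: no cover
    from .gridding import CpueGrid

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays; uses a spherical Earth of
    radius 6371 km.
    """
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine(lons, lats):
    """Full n x n great-circle distance matrix (km)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


@dataclass
class SpatialWeights:
    """Sparse spatial weights aligned with a sequence of analysis units.

    Parameters
    ----------
    matrix
        n x n sparse weight matrix; ``matrix[i, j]`` is w_ij.
    ids
        Unit labels aligned with matrix rows (e.g. grid cell (i, j) tuples).
    style
        ``"binary"`` (w in {0, 1}) or ``"row"`` (rows sum to 1).
    self_included
        True when the diagonal carries w_ii = 1 (Gi* convention).
    meta
        Provenance: contiguity kind or distance band.
    """

    matrix: sp.csr_matrix
    ids: list
    style: str = "binary"
    self_included: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("weight matrix must be square")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids length must match matrix dimension")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights, Σ_ij w_ij."""
        return float(self.matrix.sum())

    @property
    def s1(self) -> float:
        """Σ_ij (w_ij + w_ji)^2 / 2 — first moment term of Var(I)."""
        m = self.matrix + self.matrix.T
        return float(m.multiply(m).sum()) / 2.0

    @property
    def s2(self) -> float:
        """Σ_i (Σ_j w_ij + Σ_j w_ji)^2 — second moment term of Var(I)."""
        rows = np.asarray(self.matrix.sum(axis=1)).ravel()
        cols = np.asarray(self.matrix.sum(axis=0)).ravel()
        return float(((rows + cols) ** 2).sum())

    @property
    def n_edges(self) -> int:
        """Number of nonzero off-diagonal weight entries."""
        m = self.matrix.copy()
        m.setdiag(0)
        m.eliminate_zeros()
        return m.nnz

    def islands(self) -> np.ndarray:
        """Indices of units with no neighbors (diagonal ignored)."""
        m = self.matrix.copy()
        m.setdiag(0)
        m.eliminate_zeros()
        deg = np.asarray(m.sum(axis=1)).ravel() + np.asarray(m.sum(axis=0)).ravel()
        return np.flatnonzero(deg == 0)

    def neighbors(self, i: int) -> np.ndarray:
        """Column indices of the nonzero weights in row i."""
        row = self.matrix.getrow(i)
        return row.indices[row.data != 0]

    def with_self(self) -> "SpatialWeights":
        """Copy with w_ii = 1 on every unit (Gi* 'star' convention)."""
        m = sp.lil_matrix(self.matrix)
        m.setdiag(1.0)
        return SpatialWeights(
            sp.csr_matrix(m), list(self.ids), style=self.style,
            self_included=True, meta=dict(self.meta),
        )

    def row_standardized(self) -> "SpatialWeights":
        """Copy with each nonempty row scaled to sum to 1."""
        rows = np.asarray(self.matrix.sum(axis=1)).ravel()
        inv = np.where(rows > 0, 1.0 / np.where(rows > 0, rows, 1.0), 0.0)
        m = sp.diags(inv) @ self.matrix
        return SpatialWeights(
            sp.csr_matrix(m), list(self.ids), style="row",
            self_included=self.self_included, meta=dict(self.meta),
        )

    def subset(self, idx) -> "SpatialWeights":
        idx = np.asarray(idx)
        m = self.matrix[idx][:, idx]
        return SpatialWeights(
            sp.csr_matrix(m), [self.ids[k] for k in idx], style=self.style,
            self_included=self.self_included, meta=dict(self.meta),
        )

    def to_edgelist(self, path) -> None:
        """Write nonzero weights as plain text lines ``i<TAB>j<TAB>w``."""
        coo = sp.coo_matrix(self.matrix)
        with open(path, "w") as fh:
            fh.write("# i\tj\tw\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                if w != 0:
                    fh.write(f"{i}\t{j}\t{w:g}\n")


_ROOK = ((1, 0), (-1, 0), (0, 1), (0, -1))
_QUEEN = _ROOK + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def contiguity_weights(grid: "CpueGrid", kind: str = "queen") -> SpatialWeights:
    """Binary contiguity weights among the occupied cells of a grid.

    Rook neighbors share an edge; queen neighbors share an edge or a corner.
    Cells absent from the grid (no fishing effort) are not units and create
    no adjacency. A single-cell grid yields an isolated unit, not an error.
    """
    if grid.n == 0:
        raise ValueError("cannot build weights on an empty grid")
    offsets = {"rook": _ROOK, "queen": _QUEEN}.get(kind)
    if offsets is None:
        raise ValueError(f"unknown contiguity kind: {kind!r}")
    ij = list(zip(grid.cells["i"].to_numpy(), grid.cells["j"].to_numpy()))
    index = {c: k for k, c in enumerate(ij)}
    rows, cols = [], []
    for k, (i, j) in enumerate(ij):
        for di, dj in offsets:
            other = index.get((i + di, j + dj))
            if other is not None:
                rows.append(k)
                cols.append(other)
    m = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(ij), len(ij))
    )
    return SpatialWeights(m, ij, meta={"kind": kind})


def distance_band_weights(
    grid: "CpueGrid" = None,
    d_lo: float = 0.0,
    d_hi: float = None,
    *,
    lons=None,
    lats=None,
    ids=None,
    dist_matrix=None,
) -> SpatialWeights:
    """Binary weights: w_ij = 1 iff haversine(i, j) in [d_lo, d_hi) km.

    Accepts either a CpueGrid (centroids are used) or explicit coordinate
    arrays; ``dist_matrix`` may be passed to reuse a precomputed pairwise
    matrix across several bands.
    """
    if d_hi is None or d_hi <= d_lo or d_lo < 0:
        raise ValueError("need 0 <= d_lo < d_hi")
    if grid is not None:
        lons = grid.cells["lon_c"].to_numpy()
        lats = grid.cells["lat_c"].to_numpy()
        ids = list(zip(grid.cells["i"].to_numpy(), grid.cells["j"].to_numpy()))
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if ids is None:
        ids = list(range(lons.size))
    d = pairwise_haversine(lons, lats) if dist_matrix is None else dist_matrix
    mask = (d >= d_lo) & (d < d_hi)
    np.fill_diagonal(mask, False)
    m = sp.csr_matrix(mask.astype(float))
    return SpatialWeights(m, ids, meta={"band_km": (float(d_lo), float(d_hi))})
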