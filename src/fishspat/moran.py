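"""Global and incremental spatial autocorrelation (Moran's I).

The global statistic over n units with weights w_ij (w_ii = 0) and centered
values z_i = x_i - x̄ is

    I = (n / S0) * Σ_ij w_ij z_i z_j / Σ_i z_i^2,      S0 = Σ_ij w_ij.

Under the null of no spatial structure E(I) = -1/(n-1); inference is either
analytic under the randomization assumption (Cliff-Ord variance with the
sample kurtosis correction) or by random permutation of the values over the
units. Positive I indicates clustering of similar values, negative I
dispersion.

The incremental sweep evaluates I over cumulative distance bands [0, d) for
an increasing series of d (km) and reports the z-score profile; the first
significant peak of z sets the natural analysis scale for local statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weights import SpatialWeights, distance_band_weights, pairwise_haversine


@dataclass
class MoranResult:
    """Global Moran's I with analytic and (optionally) permutation inference."""

    I: float
    E_I: float
    var_I: float
    z: float
    p_analytic: float  # two-sided normal tail
    n: int
    s0: float
    p_perm: float | None = None
    n_perm: int = 0
    seed: int | None = None
    n_islands: int = 0


def _prepare(values, weights: SpatialWeights):
    """Drop units without neighbors; return centered values and the matrix."""
    x = np.asarray(values, dtype=float)
    if x.size != weights.n:
        raise ValueError("values length does not match weights")
    islands = weights.islands()
    if islands.size:
        keep = np.setdiff1d(np.arange(weights.n), islands)
        x = x[keep]
        weights = weights.subset(keep)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 connected units")
    z = x - x.mean()
    if np.allclose(z, 0):
        raise ValueError("values are constant; Moran's I is undefined")
    w = weights.matrix.copy()
    w.setdiag(0)
    w.eliminate_zeros()
    if w.nnz == 0:
        raise ValueError("weights have no edges")
    return z, w, n, islands.size


def _moran_stat(z, w, n, s0):
    return (n / s0) * float(z @ (w @ z)) / float(z @ z)


def moran_randomization_variance(values, weights: SpatialWeights) -> float:
    """Var(I) under the randomization (permutation) assumption.

    Uses the closed form with the weight moments S0, S1, S2 and the sample
    kurtosis b2 = n Σz^4 / (Σz^2)^2.
    """
    z, w, n, _ = _prepare(values, weights)
    s0 = float(w.sum())
    m = w + w.T
    s1 = float(m.multiply(m).sum()) / 2.0
    rows = np.asarray(w.sum(axis=1)).ravel()
    cols = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((rows + cols) ** 2).sum())
    b2 = n * float((z**4).sum()) / float((z**2).sum()) ** 2
    e_i = -1.0 / (n - 1)
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
        (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    return num / den - e_i * e_i


def moran_global(values, weights: SpatialWeights) -> MoranResult:
    """Global Moran's I with analytic (randomization) inference."""
    z, w, n, n_isl = _prepare(values, weights)
    s0 = float(w.sum())
    i_obs = _moran_stat(z, w, n, s0)
    e_i = -1.0 / (n - 1)
    var_i = moran_randomization_variance(values, weights)
    zscore = (i_obs - e_i) / np.sqrt(var_i)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(
        I=i_obs, E_I=e_i, var_I=var_i, z=zscore, p_analytic=p,
        n=n, s0=s0, n_islands=n_isl,
    )


def moran_permutation_test(
    values, weights: SpatialWeights, n_perm: int = 999, seed: int | None = None
) -> MoranResult:
    """Permutation test for Moran's I.

    Values are randomly reassigned to units ``n_perm`` times; the two-sided
    p-value uses the add-one estimator

        p = (1 + #{ |I* - E(I)| >= |I - E(I)| }) / (n_perm + 1),

    which can never be zero (minimum 1/(n_perm+1); with the 99,999 draws
    conventional for this analysis, 1e-5).
    """
    import warnings

    if n_perm < 99:
        warnings.warn("n_perm < 99 gives unstable permutation p-values", stacklevel=2)
    res = moran_global(values, weights)
    z, w, n, _ = _prepare(values, weights)
    s0 = res.s0
    denom = float(z @ z)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, int(4e6 // max(n, 1))))
    done = 0
    thresh = abs(res.I - res.E_I)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        zm = rng.permuted(np.broadcast_to(z, (b, n)).copy(), axis=1).T  # n x b
        i_star = (n / s0) * np.einsum("ib,ib->b", zm, w @ zm) / denom
        count += int((np.abs(i_star - res.E_I) >= thresh - 1e-14).sum())
        done += b
    res.p_perm = (1.0 + count) / (n_perm + 1.0)
    res.n_perm = n_perm
    res.seed = seed
    return res


@dataclass
class IncrementalProfile:
    """Moran z-score profile over increasing distance thresholds.

    ``bands`` columns: distance_km, n_pairs, I, z, p (one-sided, clustering),
    ok (False where the band has no pairs and carries no statistic).
    """

    bands: pd.DataFrame
    mode: str = "cumulative"

    @property
    def first_peak(self) -> float | None:
        return select_first_peak(self)


def incremental_moran(
    values,
    grid=None,
    distances=None,
    *,
    lons=None,
    lats=None,
    mode: str = "cumulative",
) -> IncrementalProfile:
    """Moran's I and z over a series of increasing distance thresholds (km).

    ``cumulative`` mode uses bands [0, d) (the convention of distance-range
    tools); ``annular`` uses [d_prev, d). Bands with no pairs are flagged and
    carry no statistic. Inference is analytic; the z profile is meant for
    peak-finding, not for per-band hypothesis tests.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size < 3:
        raise ValueError("need at least 3 distances")
    if not np.all(np.diff(distances) > 0):
        raise ValueError("distances must be strictly increasing")
    if grid is not None:
        lons = grid.cells["lon_c"].to_numpy()
        lats = grid.cells["lat_c"].to_numpy()
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    dmat = pairwise_haversine(lons, lats)

    rows = []
    prev = 0.0
    for d in distances:
        lo = prev if mode == "annular" else 0.0
        w = distance_band_weights(
            d_lo=lo, d_hi=d, lons=lons, lats=lats, dist_matrix=dmat
        )
        n_pairs = w.n_edges // 2
        if n_pairs == 0:
            rows.append((d, 0, np.nan, np.nan, np.nan, False))
        else:
            try:
                r = moran_global(values, w)
                rows.append((d, n_pairs, r.I, r.z, stats.norm.sf(r.z), True))
            except ValueError:
                rows.append((d, n_pairs, np.nan, np.nan, np.nan, False))
        if mode == "annular":
            prev = d
    bands = pd.DataFrame(
        rows, columns=["distance_km", "n_pairs", "I", "z", "p", "ok"]
    )
    if not bands["ok"].any():
        raise ValueError("all distance bands are empty")
    return IncrementalProfile(bands=bands, mode=mode)


def select_first_peak(profile, z_crit: float = 1.96) -> float | None:
    """Distance of the first significant local maximum of the z profile.

    Equal consecutive z-values form a single candidate located at the run's
    first distance; a run is a peak when every adjacent run (where one
    exists) is strictly lower. Returns None when no peak reaches ``z_crit``.
    """
    if isinstance(profile, IncrementalProfile):
        bands = profile.bands[profile.bands["ok"]]
        dist = bands["distance_km"].to_numpy(dtype=float)
        z = bands["z"].to_numpy(dtype=float)
    else:
        dist, z = (np.asarray(a, dtype=float) for a in profile)
    if z.size == 0:
        return None
    # maximal runs of equal z
    starts = [0]
    for k in range(1, z.size):
        if z[k] != z[k - 1]:
            starts.append(k)
    starts.append(z.size)
    for r in range(len(starts) - 1):
        s = starts[r]
        zl = z[starts[r - 1]] if r > 0 else None
        zr = z[starts[r + 1]] if starts[r + 1] < z.size else None
        if (zl is None or zl < z[s]) and (zr is None or zr < z[s]) and z[s] >= z_crit:
            return float(dist[s])
    return None
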