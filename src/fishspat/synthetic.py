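"""Synthetic purse-seine fishery logs with known spatial ground truth.

Emulates an eight-year logbook of per-haul records (date, position, catch in
tons, effort in net deployments) from a pelagic fishery in the Northwest
Pacific high seas (35-45°N, 145-160°E), together with smooth monthly
environmental fields (SST, Chl-a, SSS, SSH) on a 0.083° grid.

Ground truth the generator controls, and downstream stages must recover:

* haul positions form anisotropic Gaussian clusters elongated SW-NE;
* cluster centers drift northeastward across years at a configured rate and
  cycle northeast-then-southwest within each year, northeast-most in August;
* log-catch is Gaussian around a mean tied to local covariates, including a
  dome-shaped SST response that is flat on a 10-20 °C plateau and falls off
  quadratically outside it;
* effort is 1 + Poisson, so every record has at least one net.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so the same configuration is byte-identical across runs and the
environmental fields do not depend on how many hauls are drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .gridding import HAUL_COLUMNS

BBOX_DEFAULT = (145.0, 160.0, 35.0, 45.0)  # lon_min, lon_max, lat_min, lat_max


@dataclass
class EnvFieldSpec:
    """Smooth-surface recipe for one environmental covariate.

    value = mean + grad_lon * (lon - lon0) + grad_lat * (lat - lat0)
          + seasonal_amp * cos(2π (month - peak_month) / 12) + noise

    with (lon0, lat0) the domain center. The noise term has marginal sd
    ``noise_sd``; with ``noise_corr_deg`` > 0 it is smoothed to that spatial
    correlation scale (mesoscale eddies and fronts are coherent over tens of
    km, not white pixel to pixel). Units follow the covariate (°C, mg/m^3,
    psu, m).
    """

    mean: float
    grad_lon: float = 0.0
    grad_lat: float = 0.0
    seasonal_amp: float = 0.0
    peak_month: int = 8
    noise_sd: float = 0.0
    noise_corr_deg: float = 0.0  # 0 = white noise
    noise_persist: float = 0.0  # fraction of noise variance fixed within a year
    floor: float | None = None  # clip, e.g. chlorophyll >= 0


def default_env_specs() -> dict:
    """Plausible Northwest Pacific surface fields (statistical stand-ins)."""
    # noise sds represent mesoscale variability (eddies, fronts), sized so
    # no covariate is a near-deterministic function of position and season.
    # The 0.4° (~40 km) correlation scale and the within-year persistence
    # make the stand-in fields — and hence CPUE — spatially coherent patches
    # at the scale such fisheries cluster, rather than pixel noise.
    return {
        "sst": EnvFieldSpec(mean=14.0, grad_lat=-0.8, seasonal_amp=5.0,
                            peak_month=8, noise_sd=1.8, noise_corr_deg=0.4,
                            noise_persist=0.6),
        "chla": EnvFieldSpec(mean=2.0, grad_lat=0.15, seasonal_amp=1.0,
                             peak_month=4, noise_sd=0.6, noise_corr_deg=0.4,
                             noise_persist=0.6, floor=0.01),
        "sss": EnvFieldSpec(mean=34.0, grad_lat=-0.08, seasonal_amp=0.3,
                            peak_month=2, noise_sd=0.25, noise_corr_deg=0.4,
                            noise_persist=0.6),
        "ssh": EnvFieldSpec(mean=0.30, grad_lat=-0.035, seasonal_amp=0.06,
                            peak_month=9, noise_sd=0.05, noise_corr_deg=0.4,
                            noise_persist=0.6),
    }


@dataclass
class CatchModel:
    """Lognormal per-haul catch linked to local covariates.

    log(catch) = mu + year_trend * (year - first year)
               + sst_link(SST) + chla_coef * (Chla - 2) + sss_coef * (SSS - 34)
               + ssh_coef * (SSH - 0.3) + N(0, sigma)

    ``sst_link`` is dome-shaped: zero on [sst_lo, sst_hi] and
    ``-sst_decline * (distance beyond the plateau)^2`` outside, so catch is
    stable within the thermal optimum and falls off beyond it.
    """

    mu: float = 2.1  # log-tons; median haul ≈ 8 t
    sigma: float = 0.6
    year_trend: float = 0.12  # catches rise across the study years
    sst_lo: float = 10.0
    sst_hi: float = 20.0
    sst_decline: float = 0.035
    chla_coef: float = -0.25
    sss_coef: float = -0.30
    ssh_coef: float = 6.0  # SSH anomalies are the dominant aggregation driver

    def sst_link(self, sst):
        sst = np.asarray(sst, dtype=float)
        below = np.clip(self.sst_lo - sst, 0.0, None)
        above = np.clip(sst - self.sst_hi, 0.0, None)
        return -self.sst_decline * (below + above) ** 2

    def log_mean(self, year, year0, sst, chla, sss, ssh):
        return (
            self.mu
            + self.year_trend * (np.asarray(year) - year0)
            + self.sst_link(sst)
            + self.chla_coef * (np.asarray(chla) - 2.0)
            + self.sss_coef * (np.asarray(sss) - 34.0)
            + self.ssh_coef * (np.asarray(ssh) - 0.30)
        )


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic fishery.

    Defaults reproduce the conditions of the emulated fishery: 2014-2021,
    March-December seasons, ~4710 hauls per year (37,680 total), clusters
    drifting northeast by (0.356°E, 0.300°N) per year from a starting center
    of (150.0°E, 39.8°N), cluster anisotropy at azimuth 58° from north, and
    a within-year NE-SW cycle of 1.2° amplitude peaking in August.
    """

    years: tuple = tuple(range(2014, 2022))
    months_active: tuple = tuple(range(3, 13))
    n_hauls_per_year: int = 4710
    bbox: tuple = BBOX_DEFAULT
    start_center: tuple = (150.0, 39.8)  # lon, lat of first-year cluster center
    annual_drift: tuple = (2.49 / 7.0, 2.10 / 7.0)  # °/year, NE
    cluster_centers_by_year: dict | None = None  # overrides start+drift
    cluster_sd_lonlat: tuple = (1.1, 0.45)  # sd along major/minor axes, degrees
    cluster_azimuth_deg: float = 58.0  # major-axis azimuth, clockwise from north
    seasonal_amplitude: float = 1.2  # ° of NE-SW within-year cycle
    peak_month: int = 8  # NE-most month
    catch_model: CatchModel = field(default_factory=CatchModel)
    effort_lambda: float = 1.5  # effort = 1 + Poisson(lambda)
    env_resolution: float = 0.083
    env_specs: dict = field(default_factory=default_env_specs)
    seed: int = 0

    def validate(self) -> None:
        if not self.years:
            raise ValueError("years must be nonempty")
        if self.n_hauls_per_year <= 0:
            raise ValueError("n_hauls_per_year must be positive")
        if any(s < 0 for s in self.cluster_sd_lonlat):
            raise ValueError("cluster sds must be nonnegative")
        if not set(self.months_active) <= set(range(1, 13)):
            raise ValueError("months_active must be within 1..12")
        if self.env_resolution <= 0:
            raise ValueError("env_resolution must be positive")
        if self.cluster_centers_by_year is not None:
            missing = [y for y in self.years if y not in self.cluster_centers_by_year]
            if missing:
                raise ValueError(f"cluster_centers_by_year missing years {missing}")

    def centers_for_year(self, year: int) -> list:
        """Cluster centers for a year: explicit list or start + drift."""
        if self.cluster_centers_by_year is not None:
            c = self.cluster_centers_by_year[year]
            return [tuple(c)] if np.ndim(c[0]) == 0 and not isinstance(c[0], (tuple, list)) else [tuple(p) for p in c]
        k = self.years.index(year) if year in self.years else year - self.years[0]
        return [
            (
                self.start_center[0] + k * self.annual_drift[0],
                self.start_center[1] + k * self.annual_drift[1],
            )
        ]

    def seasonal_offset(self, month) -> tuple:
        """NE displacement (dlon, dlat) for a month; peaks at ``peak_month``.

        The half-sine ramp sin(π (m - p + 6) / 12) rises from the season
        start, peaks at the peak month and decays after it without going
        negative, so the season's last month still sits northeast of its
        first — the pattern of a stock that returns southwest but not all
        the way.
        """
        m = np.asarray(month, dtype=float)
        phase = np.sin(np.pi * ((m - self.peak_month + 6.0) % 12.0) / 12.0)
        az = math.radians(45.0)  # cycle runs along the NE axis
        return (
            self.seasonal_amplitude * phase * math.sin(az),
            self.seasonal_amplitude * phase * math.cos(az),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["env_specs"] = {k: asdict(v) for k, v in self.env_specs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "catch_model" in d and isinstance(d["catch_model"], dict):
            d["catch_model"] = CatchModel(**d["catch_model"])
        if "env_specs" in d:
            d["env_specs"] = {
                k: (EnvFieldSpec(**v) if isinstance(v, dict) else v)
                for k, v in d["env_specs"].items()
            }
        for key in ("years", "months_active", "bbox", "start_center",
                    "annual_drift", "cluster_sd_lonlat"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("cluster_centers_by_year") is not None:
            d["cluster_centers_by_year"] = {
                int(k): v for k, v in d["cluster_centers_by_year"].items()
            }
        return cls(**d)


class EnvField:
    """One covariate's monthly values on a regular lon/lat grid.

    Cell (iy, ix) is centered at (lat_min + (iy + 0.5) res,
    lon_min + (ix + 0.5) res). ``value_at`` does nearest-cell lookup with a
    lower-left tie rule on cell boundaries.
    """

    def __init__(self, name, bbox, resolution, months_index, data):
        self.name = name
        self.bbox = bbox
        self.resolution = float(resolution)
        #: ordered list of (year, month) keys present
        self.months_index = list(months_index)
        #: dict[(year, month)] -> 2D array (nlat, nlon)
        self.data = data
        lon_min, lon_max, lat_min, lat_max = bbox
        self.nlon = int(round((lon_max - lon_min) / self.resolution))
        self.nlat = int(round((lat_max - lat_min) / self.resolution))
        self.lon_centers = lon_min + (np.arange(self.nlon) + 0.5) * self.resolution
        self.lat_centers = lat_min + (np.arange(self.nlat) + 0.5) * self.resolution

    def _nearest_idx(self, coord, cmin, ncells):
        # continuous center index u; nearest with ties going to the
        # lower(-left) cell: ceil(u - 0.5)
        u = (np.asarray(coord, dtype=float) - cmin) / self.resolution - 0.5
        idx = np.ceil(np.round(u - 0.5, 9)).astype(int)
        return np.clip(idx, 0, ncells - 1)

    def value_at(self, year, month, lons, lats) -> np.ndarray:
        """Nearest-cell values for positions in the given year-month."""
        key = (int(year), int(month))
        if key not in self.data:
            raise KeyError(f"field {self.name!r} has no month {key}")
        lon_min, lon_max, lat_min, lat_max = self.bbox
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        if ((lons < lon_min) | (lons > lon_max) | (lats < lat_min) | (lats > lat_max)).any():
            raise ValueError(f"position outside {self.name!r} field extent")
        ix = self._nearest_idx(lons, lon_min, self.nlon)
        iy = self._nearest_idx(lats, lat_min, self.nlat)
        return self.data[key][iy, ix]

    def to_dataframe(self, year, month) -> pd.DataFrame:
        arr = self.data[(int(year), int(month))]
        iy, ix = np.indices(arr.shape)
        return pd.DataFrame(
            {
                "lon_c": self.lon_centers[ix.ravel()],
                "lat_c": self.lat_centers[iy.ravel()],
                self.name: arr.ravel(),
            }
        )


def generate_env_fields(config: SyntheticConfig) -> dict:
    """Build the four monthly covariate fields on the 0.083° grid.

    Surfaces are a linear lon/lat trend plus a seasonal sinusoid plus white
    noise — statistical stand-ins with the right scales, not ocean dynamics.
    Deterministic given the config seed, independent of haul generation.
    """
    config.validate()
    for name in ("sst", "chla", "sss", "ssh"):
        if name not in config.env_specs:
            raise ValueError(f"env_specs missing covariate {name!r}")
    ss = np.random.SeedSequence(config.seed, spawn_key=(1,))
    children = ss.spawn(len(config.env_specs))
    lon_min, lon_max, lat_min, lat_max = config.bbox
    lon0 = 0.5 * (lon_min + lon_max)
    lat0 = 0.5 * (lat_min + lat_max)
    months = [(y, m) for y in config.years for m in sorted(config.months_active)]

    fields = {}
    for child, (name, spec) in zip(children, sorted(config.env_specs.items())):
        rng = np.random.default_rng(child)
        proto = EnvField(name, config.bbox, config.env_resolution, months, {})
        lon_g, lat_g = np.meshgrid(proto.lon_centers, proto.lat_centers)
        trend = (
            spec.mean
            + spec.grad_lon * (lon_g - lon0)
            + spec.grad_lat * (lat_g - lat0)
        )
        def unit_noise():
            noise = rng.normal(0.0, 1.0, size=trend.shape)
            if spec.noise_corr_deg > 0:
                sigma_px = spec.noise_corr_deg / config.env_resolution
                noise = gaussian_filter(noise, sigma_px, mode="reflect")
                sd = noise.std()
                if sd > 0:
                    noise = noise / sd
            return noise

        data = {}
        annual_patch = None
        current_year = None
        p = min(max(spec.noise_persist, 0.0), 1.0)
        for (y, m) in months:
            seasonal = spec.seasonal_amp * math.cos(
                2.0 * math.pi * (m - spec.peak_month) / 12.0
            )
            arr = trend + seasonal
            if spec.noise_sd > 0:
                if y != current_year:
                    annual_patch = unit_noise()
                    current_year = y
                # persistent eddy/front pattern for the year plus a fresh
                # monthly component; marginal sd stays noise_sd
                noise = math.sqrt(p) * annual_patch + math.sqrt(1 - p) * unit_noise()
                arr = arr + spec.noise_sd * noise
            if spec.floor is not None:
                arr = np.maximum(arr, spec.floor)
            data[(y, m)] = arr
        proto.data = data
        fields[name] = proto
    return fields


def _sample_cluster_offsets(rng, n, sd_major, sd_minor, azimuth_deg):
    """Anisotropic Gaussian offsets (dlon, dlat) with the major axis at the
    given azimuth (degrees clockwise from north)."""
    u = rng.normal(0.0, sd_major, n)  # along major axis
    v = rng.normal(0.0, sd_minor, n)  # along minor axis
    az = math.radians(azimuth_deg)
    dlon = u * math.sin(az) + v * math.cos(az)
    dlat = u * math.cos(az) - v * math.sin(az)
    return dlon, dlat


def generate_hauls(config: SyntheticConfig, fields: dict | None = None) -> pd.DataFrame:
    """Draw the per-haul fishery log for every configured year.

    Positions are truncated to the bounding box by resampling, so cluster
    tails never leave the study area. Catch is linked to the covariate
    fields at each haul's position and month; pass ``fields`` to reuse
    already-generated surfaces (they are regenerated deterministically from
    the config seed otherwise).
    """
    config.validate()
    if fields is None:
        fields = generate_env_fields(config)

    ss = np.random.SeedSequence(config.seed, spawn_key=(2,))
    year_seeds = ss.spawn(len(config.years))
    lon_min, lon_max, lat_min, lat_max = config.bbox
    cm = config.catch_model
    year0 = config.years[0]
    months = np.array(sorted(config.months_active))

    frames = []
    for year, child in zip(config.years, year_seeds):
        rng = np.random.default_rng(child)
        n = config.n_hauls_per_year
        month = rng.choice(months, size=n)
        day = rng.integers(1, 29, size=n)
        centers = config.centers_for_year(year)
        which = rng.integers(0, len(centers), size=n)
        base = np.array([centers[k] for k in which])
        off_lon, off_lat = config.seasonal_offset(month)
        lon = np.empty(n)
        lat = np.empty(n)
        pending = np.arange(n)
        # rejection-sample offsets until every haul is inside the bbox
        for _ in range(1000):
            dlon, dlat = _sample_cluster_offsets(
                rng, pending.size, *config.cluster_sd_lonlat, config.cluster_azimuth_deg
            )
            lon[pending] = base[pending, 0] + np.asarray(off_lon)[pending] + dlon
            lat[pending] = base[pending, 1] + np.asarray(off_lat)[pending] + dlat
            inside = (
                (lon[pending] >= lon_min) & (lon[pending] <= lon_max)
                & (lat[pending] >= lat_min) & (lat[pending] <= lat_max)
            )
            pending = pending[~inside]
            if pending.size == 0:
                break
        else:  # pragma: no cover - means a center sits far outside the bbox
            raise RuntimeError("could not place hauls inside the bounding box")

        env = {
            name: np.empty(n) for name in ("sst", "chla", "sss", "ssh")
        }
        for m in months:
            sel = month == m
            if not sel.any():
                continue
            for name in env:
                env[name][sel] = fields[name].value_at(year, m, lon[sel], lat[sel])
        log_mu = cm.log_mean(year, year0, env["sst"], env["chla"], env["sss"], env["ssh"])
        catch = np.exp(log_mu + rng.normal(0.0, cm.sigma, size=n))
        effort = 1 + rng.poisson(config.effort_lambda, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "year": year,
                    "month": month,
                    "day": day,
                    "lon": lon,
                    "lat": lat,
                    "catch_t": catch,
                    "effort_nets": effort,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out[HAUL_COLUMNS]


def sample_env_at(hauls: pd.DataFrame, fields: dict) -> pd.DataFrame:
    """Attach covariate columns to records by nearest-cell lookup.

    Works for raw hauls (lon/lat) or grid-cell tables (lon_c/lat_c). Raises
    if any position falls outside a field's extent.
    """
    lon_col = "lon" if "lon" in hauls.columns else "lon_c"
    lat_col = "lat" if "lat" in hauls.columns else "lat_c"
    out = hauls.copy()
    for name in sorted(fields):
        vals = np.empty(len(out))
        for (y, m), sub in out.groupby(["year", "month"]):
            vals[out.index.get_indexer(sub.index)] = fields[name].value_at(
                y, m, sub[lon_col].to_numpy(), sub[lat_col].to_numpy()
            )
        out[name] = vals
    return out
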