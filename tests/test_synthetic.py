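"""Generator contracts: determinism, invariants, and recovery of the
configured ground truth from the generated records."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fishspat import (
    CatchModel,
    SyntheticConfig,
    generate_env_fields,
    generate_hauls,
    sample_env_at,
)
from fishspat.synthetic import EnvFieldSpec, default_env_specs


def test_same_seed_gives_identical_records(small_config, small_hauls):
    again = generate_hauls(SyntheticConfig(**{**small_config.__dict__}))
    pd.testing.assert_frame_equal(small_hauls, again)


def test_degenerate_variance_collapses_to_center():
    cfg = SyntheticConfig(
        years=(2014,), n_hauls_per_year=50, cluster_sd_lonlat=(0.0, 0.0),
        seasonal_amplitude=0.0, annual_drift=(0.0, 0.0),
        start_center=(150.0, 40.0), env_resolution=0.5, seed=1,
    )
    hauls = generate_hauls(cfg)
    assert np.allclose(hauls["lon"], 150.0)
    assert np.allclose(hauls["lat"], 40.0)


def test_basic_invariants(small_config, small_hauls):
    lon_min, lon_max, lat_min, lat_max = small_config.bbox
    assert small_hauls["lon"].between(lon_min, lon_max).all()
    assert small_hauls["lat"].between(lat_min, lat_max).all()
    assert (small_hauls["effort_nets"] >= 1).all()
    assert (small_hauls["catch_t"] >= 0).all()
    assert set(small_hauls["month"]) <= set(small_config.months_active)
    counts = small_hauls.groupby("year").size()
    assert (counts == small_config.n_hauls_per_year).all()


@pytest.mark.parametrize(
    "bad",
    [
        {"years": ()},
        {"n_hauls_per_year": 0},
        {"cluster_sd_lonlat": (-0.1, 0.2)},
        {"env_resolution": 0.0},
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        SyntheticConfig(**bad).validate()


def test_missing_cluster_center_year_rejected():
    cfg = SyntheticConfig(
        years=(2014, 2015), cluster_centers_by_year={2014: (150.0, 40.0)}
    )
    with pytest.raises(ValueError, match="2015"):
        cfg.validate()


def test_flat_noiseless_field_is_constant():
    cfg = SyntheticConfig(
        years=(2014,), env_resolution=0.5, seed=0,
        env_specs={
            **default_env_specs(),
            "sst": EnvFieldSpec(mean=15.0),
        },
    )
    f = generate_env_fields(cfg)["sst"]
    assert np.allclose(f.data[(2014, 3)], 15.0)


def test_latitudinal_gradient_recovered_by_least_squares():
    cfg = SyntheticConfig(
        years=(2014,), env_resolution=0.25, seed=0,
        env_specs={
            **default_env_specs(),
            "sst": EnvFieldSpec(mean=15.0, grad_lat=-0.8),
        },
    )
    f = generate_env_fields(cfg)["sst"]
    df = f.to_dataframe(2014, 3)
    slope = np.polyfit(df["lat_c"], df["sst"], 1)[0]
    assert slope == pytest.approx(-0.8, rel=0.01)


def test_independent_covariates_nearly_uncorrelated():
    cfg = SyntheticConfig(
        years=(2014,), env_resolution=0.083, seed=5,
        env_specs={
            "sst": EnvFieldSpec(mean=15.0, noise_sd=1.0),
            "chla": EnvFieldSpec(mean=2.0, noise_sd=0.5),
            "sss": EnvFieldSpec(mean=34.0, noise_sd=0.2),
            "ssh": EnvFieldSpec(mean=0.3, noise_sd=0.05),
        },
    )
    fields = generate_env_fields(cfg)
    a = fields["sst"].data[(2014, 3)].ravel()
    b = fields["chla"].data[(2014, 3)].ravel()
    assert a.size >= 10_000
    r = np.corrcoef(a, b)[0, 1]
    assert abs(r) < 0.05


class TestNearestCellLookup:
    def _field(self):
        cfg = SyntheticConfig(years=(2014,), env_resolution=0.5, seed=0)
        return generate_env_fields(cfg)["sst"], cfg

    def test_cell_center_hits_exactly_that_cell(self):
        f, cfg = self._field()
        lon, lat = f.lon_centers[10], f.lat_centers[4]
        assert f.value_at(2014, 3, [lon], [lat])[0] == f.data[(2014, 3)][4, 10]

    def test_boundary_tie_goes_lower_left(self):
        f, cfg = self._field()
        lon_min, _, lat_min, _ = cfg.bbox
        # boundary between cells 2 and 3 in each axis
        lon = lon_min + 3 * f.resolution
        lat = lat_min + 3 * f.resolution
        assert f.value_at(2014, 3, [lon], [lat])[0] == f.data[(2014, 3)][2, 2]

    def test_matches_brute_force_nearest_center(self):
        f, cfg = self._field()
        rng = np.random.default_rng(7)
        lon_min, lon_max, lat_min, lat_max = cfg.bbox
        lons = rng.uniform(lon_min, lon_max, 100)
        lats = rng.uniform(lat_min, lat_max, 100)
        got = f.value_at(2014, 3, lons, lats)
        arr = f.data[(2014, 3)]
        for k in range(100):
            ix = int(np.argmin(np.abs(f.lon_centers - lons[k])))
            iy = int(np.argmin(np.abs(f.lat_centers - lats[k])))
            assert got[k] == arr[iy, ix]

    def test_outside_extent_rejected(self):
        f, _ = self._field()
        with pytest.raises(ValueError, match="extent"):
            f.value_at(2014, 3, [120.0], [40.0])


def test_sample_env_matches_direct_lookup(small_hauls, small_fields):
    aug = sample_env_at(small_hauls, small_fields)
    assert {"sst", "chla", "sss", "ssh"} <= set(aug.columns)
    row = aug.iloc[17]
    direct = small_fields["sst"].value_at(
        row["year"], row["month"], [row["lon"]], [row["lat"]]
    )[0]
    assert row["sst"] == direct


def test_log_catch_normal_when_links_zeroed():
    cm = CatchModel(mu=2.0, sigma=0.5, year_trend=0.0, sst_decline=0.0,
                    chla_coef=0.0, sss_coef=0.0, ssh_coef=0.0)
    cfg = SyntheticConfig(
        years=(2014,), n_hauls_per_year=2000, catch_model=cm,
        env_resolution=0.5, seed=9,
    )
    logs = np.log(generate_hauls(cfg)["catch_t"].to_numpy())
    assert logs.mean() == pytest.approx(2.0, abs=0.05)
    assert logs.std() == pytest.approx(0.5, abs=0.05)
    assert stats.shapiro(logs[:500]).pvalue > 0.01


def test_within_year_cog_is_northeast_most_at_peak_month():
    cfg = SyntheticConfig(
        years=(2014,), n_hauls_per_year=12_000, seasonal_amplitude=3.0,
        env_resolution=0.5, seed=13,
    )
    hauls = generate_hauls(cfg)
    cog = hauls.groupby("month")[["lon", "lat"]].mean()
    # "northeast-most": maximal NE projection (lon+lat)/sqrt2
    ne = cog["lon"] + cog["lat"]
    assert int(ne.idxmax()) == cfg.peak_month


def test_annual_drift_recovered_from_yearly_cogs():
    cfg = SyntheticConfig(
        years=tuple(range(2014, 2022)), n_hauls_per_year=5000,
        annual_drift=(0.3, 0.25), env_resolution=0.5, seed=21,
    )
    hauls = generate_hauls(cfg)
    cog = hauls.groupby("year")[["lon", "lat"]].mean()
    yrs = cog.index.to_numpy(dtype=float)
    for axis, truth in (("lon", 0.3), ("lat", 0.25)):
        fit = stats.linregress(yrs, cog[axis])
        assert abs(fit.slope - truth) < 2 * fit.stderr
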