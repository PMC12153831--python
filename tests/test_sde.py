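"""Gravity centers and weighted standard deviational ellipses.

The eigen-oracle: the SDE azimuth/axes must coincide with the
eigendecomposition of the weighted coordinate covariance matrix.
"""

import math

import numpy as np
import pandas as pd
import pytest

from fishspat import (
    center_of_gravity,
    cog_trajectory,
    sde_series,
    standard_deviational_ellipse,
)
from fishspat.ellipse import ellipse_polygon


def eigen_oracle(lons, lats, weights):
    """Azimuth (° from north) and axes from the weighted covariance matrix."""
    w = np.asarray(weights, float) / np.sum(weights)
    cx = (w * lons).sum()
    cy = (w * lats).sum()
    d = np.column_stack([lons - cx, lats - cy])
    cov = (w[:, None, None] * np.einsum("ni,nj->nij", d, d)).sum(axis=0)
    ev, evec = np.linalg.eigh(cov)
    major_vec = evec[:, np.argmax(ev)]
    az = math.degrees(math.atan2(major_vec[0], major_vec[1])) % 180.0
    return az, math.sqrt(ev.max()), math.sqrt(ev.min())


class TestCenterOfGravity:
    def test_single_point(self):
        c = center_of_gravity([150.0], [40.0], [2.5])
        assert (c.x, c.y) == (150.0, 40.0)

    def test_equal_weight_midpoint(self):
        c = center_of_gravity([150.0, 152.0], [40.0, 42.0])
        assert (c.x, c.y) == (151.0, 41.0)

    def test_weighted_mean_hand_computed(self):
        # weights (1, 3) at lon 150 and 154: (150 + 3*154)/4 = 153
        c = center_of_gravity([150.0, 154.0], [40.0, 40.0], [1.0, 3.0])
        assert c.x == pytest.approx(153.0)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            center_of_gravity([150.0, 151.0], [40.0, 41.0], [0.0, 0.0])

    def test_inside_convex_hull(self):
        rng = np.random.default_rng(0)
        lons = rng.uniform(145, 160, 40)
        lats = rng.uniform(35, 45, 40)
        c = center_of_gravity(lons, lats, rng.uniform(0, 5, 40))
        assert lons.min() <= c.x <= lons.max()
        assert lats.min() <= c.y <= lats.max()


class TestSde:
    def test_matches_eigen_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            lons = rng.uniform(145, 160, n)
            lats = rng.uniform(35, 45, n)
            w = rng.uniform(0.1, 5.0, n)
            p = standard_deviational_ellipse(lons, lats, w)
            az, major, minor = eigen_oracle(lons, lats, w)
            if p.isotropic:
                continue
            assert p.sigma_major == pytest.approx(major, abs=1e-6)
            assert p.sigma_minor == pytest.approx(minor, abs=1e-6)
            # azimuth compared on the half-circle
            diff = abs(p.azimuth_deg - az) % 180.0
            assert min(diff, 180.0 - diff) < 1e-6

    def test_recovers_rotated_anisotropic_gaussian(self):
        rng = np.random.default_rng(2)
        n = 10_000
        u = rng.normal(0, 2.0, n)   # major axis sd 2°
        v = rng.normal(0, 0.5, n)   # minor axis sd 0.5°
        az = math.radians(55.0)     # 55° clockwise from north
        lons = 150.0 + u * math.sin(az) + v * math.cos(az)
        lats = 40.0 + u * math.cos(az) - v * math.sin(az)
        p = standard_deviational_ellipse(lons, lats)
        assert abs(p.azimuth_deg - 55.0) < 2.0
        assert p.oblateness == pytest.approx(4.0, rel=0.05)

    def test_printed_axes_give_printed_oblateness(self):
        # a published SDE table row: major 2.89, short 1.06 -> 2.73
        assert round(2.89 / 1.06, 2) == 2.73

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        lons = rng.uniform(145, 150, 30)
        lats = rng.uniform(38, 42, 30)
        w = rng.uniform(1, 3, 30)
        p0 = standard_deviational_ellipse(lons, lats, w)
        p1 = standard_deviational_ellipse(lons + 1.0, lats + 1.0, w)
        assert p1.center_x == pytest.approx(p0.center_x + 1.0)
        assert p1.center_y == pytest.approx(p0.center_y + 1.0)
        assert p1.azimuth_deg == pytest.approx(p0.azimuth_deg, abs=1e-9)
        assert p1.sigma_major == pytest.approx(p0.sigma_major, abs=1e-9)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(4)
        lons = rng.uniform(145, 150, 25)
        lats = rng.uniform(38, 42, 25)
        w = rng.uniform(1, 3, 25)
        p0 = standard_deviational_ellipse(lons, lats, w)
        p1 = standard_deviational_ellipse(lons, lats, 2.0 * w)
        assert p1.azimuth_deg == pytest.approx(p0.azimuth_deg)
        assert p1.sigma_major == pytest.approx(p0.sigma_major)
        assert p1.sigma_minor == pytest.approx(p0.sigma_minor)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        lons = rng.normal(0, 2.0, 50)
        lats = rng.normal(0, 0.7, 50)
        p0 = standard_deviational_ellipse(lons, lats)
        phi = math.radians(30.0)  # rotate clockwise (viewed from north)
        lons2 = lons * math.cos(phi) + lats * math.sin(phi)
        lats2 = -lons * math.sin(phi) + lats * math.cos(phi)
        p1 = standard_deviational_ellipse(lons2, lats2)
        assert p1.azimuth_deg == pytest.approx(
            (p0.azimuth_deg + 30.0) % 180.0, abs=1e-6
        )
        assert p1.sigma_major == pytest.approx(p0.sigma_major, abs=1e-9)
        assert p1.oblateness == pytest.approx(p0.oblateness, abs=1e-9)

    def test_collinear_points_flagged_degenerate(self):
        p = standard_deviational_ellipse([150, 151, 152.0], [40, 41, 42.0])
        assert p.degenerate
        assert p.sigma_minor == 0.0
        assert math.isnan(p.oblateness)

    def test_circle_flagged_isotropic(self):
        t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        p = standard_deviational_ellipse(150 + np.cos(t), 40 + np.sin(t))
        assert p.isotropic
        assert p.azimuth_deg == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            standard_deviational_ellipse([150.0, 151.0], [40.0, 41.0])

    def test_polygon_is_closed_and_on_the_ellipse(self):
        rng = np.random.default_rng(6)
        p = standard_deviational_ellipse(
            rng.normal(150, 1, 100), rng.normal(40, 0.4, 100)
        )
        ring = ellipse_polygon(p, n_segments=32)
        assert ring[0] == ring[-1]
        assert len(ring) == 33


class TestTrajectories:
    def test_stationary_generator_steps_near_zero(self):
        from fishspat import SyntheticConfig, generate_hauls

        cfg = SyntheticConfig(
            years=(2014, 2015, 2016), n_hauls_per_year=5000,
            annual_drift=(0.0, 0.0), seasonal_amplitude=0.0,
            env_resolution=0.5, seed=30,
        )
        traj = cog_trajectory(generate_hauls(cfg))
        steps = traj.dropna(subset=["dlon"])
        # COG standard error ~ sd/sqrt(n) ~ 1.0/70 ~ 0.015° per period
        assert (steps["dlon"].abs() < 0.1).all()
        assert (steps["dlat"].abs() < 0.1).all()

    def test_ne_drift_gives_ne_bearings(self, small_hauls):
        traj = cog_trajectory(small_hauls)
        steps = traj.dropna(subset=["bearing_deg"])
        assert ((steps["bearing_deg"] > 0) & (steps["bearing_deg"] <= 90)).all()

    def test_single_period_has_no_steps(self, small_hauls):
        one = small_hauls[small_hauls["year"] == 2014]
        traj = cog_trajectory(one)
        assert len(traj) == 1
        assert traj["bearing_deg"].isna().all()

    def test_sde_series_azimuth_stable_under_fixed_anisotropy(self, small_hauls):
        series = sde_series(small_hauls)
        assert series["rotation_deg"].max() - series["rotation_deg"].min() < 10.0

    def test_sde_series_matches_single_period_computation(self, small_hauls):
        series = sde_series(small_hauls).set_index("period")
        g = small_hauls[small_hauls["year"] == 2015]
        p = standard_deviational_ellipse(
            g["lon"].to_numpy(), g["lat"].to_numpy(), g["catch_t"].to_numpy()
        )
        assert series.loc["2015", "rotation_deg"] == pytest.approx(p.azimuth_deg)
        assert series.loc["2015", "oblateness"] == pytest.approx(p.oblateness)
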