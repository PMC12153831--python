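"""Global Moran's I, its randomization inference, and the incremental sweep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fishspat import (
    contiguity_weights,
    incremental_moran,
    moran_global,
    moran_permutation_test,
    moran_randomization_variance,
    select_first_peak,
)

from conftest import make_grid


def brute_force_moran(x, w_dense):
    """Double loop over ordered pairs, straight from the definition."""
    x = np.asarray(x, dtype=float)
    n = x.size
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                num += w_dense[i, j] * z[i] * z[j]
                s0 += w_dense[i, j]
    return (n / s0) * num / (z**2).sum()


def test_checkerboard_rook_is_minus_one():
    vals = np.fromfunction(lambda j, i: ((i + j) % 2) * 2.0 - 1.0, (4, 4))
    g = make_grid(vals)
    w = contiguity_weights(g, kind="rook")
    r = moran_global(g.values("cpue"), w)
    assert r.I == pytest.approx(-1.0, abs=1e-12)


def test_expectation_is_closed_form():
    rng = np.random.default_rng(0)
    g = make_grid(rng.normal(size=(2, 5)))
    r = moran_global(g.values("cpue"), contiguity_weights(g, kind="queen"))
    assert r.E_I == -1.0 / 9.0


def test_matches_brute_force_double_loop():
    rng = np.random.default_rng(1)
    g = make_grid(rng.normal(size=(5, 5)))
    w = contiguity_weights(g, kind="queen")
    r = moran_global(g.values("cpue"), w)
    assert r.I == pytest.approx(
        brute_force_moran(g.values("cpue"), w.matrix.toarray()), abs=1e-12
    )


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    st.floats(min_value=-5, max_value=5).filter(lambda a: abs(a) > 1e-3),
    st.floats(min_value=-100, max_value=100),
)
def test_affine_invariance(a, b):
    rng = np.random.default_rng(8)
    g = make_grid(rng.normal(size=(4, 4)))
    w = contiguity_weights(g, kind="queen")
    x = g.values("cpue")
    assert moran_global(a * x + b, w).I == pytest.approx(moran_global(x, w).I, abs=1e-9)


def test_constant_values_rejected():
    g = make_grid(np.ones((3, 3)))
    with pytest.raises(ValueError, match="constant"):
        moran_global(g.values("cpue"), contiguity_weights(g, kind="rook"))


def test_variance_positive_and_matches_monte_carlo():
    """Closed-form Var(I) vs the empirical variance over random relabelings."""
    rng = np.random.default_rng(2)
    vals = np.array([[1.0, 4.0, 2.0], [7.0, 0.5, 3.0], [2.5, 6.0, 1.5]])
    g = make_grid(vals)
    w = contiguity_weights(g, kind="rook")
    var = moran_randomization_variance(g.values("cpue"), w)
    assert var > 0
    x = g.values("cpue")
    wd = w.matrix
    n = x.size
    s0 = wd.sum()
    draws = np.empty(100_000)
    for k in range(draws.size):
        z = rng.permutation(x)
        z = z - z.mean()
        draws[k] = (n / s0) * (z @ (wd @ z)) / (z @ z)
    assert var == pytest.approx(draws.var(), rel=0.02)


def test_analytic_and_permutation_z_agree():
    rng = np.random.default_rng(5)
    g = make_grid(rng.normal(size=(5, 5)))
    w = contiguity_weights(g, kind="queen")
    x = g.values("cpue")
    var = moran_randomization_variance(x, w)
    # permutation distribution sd on the same instance
    wd = w.matrix
    n = x.size
    s0 = wd.sum()
    draws = np.empty(100_000)
    for k in range(draws.size):
        z = rng.permutation(x)
        z = z - z.mean()
        draws[k] = (n / s0) * (z @ (wd @ z)) / (z @ z)
    assert np.sqrt(var) == pytest.approx(draws.std(), rel=0.05)


def test_permutation_same_seed_identical_p():
    rng = np.random.default_rng(6)
    g = make_grid(rng.normal(size=(5, 5)))
    w = contiguity_weights(g, kind="queen")
    r1 = moran_permutation_test(g.values("cpue"), w, n_perm=999, seed=77)
    r2 = moran_permutation_test(g.values("cpue"), w, n_perm=999, seed=77)
    assert r1.p_perm == r2.p_perm
    assert 0 < r1.p_perm <= 1


def test_permutation_detects_clustered_patch():
    vals = np.zeros((6, 6))
    vals[:3, :3] = 10.0  # one high patch
    vals += np.linspace(0, 0.01, 36).reshape(6, 6)  # break exact ties
    g = make_grid(vals)
    w = contiguity_weights(g, kind="queen")
    r = moran_permutation_test(g.values("cpue"), w, n_perm=999, seed=1)
    assert r.p_perm <= 0.01
    assert r.I > 0


def test_low_n_perm_warns():
    rng = np.random.default_rng(9)
    g = make_grid(rng.normal(size=(4, 4)))
    w = contiguity_weights(g, kind="queen")
    with pytest.warns(UserWarning, match="unstable"):
        moran_permutation_test(g.values("cpue"), w, n_perm=50, seed=0)


class TestIncremental:
    def test_distances_below_separation_flagged(self):
        rng = np.random.default_rng(3)
        g = make_grid(rng.normal(size=(4, 4)))
        prof = incremental_moran(
            g.values("cpue"), g, distances=[0.5, 1.0, 12.0, 30.0]
        )
        flagged = prof.bands[~prof.bands["ok"]]
        assert set(flagged["distance_km"]) == {0.5, 1.0}

    def test_gradient_field_z_positive_and_declining(self):
        # smooth north-south gradient: clustering strongest at short range
        jj, ii = np.indices((10, 10))
        g = make_grid(jj + 0.01 * np.random.default_rng(0).normal(size=(10, 10)))
        prof = incremental_moran(
            g.values("cpue"), g, distances=np.arange(15, 120, 15.0)
        )
        ok = prof.bands[prof.bands["ok"]]
        z = ok["z"].to_numpy()
        i_vals = ok["I"].to_numpy()
        assert (z > 0).all()
        # autocorrelation weakens as the threshold distance grows; the
        # z-score (which also gains pairs in cumulative bands) falls off
        # from its maximum by the largest distance
        assert (np.diff(i_vals) < 0).all()
        assert z[-1] < z.max()

    def test_cluster_scale_recovered_within_factor_two(self):
        # Gaussian blob of sd 0.2° (~22 km): peak z near the cluster
        # diameter, within a factor of 2
        rng = np.random.default_rng(12)
        jj, ii = np.indices((16, 16))
        lon = (ii - 8) * 0.1
        lat = (jj - 8) * 0.1
        vals = 10 * np.exp(-(lon**2 + lat**2) / (2 * 0.2**2))
        g = make_grid(vals + 0.05 * rng.normal(size=vals.shape))
        prof = incremental_moran(
            g.values("cpue"), g, distances=np.arange(10, 130, 5.0)
        )
        peak = select_first_peak(prof)
        diameter_km = 2 * 0.2 * 111.0
        assert peak is not None
        assert diameter_km / 2 <= peak <= diameter_km * 2

    def test_all_bands_empty_is_error(self):
        rng = np.random.default_rng(3)
        g = make_grid(rng.normal(size=(3, 3)))
        with pytest.raises(ValueError, match="empty"):
            incremental_moran(g.values("cpue"), g, distances=[0.1, 0.2, 0.3])


@pytest.mark.parametrize(
    "dist, z, expect",
    [
        ((10, 20, 30, 40, 50), (1.0, 2.5, 2.0, 3.0, 1.0), 20.0),
        ((10, 20, 30), (1.0, 1.5, 1.0), None),  # all below threshold
        ((10, 20), (2.5, 2.5), 10.0),  # plateau -> smaller distance
        ((10, 20, 30), (3.0, 2.0, 1.0), 10.0),  # strict endpoint max
        ((10, 20, 30), (2.0, 2.0, 3.0), 30.0),  # rising end; leading plateau not a peak
    ],
)
def test_first_peak_selection_rules(dist, z, expect):
    got = select_first_peak((np.array(dist, float), np.array(z, float)))
    assert got == expect
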