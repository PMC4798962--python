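"""Circular statistics: oracles by brute force, enumeration and simulation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import vesselpol as vp
from vesselpol.circstats import kuiper_statistic


class TestCircularMeanCI:
    def test_degenerate_all_equal(self):
        s = vp.circular_mean_ci([180.0] * 20)
        assert s.mean_angle_deg == pytest.approx(180.0)
        assert s.resultant_length == pytest.approx(1.0)
        assert s.ci95_halfwidth_deg == pytest.approx(0.0, abs=1e-6)
        assert s.significantly_polarized

    def test_antipodal_pair_not_polarized(self):
        s = vp.circular_mean_ci([0.0, 180.0] * 10)
        assert s.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert not s.significantly_polarized
        assert np.isnan(s.ci95_halfwidth_deg)

    def test_von_mises_sample_mean_within_ci(self):
        rng = np.random.default_rng(21)
        angles = np.degrees(rng.vonmises(np.pi, 2.0, size=1000)) % 360.0
        s = vp.circular_mean_ci(angles)
        assert s.significantly_polarized and s.rayleigh_p < 1e-3
        assert abs(s.mean_angle_deg - 180.0) <= s.ci95_halfwidth_deg

    def test_too_few_angles_error(self):
        with pytest.raises(ValueError):
            vp.circular_mean_ci([10.0])


def brute_force_kuiper(a, b):
    """V by explicit D+/D- evaluation at every rotation cut (O(n^2))."""
    a = np.sort(np.asarray(a) % 360.0)
    b = np.sort(np.asarray(b) % 360.0)
    pooled = np.concatenate([a, b])
    best = None
    for cut in pooled:
        aa = np.sort((a - cut) % 360.0)
        bb = np.sort((b - cut) % 360.0)
        xs = np.concatenate([aa, bb])
        dplus = dminus = 0.0
        for x in xs:
            fa = np.mean(aa <= x)
            fb = np.mean(bb <= x)
            dplus = max(dplus, fa - fb)
            dminus = max(dminus, fb - fa)
        v = dplus + dminus
        if best is None:
            best = v
        else:
            assert abs(v - best) < 1e-12  # rotation invariance of V
    return best


class TestKuiper:
    def test_small_sample_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.uniform(0, 360, 5)
            b = rng.uniform(0, 360, 5)
            assert kuiper_statistic(a, b) == pytest.approx(
                brute_force_kuiper(a, b), abs=1e-12)

    def test_permutation_p_matches_full_enumeration(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 360, 5)
        b = rng.vonmises(np.pi, 1.0, 5)
        b = np.degrees(b) % 360.0
        v_obs = kuiper_statistic(a, b)
        pooled = np.concatenate([a, b])
        vs = []
        for idx in itertools.combinations(range(10), 5):
            sel = np.zeros(10, dtype=bool)
            sel[list(idx)] = True
            vs.append(kuiper_statistic(pooled[sel], pooled[~sel]))
        vs = np.asarray(vs)
        exact_mid = (np.count_nonzero(vs > v_obs + 1e-12)
                     + 0.5 * np.count_nonzero(np.abs(vs - v_obs) <= 1e-12)
                     ) / vs.size
        _, p = vp.kuiper_two_sample(a, b, n_perm=9999, seed=0)
        assert p == pytest.approx(exact_mid, abs=0.03)

    def test_identical_samples_high_p(self):
        a = np.linspace(0, 359, 40)
        v, p = vp.kuiper_two_sample(a, a.copy(), n_perm=999, seed=1)
        assert p > 0.9

    def test_detects_von_mises_against_uniform(self):
        rng = np.random.default_rng(31)
        a = rng.uniform(0, 360, 500)
        b = np.degrees(rng.vonmises(0.0, 2.0, 500)) % 360.0
        _, p = vp.kuiper_two_sample(a, b, n_perm=999, seed=2)
        assert p < 0.01

    def test_rotation_invariance_of_statistic(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 360, 80)
        b = rng.uniform(0, 360, 120)
        v0 = kuiper_statistic(a, b)
        for off in (17.3, 123.456, 300.0):
            assert abs(kuiper_statistic(a + off, b + off) - v0) < 1e-12

    def test_asymptotic_p_reasonable(self):
        rng = np.random.default_rng(14)
        a = rng.uniform(0, 360, 300)
        b = np.degrees(rng.vonmises(0.0, 1.0, 300)) % 360.0
        v, p_asym = vp.kuiper_two_sample(a, b, method="asymptotic")
        assert p_asym < 0.01
        a2 = rng.uniform(0, 360, 300)
        b2 = rng.uniform(0, 360, 300)
        _, p_null = vp.kuiper_two_sample(a2, b2, method="asymptotic")
        assert p_null > 0.05

    def test_low_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            vp.kuiper_two_sample([1.0, 2.0], [3.0, 4.0], n_perm=10, seed=0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            vp.kuiper_two_sample([], [1.0])


class TestAntialignedFraction:
    def test_examples(self):
        assert vp.antialigned_fraction([180.0] * 4) == 1.0
        assert vp.antialigned_fraction([180.0, 170.0, 90.0, 0.0]) == 0.5

    def test_uniform_null_quarter(self):
        rng = np.random.default_rng(77)
        a = rng.uniform(0, 360, 10000)
        se = np.sqrt(0.25 * 0.75 / 10000)
        assert vp.antialigned_fraction(a) == pytest.approx(0.25, abs=3 * se)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            vp.antialigned_fraction([0.0], window_deg=200.0)


class TestBinByWss:
    def test_single_bin_recovers_global_fraction(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(0, 10, 500)
        a = rng.uniform(0, 360, 500)
        binned = vp.bin_by_wss(w, a, [0.0, 10.0])
        assert binned.n_cells[0] == 500
        assert binned.fraction_antialigned[0] == pytest.approx(
            vp.antialigned_fraction(a))

    def test_empty_bins_have_nan_fraction(self):
        binned = vp.bin_by_wss([1.0, 1.5], [180.0, 0.0], [0, 2, 4, 6])
        assert binned.n_cells.tolist() == [2, 0, 0]
        assert binned.fraction_antialigned[0] == 0.5
        assert np.isnan(binned.fraction_antialigned[1:]).all()

    def test_missing_wss_excluded_and_counted(self):
        binned = vp.bin_by_wss([1.0, np.nan, 2.0], [180.0, 180.0, 0.0],
                               [0.0, 4.0])
        assert binned.n_excluded == 1
        assert binned.n_cells.sum() == 2

    def test_wilson_ci_brackets_fraction(self):
        binned = vp.bin_by_wss([1.0] * 30, [180.0] * 21 + [0.0] * 9, [0, 2])
        assert binned.ci_low[0] < 0.7 < binned.ci_high[0]

    def test_nondecreasing_edges_required(self):
        with pytest.raises(ValueError):
            vp.bin_by_wss([1.0], [0.0], [3.0, 1.0])


class TestThresholdShear:
    def test_linear_interpolation_example(self):
        binned = vp.BinnedPolarization(
            bin_edges=np.array([0.0, 4.0, 8.0]),
            n_cells=np.array([50, 50]),
            fraction_antialigned=np.array([0.4, 0.8]),
            ci_low=np.zeros(2), ci_high=np.ones(2), window_deg=45.0)
        # midpoints 2 and 6 Pa; 0.6 is reached halfway
        assert vp.polarization_threshold_shear(binned, 0.6) == pytest.approx(4.0)

    def test_never_reached_returns_none(self):
        binned = vp.BinnedPolarization(
            bin_edges=np.array([0.0, 4.0, 8.0]),
            n_cells=np.array([50, 50]),
            fraction_antialigned=np.array([0.2, 0.4]),
            ci_low=np.zeros(2), ci_high=np.ones(2), window_deg=45.0)
        assert vp.polarization_threshold_shear(binned, 0.6) is None

    def test_single_nonempty_bin_warns_none(self):
        binned = vp.bin_by_wss([1.0, 1.2], [180.0, 170.0], [0, 2, 4])
        with pytest.warns(UserWarning):
            assert vp.polarization_threshold_shear(binned, 0.5) is None


def _records(wss, plen, angle_deg):
    wss = np.asarray(wss, dtype=float)
    plen = np.asarray(plen, dtype=float)
    angle = np.asarray(angle_deg, dtype=float)
    return pd.DataFrame({
        "wss_pa": wss,
        "angle_deg": angle,
        "scalar_product": plen * wss * np.cos(np.deg2rad(angle)),
    })


class TestScalarRegression:
    def test_pure_antiparallel_gradient(self):
        recs = _records(np.linspace(1, 9, 30), 5.0, 180.0)
        pos, neg = vp.scalar_product_regression(recs)
        assert not pos.available
        assert neg.available
        assert neg.gradient == pytest.approx(-5.0, rel=1e-9)
        assert neg.r_value == pytest.approx(-1.0, rel=1e-9)

    def test_pure_parallel_gradient(self):
        recs = _records(np.linspace(1, 9, 30), 5.0, 0.0)
        pos, _ = vp.scalar_product_regression(recs)
        assert pos.gradient == pytest.approx(5.0, rel=1e-9)

    def test_noisy_projection_recovers_gradient(self):
        rng = np.random.default_rng(13)
        n = 2000
        tau = rng.uniform(1.0, 10.0, n)
        c = 4.0
        proj = -c + rng.normal(0.0, 0.8, n)  # |p| cos(theta) around -c
        recs = pd.DataFrame({
            "wss_pa": tau,
            "angle_deg": np.where(proj < 0, 180.0, 0.0),
            "scalar_product": proj * tau,
        })
        _, neg = vp.scalar_product_regression(recs)
        assert neg.available
        assert abs(neg.gradient - (-c)) <= 2.0 * neg.stderr + 0.05

    def test_small_subset_unavailable(self):
        recs = _records([1.0, 2.0], 5.0, 180.0)
        pos, neg = vp.scalar_product_regression(recs)
        assert not neg.available and not pos.available

    def test_gradient_more_negative_with_higher_kappa(self):
        rng = np.random.default_rng(19)
        grads = []
        n = 4000
        tau = rng.uniform(1.0, 10.0, n)
        for kappa in (0.5, 2.0, 8.0):
            ang = np.degrees(rng.vonmises(np.pi, kappa, n)) % 360.0
            plen = rng.lognormal(np.log(7.0), 0.25, n)
            recs = _records(tau, plen, ang)
            _, neg = vp.scalar_product_regression(recs)
            grads.append(neg.gradient)
        assert grads[0] > grads[1] > grads[2]


def test_angle_histogram_covers_circle():
    rng = np.random.default_rng(2)
    a = rng.uniform(0, 360, 720)
    h = vp.angle_histogram(a, 10.0)
    assert len(h) == 36
    assert h["count"].sum() == 720
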