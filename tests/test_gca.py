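import numpy as np
import pytest

from causalflow import (GcaParams, connectivity_matrix, embed_delays,
                        linear_gca, npmr_gca, npmr_gca_pair, npmr_regress_loo,
                        simulate_subject_timeseries)
from causalflow.synthetic import GroundTruthNetwork
from causalflow.timeseries import RegionTimeSeries

from conftest import make_var_pair


class TestEmbedDelays:
    def test_row_and_column_counts(self):
        x = np.arange(20.0)
        y = np.arange(20.0) * 2
        restricted, full, target = embed_delays(x, y, 1)
        assert target.shape == (19,)
        assert restricted.shape == (19, 1)
        assert full.shape == (19, 2)

    def test_hand_constructed_lag2(self):
        y = np.array([1.0, 2, 3, 4, 5] + list(range(6, 16)))
        restricted, _, target = embed_delays(np.zeros_like(y), y, 2)
        np.testing.assert_array_equal(restricted[:3], [[2, 1], [3, 2], [4, 3]])
        np.testing.assert_array_equal(target[:3], [3, 4, 5])

    def test_too_short_rejected(self):
        x = np.arange(11.0)
        with pytest.raises(ValueError, match="too short"):
            embed_delays(x, x, 1)


class TestLinearGca:
    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        assert linear_gca(x, y, 1) < 0.02

    def test_var1_analytic_benchmark(self):
        # y_t = 0.8 x_{t-1} + e_t with unit variances: GCA = ln(1.64)
        x, y = make_var_pair(0.8, 5000, seed=1)
        assert abs(linear_gca(x, y, 1) - np.log(1.64)) < 0.1 * np.log(1.64)

    def test_reverse_direction_near_zero(self):
        x, y = make_var_pair(0.8, 5000, seed=1)
        assert linear_gca(y, x, 1) < 0.02

    def test_zero_variance_target_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="zero variance"):
            linear_gca(rng.normal(size=100), np.ones(100), 1)

    def test_non_negative(self):
        rng = np.random.default_rng(3)
        for s in range(10):
            x, y = rng.normal(size=50), rng.normal(size=50)
            assert linear_gca(x, y, 1) >= 0


class TestNpmrRegressLoo:
    def test_constant_target_zero_residuals(self):
        rng = np.random.default_rng(4)
        design = rng.normal(size=(30, 2))
        resid = npmr_regress_loo(design, np.full(30, 3.5), ridge=0.0)
        assert np.max(np.abs(resid)) < 1e-10

    def test_large_bandwidth_tends_to_loo_mean(self):
        rng = np.random.default_rng(5)
        design = rng.normal(size=(40, 1))
        target = rng.normal(size=40)
        resid = npmr_regress_loo(design, target, bandwidth=1e8, ridge=0.0)
        n = len(target)
        loo_mean = (target.sum() - target) / (n - 1)
        np.testing.assert_allclose(target - resid, loo_mean, atol=1e-6)

    def test_matches_bruteforce_per_row_loop(self):
        rng = np.random.default_rng(6)
        design = rng.normal(size=(30, 2))
        target = rng.normal(size=30)
        h = 0.7
        ridge = 1e-6
        resid = npmr_regress_loo(design, target, bandwidth=h, ridge=ridge)
        for t in range(30):
            others = np.delete(np.arange(30), t)
            w = np.ones(29)
            for c in range(2):
                w *= np.exp(-0.5 * ((design[t, c] - design[others, c]) / h) ** 2)
            pred = (w @ target[others]) / (w.sum() + ridge)
            assert abs(resid[t] - (target[t] - pred)) < 1e-10

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="20 rows"):
            npmr_regress_loo(np.random.default_rng(7).normal(size=(10, 1)),
                             np.zeros(10))
        with pytest.raises(ValueError, match="identical"):
            npmr_regress_loo(np.ones((25, 2)), np.arange(25.0))


class TestNpmrGca:
    def test_null_pair_small_value_balanced_direction(self):
        values, preferred = [], []
        for s in range(20):
            rng = np.random.default_rng(800 + s)
            x, y = rng.normal(size=1000), rng.normal(size=1000)
            gxy, gyx = npmr_gca_pair(x, y)
            values.append(gxy)
            total = gxy + gyx
            preferred.append(0.5 if total == 0 else gxy / total)
        assert np.mean(values) < 0.05
        assert 0.35 < np.mean(preferred) < 0.65

    def test_linear_kernel_reduces_to_linear_gca(self):
        x, y = make_var_pair(0.6, 800, seed=8)
        params = GcaParams(kernel="linear")
        assert abs(npmr_gca(x, y, params) - linear_gca(x, y, 1)) < 0.05

    def test_quadratic_coupling_seen_by_kernel_not_linear(self):
        npmr_wins = linear_blind = 0
        for s in range(10):
            x, y = make_var_pair(0.9, 1000, seed=900 + s, quadratic=True)
            gxy, gyx = npmr_gca_pair(x, y)
            npmr_wins += gxy > gyx
            linear_blind += linear_gca(x, y, 1) < 0.05
        assert npmr_wins >= 9
        assert linear_blind >= 8

    def test_in_sample_mode_runs(self):
        x, y = make_var_pair(0.5, 300, seed=10)
        value = npmr_gca(x, y, GcaParams(residual_mode="in_sample"))
        assert np.isfinite(value) and value >= 0

    def test_circular_shift_destroys_causality(self):
        x, y = make_var_pair(0.7, 500, seed=11)
        unshifted = npmr_gca(x, y)
        rng = np.random.default_rng(12)
        shifted_vals = []
        for _ in range(50):
            offset = int(rng.integers(50, 450))
            shifted_vals.append(npmr_gca(np.roll(x, offset), y))
        assert np.mean(shifted_vals) < 0.05 * unshifted + 0.02

    def test_params_validation(self):
        with pytest.raises(ValueError):
            GcaParams(order=0)
        with pytest.raises(ValueError):
            GcaParams(kernel="cubic")
        with pytest.raises(ValueError):
            GcaParams(bandwidth=-1.0)
        with pytest.raises(ValueError):
            GcaParams(ridge=-1e-3)


class TestConnectivityMatrix:
    def test_independent_regions_all_small(self):
        rng = np.random.default_rng(13)
        ts = RegionTimeSeries(data=rng.normal(size=(1000, 3)), tr=3.0)
        conn = connectivity_matrix(ts)
        off = conn.g[~np.eye(3, dtype=bool)]
        assert np.all(off < 0.05)

    def test_planted_edge_is_maximum(self):
        net = GroundTruthNetwork(
            n_regions=3,
            coupling=np.array([[0.2, 0.7, 0.0],
                               [0.0, 0.2, 0.0],
                               [0.0, 0.0, 0.2]]))
        hits = 0
        for s in range(20):
            ts = simulate_subject_timeseries(net, 500, 3.0, seed=1300 + s)
            g = connectivity_matrix(ts).g
            flat = g.copy()
            flat[0, 1] = -1
            hits += g[0, 1] > flat.max()
        assert hits >= 18

    def test_shape_and_diagonal_contract(self):
        rng = np.random.default_rng(14)
        ts = RegionTimeSeries(data=rng.normal(size=(120, 4)), tr=3.0)
        conn = connectivity_matrix(ts)
        assert conn.g.shape == (4, 4)
        assert np.all(np.diag(conn.g) == 0)
        assert np.all(conn.g >= 0) and np.all(np.isfinite(conn.g))
        assert conn.n_timepoints_used == 119

    def test_zero_variance_region_rejected(self):
        rng = np.random.default_rng(15)
        data = rng.normal(size=(100, 3))
        data[:, 1] = 2.0
        ts = RegionTimeSeries(data=data, tr=3.0)
        with pytest.raises(ValueError, match="region 2"):
            connectivity_matrix(ts)

    def test_matches_pairwise_npmr_gca(self):
        rng = np.random.default_rng(16)
        ts = RegionTimeSeries(data=rng.normal(size=(150, 3)), tr=3.0)
        conn = connectivity_matrix(ts)
        for i in range(3):
            for j in range(3):
                if i != j:
                    direct = npmr_gca(ts.data[:, i], ts.data[:, j])
                    assert abs(conn.g[i, j] - direct) < 1e-10

    def test_linear_kernel_matrix(self):
        x, y = make_var_pair(0.7, 300, seed=17)
        ts = RegionTimeSeries(data=np.column_stack([x, y]), tr=3.0)
        conn = connectivity_matrix(ts, GcaParams(kernel="linear",
                                                 residual_mode="in_sample"))
        assert abs(conn.g[0, 1] - linear_gca(x, y, 1)) < 1e-10
        assert conn.g[0, 1] > conn.g[1, 0]
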