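import numpy as np
import pytest
from scipy import stats

from causalflow import (GroundTruthNetwork, InformationFlow, bh_fdr,
                        chisq_2x2, default_network, edgewise_test,
                        ks_normality, mannwhitney, nodewise_test,
                        simulate_subject_timeseries, ttest_from_summary)

from conftest import flow_from_matrix, random_valid_preferred


class TestTtestFromSummary:
    def test_identical_summaries(self):
        t, df, p = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10,
                                      variant="student")
        assert t == 0 and p == 1 and df == 18

    @pytest.mark.parametrize("variant", ["student", "welch"])
    def test_matches_moment_matched_sample_oracle(self, variant):
        rng = np.random.default_rng(0)
        m1, s1, n1, m2, s2, n2 = 73.4, 35.43, 29, 93.1, 64.66, 37

        def sample(m, s, n, seed):
            z = np.random.default_rng(seed).normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return m + s * z

        a, b = sample(m1, s1, n1, 1), sample(m2, s2, n2, 2)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=(variant == "student"))
        t, df, p = ttest_from_summary(m1, s1, n1, m2, s2, n2, variant=variant)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_welch_df_smaller_than_pooled(self):
        _, df_w, _ = ttest_from_summary(0, 1.0, 10, 1, 3.0, 30, variant="welch")
        _, df_s, _ = ttest_from_summary(0, 1.0, 10, 1, 3.0, 30, variant="student")
        assert df_w < df_s == 38

    def test_degenerate_inputs(self):
        t, _, p = ttest_from_summary(2.0, 0.0, 5, 2.0, 0.0, 5)
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(ValueError, match="infinite"):
            ttest_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)
        with pytest.raises(ValueError, match="n >= 2"):
            ttest_from_summary(1.0, 1.0, 1, 2.0, 1.0, 5)

    def test_welch_student_agree_for_balanced_equal_variance(self):
        # equal group sizes and exactly equal variances: the Welch df
        # collapses to the pooled df, so the two p-values coincide
        rng = np.random.default_rng(1)
        for _ in range(5):
            mean_a, mean_b = rng.normal(size=2)
            args = (mean_a, 1.7, 30, mean_b, 1.7, 30)
            _, _, p_w = ttest_from_summary(*args, variant="welch")
            _, _, p_s = ttest_from_summary(*args, variant="student")
            assert abs(p_w - p_s) < 5e-4


class TestChisq2x2:
    def test_proportional_table_null(self):
        chi2, p = chisq_2x2(10, 10, 20, 20)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_association_hand_value(self):
        # Pearson formula: n (ad - bc)^2 / (r1 r2 c1 c2) = 60 * 900^2 / 30^4
        chi2, p = chisq_2x2(30, 0, 0, 30)
        assert chi2 == pytest.approx(60.0)
        assert p < 1e-13

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            chisq_2x2(0, 0, 5, 5)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2(1.5, 2, 3, 4)


class TestKsAndMannWhitney:
    def test_mw_enumerated_extreme_case(self):
        # all 3 A-ranks below all B-ranks: 1 of C(6,3)=20 arrangements,
        # two-sided p = 2/20
        U, p = mannwhitney([1, 2, 3], [4, 5, 6])
        assert U == 0
        assert p == pytest.approx(0.1)

    def test_mw_identical_samples(self):
        _, p = mannwhitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_mw_empty_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney([], [1.0])

    def test_ks_calibrated_on_normal_samples(self):
        ok = 0
        for s in range(100):
            x = np.random.default_rng(2000 + s).normal(size=100)
            _, p = ks_normality(x)
            ok += p > 0.05
        assert ok >= 90

    def test_ks_detects_gross_nonnormality(self):
        x = np.random.default_rng(3).exponential(size=500)
        _, p = ks_normality(x)
        assert p < 0.01

    def test_ks_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ks_normality(np.ones(20))
        with pytest.raises(ValueError, match="n >= 5"):
            ks_normality([1.0, 2.0])


class TestBhFdr:
    def test_stepup_hand_case(self):
        q, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], level=0.05)
        assert reject.all()
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        q, reject = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()
        assert np.all(q == 1.0)

    def test_single_p_equals_q(self):
        q, _ = bh_fdr([0.037])
        assert q[0] == pytest.approx(0.037)

    def test_matches_hand_stepup_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        q, reject = bh_fdr(p, level=0.05)
        # independent step-up implementation
        m = len(p)
        order = np.argsort(p)
        q_hand = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, m * p[order[rank - 1]] / rank)
            q_hand[order[rank - 1]] = running
        np.testing.assert_allclose(q, q_hand, atol=1e-12)
        np.testing.assert_array_equal(reject, q_hand <= 0.05)

    def test_monotone_rejection_nesting(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        _, reject_strict = bh_fdr(p, level=0.01)
        _, reject_loose = bh_fdr(p, level=0.05)
        assert np.all(reject_loose[reject_strict])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestEdgewiseNodewise:
    def test_identical_groups_no_discoveries(self, small_cohort_flows):
        half = small_cohort_flows[:6]
        edge = edgewise_test(half, list(half))
        node = nodewise_test(half, list(half))
        assert edge.n_significant == 0
        assert node.n_significant == 0

    def test_report_dimensions(self, small_cohort_flows):
        a, b = small_cohort_flows[:6], small_cohort_flows[6:]
        n = a[0].n_regions
        edge = edgewise_test(a, b)
        node = nodewise_test(a, b)
        assert len(edge.table) == n * (n - 1) // 2
        assert len(node.table) == n
        assert set(edge.table.columns) >= {"id", "t", "p", "q", "significant",
                                           "direction"}
        assert np.all(edge.table.q >= edge.table.p - 1e-12)

    def test_t_antisymmetric_between_triangles(self, small_cohort_flows):
        a, b = small_cohort_flows[:6], small_cohort_flows[6:]
        report = edgewise_test(a, b)
        # flipping every subject's matrix (transpose) negates every t
        flipped_a = [flow_from_matrix(f.p_matrix.T) for f in a]
        flipped_b = [flow_from_matrix(f.p_matrix.T) for f in b]
        flipped = edgewise_test(flipped_a, flipped_b)
        np.testing.assert_allclose(flipped.table.t.to_numpy(),
                                   -report.table.t.to_numpy(), atol=1e-10)

    def test_constant_edge_handling(self):
        rng = np.random.default_rng(6)
        flows_a = [flow_from_matrix(random_valid_preferred(3, rng))
                   for _ in range(4)]
        fixed = random_valid_preferred(3, rng)
        flows_b = [flow_from_matrix(fixed.copy()) for _ in range(4)]
        same = edgewise_test(flows_b, [flow_from_matrix(fixed.copy())
                                       for _ in range(4)])
        assert np.all(same.table.p == 1.0)
        assert np.all(same.table.t == 0.0)
        mixed = edgewise_test(flows_a, flows_b)
        assert np.all(np.isfinite(mixed.table.p))

    def test_minimum_group_size_enforced(self, small_cohort_flows):
        with pytest.raises(ValueError, match="2 subjects"):
            edgewise_test(small_cohort_flows[:1], small_cohort_flows[1:])

    def test_planted_source_node_discovered(self):
        # node 0 sends through three reciprocal pairs whose forward weights
        # are tripled in group B -> its flow index should rise
        net = default_network(n_regions=5,
                              reciprocal_pairs=((0, 1), (0, 2), (0, 3)),
                              reciprocal_weight=0.2, extra_edges=())
        effects = [(0, 1, 3.0), (0, 2, 3.0), (0, 3, 3.0)]
        net_b = net.with_effects(effects)
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(7000 + s)
            flows_a, flows_b = [], []
            for _ in range(25):
                seed = int(rng.integers(0, 2**31 - 1))
                ts = simulate_subject_timeseries(net, 500, 3.0, seed=seed)
                flows_a.append(InformationFlow(ts).fit().flow)
            for _ in range(25):
                seed = int(rng.integers(0, 2**31 - 1))
                ts = simulate_subject_timeseries(net_b, 500, 3.0, seed=seed)
                flows_b.append(InformationFlow(ts).fit().flow)
            report = nodewise_test(flows_a, flows_b)
            row = report.table.iloc[0]
            hits += bool(row.significant and row.direction == "increased")
        assert hits >= 0.8 * n_seeds
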