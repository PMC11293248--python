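import numpy as np
import pytest

from dnbtip.dnb_core import (
    DominantGroupConfig,
    cluster_candidates,
    compute_ci,
    detect_tipping,
    candidate_genes,
    pearson_matrix,
    permutation_test,
    per_time_sd,
    pooled_pearson_matrix,
    scan_time_points,
)
from dnbtip.synthetic_data import SimulationConfig, simulate_series

EPS = 1e-3


def pearson_bruteforce(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    return float((xm * ym).sum() / denom) if denom else 0.0


def ci_bruteforce(values, group, epsilon=EPS):
    """Explicit pair loops over the genes x replicates matrix ``values``."""
    n_genes = values.shape[0]
    sds = [np.std(values[i], ddof=1) for i in range(n_genes)]
    sd_in = np.mean([sds[i] for i in group])
    pairs_in = [
        abs(pearson_bruteforce(values[i], values[j]))
        for a, i in enumerate(group)
        for j in group[a + 1 :]
    ]
    outside = [i for i in range(n_genes) if i not in group]
    pairs_out = [
        abs(pearson_bruteforce(values[i], values[j])) for i in group for j in outside
    ]
    pcc_in = float(np.mean(pairs_in))
    pcc_out = float(np.mean(pairs_out))
    return sd_in * pcc_in / (pcc_out + epsilon), sd_in, pcc_in, pcc_out


class TestPerTimeSd:
    def test_known_value(self, series_factory):
        s = series_factory([[1, 2, 3, 4]], n_times=1, n_reps=4)
        assert per_time_sd(s, 1)[0] == pytest.approx(1.2909944487358056, abs=1e-12)

    def test_constant_gene_is_zero(self, series_factory):
        s = series_factory([[7, 7, 7, 7]], n_times=1, n_reps=4)
        assert per_time_sd(s, 1)[0] == 0.0

    def test_homogeneity(self, small_random_series):
        s = small_random_series
        doubled = type(s)(
            s.gene_ids, s.sample_labels, s.time_of_sample,
            s.replicate_of_sample, 2 * s.values,
        )
        np.testing.assert_allclose(per_time_sd(doubled, 2), 2 * per_time_sd(s, 2))


class TestPearsonMatrix:
    def test_perfect_linear_pairs(self, series_factory):
        g1 = [1.0, 2, 3, 4]
        s = series_factory([g1, [2 * v for v in g1], [-v + 7 for v in g1]],
                           n_times=1, n_reps=4)
        m = pearson_matrix(s, 1)
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)

    def test_known_correlation(self, series_factory):
        s = series_factory([[1, 2, 3, 4], [1, 1, 2, 2]], n_times=1, n_reps=4)
        assert pearson_matrix(s, 1)[0, 1] == pytest.approx(0.8944271909999159, abs=1e-12)

    def test_zero_variance_gene_recorded_as_zero(self, series_factory):
        s = series_factory([[1, 2, 3, 4], [5, 5, 5, 5]], n_times=1, n_reps=4)
        m = pearson_matrix(s, 1)
        assert m[0, 1] == 0.0 and m[1, 1] == 1.0

    def test_matches_bruteforce_on_random_instances(self, series_factory):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n_genes = rng.integers(2, 20)
            n_reps = rng.integers(2, 12)
            vals = rng.normal(size=(n_genes, n_reps))
            s = series_factory(vals, n_times=1, n_reps=n_reps)
            m = pearson_matrix(s, 1)
            assert m.shape == (n_genes, n_genes)
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(m), 1.0)
            for i in range(n_genes):
                for j in range(i + 1, n_genes):
                    assert m[i, j] == pytest.approx(
                        pearson_bruteforce(vals[i], vals[j]), abs=1e-10
                    )


class TestCandidateGenes:
    def test_fold_threshold_inclusion(self, series_factory):
        # g1 SD trebles at t2, g2 constant SD
        vals = np.array(
            [[1, 2, 3, 4, 1, 4, 7, 10], [1, 2, 3, 4, 2, 3, 4, 5]], dtype=float
        )
        s = series_factory(vals, n_times=2, n_reps=4)
        got = candidate_genes(s, 2, 1, sd_fold=2.0, sd_reference_mode="baseline")
        assert got == ["g1"]

    def test_equal_sds_excluded(self, series_factory):
        s = series_factory([[1, 2, 3, 4, 4, 3, 2, 1]], n_times=2, n_reps=4)
        assert candidate_genes(s, 2, 1, sd_fold=2.0, sd_reference_mode="baseline") == []

    def test_zero_reference_uses_median_fallback(self, series_factory):
        vals = np.array(
            [[5, 5, 5, 5, 1, 9, 1, 9], [1, 2, 3, 4, 1, 2, 3, 4]], dtype=float
        )
        s = series_factory(vals, n_times=2, n_reps=4)
        got = candidate_genes(s, 2, 1, sd_fold=2.0, sd_reference_mode="baseline")
        assert "g1" in got  # SD jumped from 0 against median reference

    def test_module_genes_enriched_among_candidates_at_tipping(self):
        hits = 0
        for seed in range(20):
            series, truth = simulate_series(SimulationConfig(seed=seed))
            dnb = set(truth.dnb_genes)
            at_tip = len(dnb & set(candidate_genes(series, truth.tipping_time, 1, 1.5)))
            off = len(dnb & set(candidate_genes(series, 3, 1, 1.5)))
            hits += at_tip > off
        assert hits >= 17


class TestClusterCandidates:
    def _series_matrix(self, blocks):
        return np.abs(np.asarray(blocks))

    def test_two_perfect_blocks_recovered(self):
        corr = np.eye(6)
        corr[:3, :3] = 1.0
        corr[3:, 3:] = 1.0
        genes = [f"g{i}" for i in range(6)]
        cfg = DominantGroupConfig(min_group_size=2, linkage_cut=0.5)
        groups = cluster_candidates(corr, genes, cfg)
        assert sorted(map(tuple, groups)) == [
            ("g0", "g1", "g2"), ("g3", "g4", "g5")
        ]

    def test_all_correlated_is_one_group(self):
        corr = np.ones((4, 4))
        cfg = DominantGroupConfig(min_group_size=2)
        assert cluster_candidates(corr, list("abcd"), cfg) == [list("abcd")]

    def test_fewer_than_min_size_returns_empty(self):
        cfg = DominantGroupConfig(min_group_size=5)
        assert cluster_candidates(np.eye(3), list("abc"), cfg) == []

    def test_small_groups_discarded(self):
        corr = np.eye(7)
        corr[:5, :5] = 1.0
        corr[5:, 5:] = 1.0
        cfg = DominantGroupConfig(min_group_size=5, linkage_cut=0.5)
        groups = cluster_candidates(corr, [f"g{i}" for i in range(7)], cfg)
        assert groups == [[f"g{i}" for i in range(5)]]


class TestComputeCI:
    def test_worked_three_gene_example(self, series_factory):
        vals = np.array([[1, 2, 3, 4], [2, 4, 6, 8], [1, 1, 2, 2]], dtype=float)
        s = series_factory(vals, n_times=1, n_reps=4)
        comp = compute_ci(
            per_time_sd(s, 1), pearson_matrix(s, 1), [0, 1],
            epsilon=EPS, gene_ids=s.gene_ids,
        )
        assert comp.sd_in == pytest.approx((1.2909944487 + 2.5819888975) / 2, abs=1e-9)
        assert comp.pcc_in == pytest.approx(1.0)
        assert comp.pcc_out == pytest.approx(0.8944271909999159, abs=1e-10)
        expected = ci_bruteforce(vals, [0, 1])[0]
        assert comp.ci == pytest.approx(expected, abs=1e-12)
        assert comp.ci == pytest.approx(2.1626, abs=5e-4)

    def test_epsilon_guard_active_when_uncorrelated(self, series_factory):
        vals = np.array([[1, 2, 3, 4], [2, 4, 6, 8], [1, -1, 1, -1]], dtype=float)
        vals[2] = [1, -1, -1, 1]  # orthogonal to the linear trend
        s = series_factory(vals, n_times=1, n_reps=4)
        comp = compute_ci(per_time_sd(s, 1), pearson_matrix(s, 1), [0, 1],
                          epsilon=EPS, gene_ids=s.gene_ids)
        assert comp.pcc_out == pytest.approx(0.0, abs=1e-12)
        assert comp.ci == pytest.approx(comp.sd_in * comp.pcc_in / EPS)

    def test_scaling_doubles_ci(self, small_random_series):
        s = small_random_series
        group = [0, 1, 2]
        a = compute_ci(per_time_sd(s, 1), pearson_matrix(s, 1), group)
        s2 = type(s)(s.gene_ids, s.sample_labels, s.time_of_sample,
                     s.replicate_of_sample, 2 * s.values)
        b = compute_ci(per_time_sd(s2, 1), pearson_matrix(s2, 1), group)
        assert b.ci == pytest.approx(2 * a.ci, rel=1e-9)

    def test_matches_bruteforce_on_random_instances(self, series_factory):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n_genes = int(rng.integers(4, 20))
            n_reps = int(rng.integers(3, 12))
            vals = rng.normal(size=(n_genes, n_reps))
            s = series_factory(vals, n_times=1, n_reps=n_reps)
            gsize = int(rng.integers(2, n_genes))
            group = sorted(rng.choice(n_genes, size=gsize, replace=False).tolist())
            comp = compute_ci(per_time_sd(s, 1), pearson_matrix(s, 1), group, epsilon=EPS)
            ci, sd_in, pcc_in, pcc_out = ci_bruteforce(vals, group)
            assert comp.ci == pytest.approx(ci, abs=1e-10)
            assert comp.sd_in == pytest.approx(sd_in, abs=1e-10)
            assert comp.pcc_in == pytest.approx(pcc_in, abs=1e-10)
            assert comp.pcc_out == pytest.approx(pcc_out, abs=1e-10)

    def test_ci_monotone_in_correlations(self):
        """Raising within-group |r| raises CI; raising out-group |r| lowers it."""
        sd = np.array([1.0, 1.0, 1.0, 1.0])
        base = np.eye(4)

        def ci_for(r_in, r_out):
            m = base.copy()
            m[0, 1] = m[1, 0] = r_in
            m[0, 2] = m[2, 0] = m[0, 3] = m[3, 0] = r_out
            m[1, 2] = m[2, 1] = m[1, 3] = m[3, 1] = r_out
            return compute_ci(sd, m, [0, 1], epsilon=EPS).ci

        cis_in = [ci_for(r, 0.3) for r in np.linspace(0.1, 0.9, 9)]
        assert np.all(np.diff(cis_in) >= 0)
        cis_out = [ci_for(0.8, r) for r in np.linspace(0.1, 0.9, 9)]
        assert np.all(np.diff(cis_out) <= 0)

    def test_degenerate_groups_rejected(self, small_random_series):
        s = small_random_series
        sd, m = per_time_sd(s, 1), pearson_matrix(s, 1)
        with pytest.raises(ValueError):
            compute_ci(sd, m, [0])
        with pytest.raises(ValueError):
            compute_ci(sd, m, list(range(20)))


class TestDetectTipping:
    def test_argmax(self):
        assert detect_tipping([0, 0.5, 0.4, 3.1, 0.2, 8.9, 1.0, 0.7]) == 6

    def test_all_zero_is_none(self):
        assert detect_tipping([0.0, 0.0, 0.0]) is None

    def test_tie_goes_to_earliest(self):
        assert detect_tipping([0, 2.0, 2.0]) == 2

    def test_custom_time_labels(self):
        assert detect_tipping([1.0, 5.0], times=[3, 7]) == 7


class TestScan:
    def test_recovers_planted_tipping_on_easy_instance(self):
        series, truth = simulate_series(SimulationConfig(seed=11))
        res = scan_time_points(series)
        assert res.tipping == truth.tipping_time
        assert set(res.tipping_group) & set(truth.dnb_genes)
        assert res.ci_series[1] == 0.0

    def test_no_candidates_flags_no_transition(self, series_factory):
        vals = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (6, 8))
        s = series_factory(vals, n_times=8, n_reps=4)
        res = scan_time_points(s)
        assert res.tipping is None
        assert "no transition detected" in res.flags

    def test_gene_order_invariance(self):
        series, _ = simulate_series(SimulationConfig(seed=12, n_genes=120, n_dnb=6))
        rng = np.random.default_rng(0)
        order = list(rng.permutation(series.gene_ids))
        shuffled = series.reordered(order)
        a = scan_time_points(series)
        b = scan_time_points(shuffled)
        assert a.tipping == b.tipping
        for t in a.ci_series:
            assert a.ci_series[t] == pytest.approx(b.ci_series[t], abs=1e-9)
        assert a.tipping_group == b.tipping_group

    def test_needs_three_time_points(self, series_factory):
        s = series_factory(np.random.default_rng(0).normal(size=(5, 8)),
                           n_times=2, n_reps=4)
        with pytest.raises(ValueError):
            scan_time_points(s)


class TestPooledPearson:
    def test_centering_removes_mean_shifts(self, series_factory):
        rng = np.random.default_rng(13)
        noise = rng.normal(size=(2, 8))
        shifted = noise.copy()
        shifted[0, 4:] += 100.0  # big mean shift at t2 only
        s_plain = series_factory(noise, n_times=2, n_reps=4)
        s_shift = series_factory(shifted, n_times=2, n_reps=4)
        np.testing.assert_allclose(
            pooled_pearson_matrix(s_plain), pooled_pearson_matrix(s_shift), atol=1e-10
        )


class TestPermutationTest:
    def test_strong_signal_gets_small_p(self):
        # the tipping samples keep their inflated variance wherever a
        # permutation puts them, so the null is not arbitrarily far below
        # the observed peak; still, a strong signal must look unusual
        series, _ = simulate_series(
            SimulationConfig(seed=1, n_genes=60, n_dnb=8, n_deg=10, sd_fold=6.0)
        )
        p = permutation_test(series, n_perm=19, seed=3)
        assert p <= 4 / 20

    def test_p_is_one_when_observed_is_weakest(self, series_factory):
        rng = np.random.default_rng(14)
        s = series_factory(rng.normal(size=(30, 32)), n_times=8, n_reps=4)
        p, obs, null = permutation_test(s, n_perm=19, seed=0, return_null=True)
        assert 0 < p <= 1
        # formula check against the returned null sample
        assert p == pytest.approx((1 + np.sum(null >= obs)) / 20)

    def test_minimum_permutations_enforced(self, small_random_series):
        with pytest.raises(ValueError):
            permutation_test(small_random_series, n_perm=5)

    def test_deterministic_given_seed(self):
        series, _ = simulate_series(
            SimulationConfig(seed=2, n_genes=80, n_dnb=6, n_deg=10)
        )
        assert permutation_test(series, n_perm=19, seed=9) == permutation_test(
            series, n_perm=19, seed=9
        )
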