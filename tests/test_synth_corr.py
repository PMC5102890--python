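"""Latent-community similarity-matrix generator: closed-form population
checks, large-sample sampling checks, and construction invariants."""

from dataclasses import replace

import numpy as np
import pytest

from commbench import synth_corr as sc
from commbench._exceptions import InvalidConditionError
from commbench.conditions import SizeScheme
from commbench.types import MatrixType, Partition, TimeSeriesData

from conftest import tiny_corr_condition


class TestAssignCommunitySizes:
    @pytest.mark.parametrize(
        "n,k,scheme,expected",
        [
            (1000, 10, "equal", [100] * 10),
            (1000, 10, "as_many_large_as_small", [150] * 5 + [50] * 5),
            (25, 5, "equal", [5] * 5),
        ],
    )
    def test_worked_examples(self, n, k, scheme, expected):
        assert sc.assign_community_sizes(n, k, scheme) == expected

    @pytest.mark.parametrize("scheme", list(SizeScheme))
    @pytest.mark.parametrize("n,k", [(25, 4), (75, 4), (500, 10), (1000, 10), (97, 7)])
    def test_sizes_sum_and_are_positive(self, n, k, scheme):
        sizes = sc.assign_community_sizes(n, k, scheme)
        assert sum(sizes) == n
        assert len(sizes) == k
        assert min(sizes) >= 1

    def test_equal_sizes_differ_by_at_most_one(self):
        sizes = sc.assign_community_sizes(103, 4, "equal")
        assert max(sizes) - min(sizes) <= 1

    def test_unequal_schemes_have_large_and_small(self):
        sizes = sc.assign_community_sizes(1000, 10, "more_small_than_large")
        assert max(sizes) > 2 * min(sizes)
        assert sizes.count(max(sizes)) < sizes.count(min(sizes))

    def test_too_many_communities_rejected(self):
        with pytest.raises(InvalidConditionError):
            sc.assign_community_sizes(5, 6, "equal")


class TestPopulationModel:
    def test_fixed_loading_range_gives_constant_loadings(self):
        cond = tiny_corr_condition(loading_range=(0.5, 0.5))
        model = sc.build_population_model(cond, seed=1)
        assert np.all(model.loadings == 0.5)

    def test_zero_level_diff_gives_zero_means(self):
        model = sc.build_population_model(tiny_corr_condition(), seed=1)
        assert np.all(model.community_means == 0.0)

    def test_level_diff_assignment_rule(self):
        model = sc.build_population_model(tiny_corr_condition(level_diff=2.0), seed=1)
        assert np.allclose(model.community_means, [0.0, 2.0, 4.0])

    def test_implied_correlation_closed_form(self):
        # same community: lambda_i * lambda_j; different: overlap * that
        cond = tiny_corr_condition(loading_range=(0.5, 0.5), overlap=0.1)
        model = sc.build_population_model(cond, seed=3)
        r = sc.implied_correlation(model).values
        lab = model.assignment.labels
        same = lab[0] == lab[1]
        assert same
        assert r[0, 1] == pytest.approx(0.25)
        other = int(np.flatnonzero(lab != lab[0])[0])
        assert r[0, other] == pytest.approx(0.025)

    def test_unit_diagonal_and_residuals(self):
        model = sc.build_population_model(tiny_corr_condition(), seed=5)
        r = sc.implied_correlation(model).values
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(model.residual_var, 1.0 - model.loadings**2)

    def test_single_community_all_offdiagonals_are_loading_products(self):
        cond = tiny_corr_condition(n_communities=1)
        model = sc.build_population_model(cond, seed=7)
        r = sc.implied_correlation(model).values
        lam = model.loadings
        expected = np.outer(lam, lam)
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(r, expected)

    def test_zero_loadings_give_identity(self):
        cond = tiny_corr_condition(loading_range=(0.0, 0.0), n_communities=1)
        model = sc.build_population_model(cond, seed=2)
        assert np.allclose(sc.implied_correlation(model).values, np.eye(cond.n_nodes))

    def test_all_registry_conditions_psd_unit_diagonal(self, registry):
        for cond in registry.corr:
            model = sc.build_population_model(cond, seed=11)
            r = sc.implied_correlation(model).values
            assert np.allclose(np.diag(r), 1.0)
            assert np.linalg.eigvalsh(r).min() > -1e-8, f"condition {cond.id}"

    def test_within_exceeds_between_strong_communities(self, registry):
        # planted communities in the strong sense whenever overlap < 1
        for cid in (1, 27, 29):
            cond = registry.corr_by_id(cid)
            model = sc.build_population_model(cond, seed=13)
            r = sc.implied_correlation(model).values
            lab = model.assignment.labels
            if model.n_communities == 1:
                continue
            same = lab[:, None] == lab[None, :]
            np.fill_diagonal(same, False)
            diff = lab[:, None] != lab[None, :]
            assert r[same].min() > 0
            # pairwise: within-pair r exceeds the between r of the same nodes
            assert r[same].mean() > r[diff].mean()


class TestTimeSeries:
    def test_determinism(self):
        model = sc.build_population_model(tiny_corr_condition(), seed=1)
        a = sc.generate_timeseries(model, 100, seed=9).values
        b = sc.generate_timeseries(model, 100, seed=9).values
        assert np.array_equal(a, b)

    def test_large_sample_moments(self):
        # law of large numbers at t = 10000 on a small graph
        cond = tiny_corr_condition(n_nodes=12, n_communities=3, level_diff=1.5, t_obs=502)
        model = sc.build_population_model(cond, seed=21)
        t_obs = 10_000
        ts = sc.generate_timeseries(model, t_obs, seed=22)
        r = sc.implied_correlation(model).values
        se_mean = 1.0 / np.sqrt(t_obs)
        means = ts.values.mean(axis=1)
        expected = model.community_means[model.assignment.labels - 1]
        assert np.all(np.abs(means - expected) < 3.5 * se_mean)
        cov = np.cov(ts.values)
        assert np.max(np.abs(cov - r)) < 3.5 * 2.0 / np.sqrt(t_obs)


class TestSampleMatrices:
    def test_pearson_toy_series(self):
        ts = TimeSeriesData(
            np.array([[1.0, 2, 3], [2, 4, 6], [3, 2, 1]]),
            Partition(np.array([1, 1, 1])),
            seed=0,
        )
        corr = sc.sample_correlation(ts).values
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)
        assert corr[1, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(corr) == 0.0)

    def test_zero_variance_node_rejected(self):
        ts = TimeSeriesData(
            np.array([[1.0, 1, 1], [1, 2, 3]]), Partition(np.array([1, 1])), seed=0
        )
        with pytest.raises(Exception, match="node 0"):
            sc.sample_correlation(ts)

    def test_reflection_arithmetic(self):
        # right triangle: distances {3, 4, 5} -> reflected {2, 1, 0}
        ts = TimeSeriesData(
            np.array([[0.0, 0], [3, 0], [0, 4]]), Partition(np.array([1, 1, 1])), seed=0
        )
        refl = sc.reflected_euclidean(ts).values
        assert refl[0, 1] == pytest.approx(2.0)
        assert refl[0, 2] == pytest.approx(1.0)
        assert refl[1, 2] == pytest.approx(0.0)  # max-distance pair -> exactly 0
        assert np.all(np.diag(refl) == 0.0)

    def test_identical_series_reflect_to_max_distance(self):
        ts = TimeSeriesData(
            np.array([[0.0, 0], [0, 0], [3, 4]]), Partition(np.array([1, 1, 1])), seed=0
        )
        refl = sc.reflected_euclidean(ts).values
        assert refl[0, 1] == pytest.approx(5.0)

    def test_reflection_reverses_ordering(self, rng):
        ts = TimeSeriesData(rng.normal(size=(6, 30)), Partition(np.ones(6, int)), seed=0)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(ts.values))
        refl = sc.reflected_euclidean(ts).values
        iu = np.triu_indices(6, 1)
        order_d = np.argsort(d[iu])
        order_r = np.argsort(refl[iu])[::-1]
        assert np.array_equal(order_d, order_r)


class TestGenerateInstance:
    def test_instances_share_truth_and_seed(self):
        cond = tiny_corr_condition()
        corr, eucd = sc.generate_corr_instance(cond, 0, seed=5)
        assert corr.truth == eucd.truth
        assert corr.seed == eucd.seed
        assert corr.matrix_type == MatrixType.CORRELATION
        assert eucd.matrix_type == MatrixType.REFLECTED_EUCD

    def test_correlation_invariant_to_level_diff_eucd_not(self):
        base = tiny_corr_condition(level_diff=0.0)
        shifted = tiny_corr_condition(level_diff=3.0)  # same id -> same draws
        c0, e0 = sc.generate_corr_instance(base, 0, seed=5)
        c1, e1 = sc.generate_corr_instance(shifted, 0, seed=5)
        assert np.allclose(c0.matrix.values, c1.matrix.values, atol=1e-10)
        assert not np.allclose(e0.matrix.values, e1.matrix.values, atol=1e-3)

    def test_determinism_and_distinct_replicate_seeds(self):
        cond = tiny_corr_condition()
        a, _ = sc.generate_corr_instance(cond, 0, seed=5)
        b, _ = sc.generate_corr_instance(cond, 0, seed=5)
        assert np.array_equal(a.matrix.values, b.matrix.values)
        seeds = {sc.generate_corr_instance(cond, r, seed=5)[0].seed for r in range(10)}
        assert len(seeds) == 10

    def test_matrix_invariants(self):
        corr, eucd = sc.generate_corr_instance(tiny_corr_condition(), 0, seed=8)
        assert np.max(np.abs(corr.matrix.values)) <= 1.0
        assert np.min(eucd.matrix.values) >= 0.0
        for m in (corr.matrix.values, eucd.matrix.values):
            assert np.allclose(m, m.T)
            assert np.all(np.diag(m) == 0.0)
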