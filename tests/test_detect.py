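"""Detection layer: preprocessing conventions, exact recovery on separable
toys, determinism/seeding, and the signed Louvain objective."""

import numpy as np
import pytest
from sklearn.base import clone

from commbench import detect as D
from commbench._exceptions import DegenerateInputError
from commbench.types import MatrixType, Partition, SimilarityMatrix

from oracles import (
    brute_best_modularity_partition,
    brute_best_signed_partition,
    brute_signed_modularity,
)


def cliques(sizes):
    n = sum(sizes)
    w = np.zeros((n, n))
    start = 0
    labels = []
    for k, s in enumerate(sizes, start=1):
        idx = np.arange(start, start + s)
        w[np.ix_(idx, idx)] = 1.0
        labels += [k] * s
        start += s
    np.fill_diagonal(w, 0.0)
    return w, Partition(np.array(labels))


class TestPreprocess:
    def test_negative_clipping_convention(self):
        w = np.array([[0.0, -0.3, 0.5], [-0.3, 0.0, 0.2], [0.5, 0.2, 0.0]])
        m = SimilarityMatrix(w, MatrixType.CORRELATION)
        clipped = D.preprocess(m, D.METHODS["Walktrap"])
        assert clipped.values[0, 1] == 0.0
        signed = D.preprocess(m, D.METHODS["LouvainGJA"])
        assert signed.values[0, 1] == -0.3

    def test_count_matrix_passes_through(self, two_cliques):
        m, _ = two_cliques
        for name in D.METHOD_NAMES:
            out = D.preprocess(m, D.METHODS[name])
            assert np.array_equal(out.values, m.values)

    def test_clipping_never_adds_edges(self, rng):
        w = rng.normal(size=(10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        m = SimilarityMatrix(w, MatrixType.CORRELATION)
        out = D.preprocess(m, D.METHODS["Walktrap"])
        assert np.count_nonzero(out.values) <= np.count_nonzero(w)

    def test_all_negative_matrix_degenerate(self):
        w = -np.ones((4, 4))
        np.fill_diagonal(w, 0)
        with pytest.raises(DegenerateInputError):
            D.preprocess(
                SimilarityMatrix(w, MatrixType.CORRELATION), D.METHODS["Walktrap"]
            )


class TestExactRecoveryOnCliques:
    @pytest.mark.parametrize("sizes", [(3, 3), (4, 4), (5, 3), (3, 3, 3), (4, 4, 4, 4)])
    @pytest.mark.parametrize("name", D.METHOD_NAMES)
    def test_disconnected_cliques_recovered(self, name, sizes):
        w, truth = cliques(sizes)
        res = D.run_method(name, w, seed=11)
        assert res.partition == truth

    def test_matches_exhaustive_modularity_optimum(self):
        # the planted two-triangle split is the global modularity optimum
        w, truth = cliques((3, 3))
        best, _ = brute_best_modularity_partition(w)
        assert Partition(best) == truth


class TestDeterminismAndSeeding:
    def test_deterministic_methods_repeat(self, two_cliques):
        m, _ = two_cliques
        for name in ("NSA", "Walktrap", "FastModularity"):
            runs = D.run_repeated(name, m, n_runs=3, seed=1)
            assert all(r.partition == runs[0].partition for r in runs)

    def test_nondeterministic_methods_reproducible_per_seed(self, rng):
        w, _ = cliques((5, 5, 5))
        noise = rng.uniform(0, 0.2, w.shape)
        w = w + (noise + noise.T) / 2
        np.fill_diagonal(w, 0)
        for name in ("LabelPropagation", "Infomap", "LouvainGJA"):
            a = D.run_method(name, w, seed=42)
            b = D.run_method(name, w, seed=42)
            assert a.partition == b.partition

    def test_run_repeated_seeds_distinct_and_logged(self, two_cliques):
        m, _ = two_cliques
        runs = D.run_repeated("LabelPropagation", m, n_runs=10, seed=3)
        seeds = [r.seed for r in runs]
        assert len(set(seeds)) == 10
        assert [r.run_index for r in runs] == list(range(10))

    def test_single_run_equals_run_method(self, two_cliques):
        m, _ = two_cliques
        (only,) = D.run_repeated("NSA", m, n_runs=1, seed=5)
        assert only.partition == D.run_method("NSA", m, seed=only.seed).partition


class TestEstimatorApi:
    def test_sklearn_contract(self, two_cliques):
        m, truth = two_cliques
        est = D.Walktrap(steps=4)
        assert clone(est).get_params()["steps"] == 4
        labels = est.fit_predict(m.values)
        assert np.array_equal(labels, est.labels_)
        assert est.n_communities_ == 2
        assert est.labels_.min() == 1

    def test_registry_flags(self):
        assert len(D.METHODS) == 6
        assert [s.accepts_negative_weights for s in D.METHODS.values()].count(True) == 1
        assert D.METHODS["LouvainGJA"].accepts_negative_weights
        for name in ("NSA", "Walktrap", "FastModularity"):
            assert D.METHODS[name].deterministic
        for name in ("LouvainGJA", "LabelPropagation", "Infomap"):
            assert not D.METHODS[name].deterministic


class TestSignedLouvain:
    def test_signed_blocks_recovered_exactly(self):
        # +0.8 within, -0.5 between: the signed objective separates the blocks
        w = np.full((8, 8), -0.5)
        w[:4, :4] = 0.8
        w[4:, 4:] = 0.8
        np.fill_diagonal(w, 0.0)
        res = D.run_method("LouvainGJA", w, seed=1)
        assert res.partition == Partition(np.array([1, 1, 1, 1, 2, 2, 2, 2]))

    def test_reaches_exhaustive_optimum_on_structured_signed_toys(self, rng):
        est = D.SignedLouvain(random_state=0)
        for trial in range(5):
            w, truth = cliques((3, 3))
            w = w - 0.4 * (truth.labels[:, None] != truth.labels[None, :])
            w += 0.05 * (lambda a: (a + a.T) / 2)(rng.normal(size=w.shape))
            np.fill_diagonal(w, 0.0)
            w = (w + w.T) / 2
            best, best_q = brute_best_signed_partition(w)
            res = D.run_method("LouvainGJA", w, seed=trial)
            q = est.signed_modularity(w, res.partition.labels)
            assert q <= best_q + 1e-9
            assert q == pytest.approx(best_q, abs=1e-9)

    def test_signed_modularity_matches_brute_sum(self, rng):
        est = D.SignedLouvain()
        for _ in range(10):
            w = rng.normal(size=(7, 7))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            labels = rng.integers(1, 4, 7)
            assert est.signed_modularity(w, labels) == pytest.approx(
                brute_signed_modularity(w, labels, "gja"), abs=1e-10
            )

    def test_sta_objective_available(self, rng):
        w = rng.normal(size=(6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        est = D.SignedLouvain(objective="sta")
        labels = rng.integers(1, 3, 6)
        assert est.signed_modularity(w, labels) == pytest.approx(
            brute_signed_modularity(w, labels, "sta"), abs=1e-10
        )

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            D.run_method("LouvainGJA", np.zeros((5, 5)), seed=0)


class TestDegenerateStructures:
    def test_single_positive_block_collapses_to_one_community(self, rng):
        # no planted structure: label propagation and infomap return 1 community
        lam = rng.uniform(0.4, 0.9, 30)
        r = np.outer(lam, lam)
        np.fill_diagonal(r, 0.0)
        for name in ("LabelPropagation", "Infomap"):
            res = D.run_method(name, r, seed=2)
            assert res.n_communities == 1
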