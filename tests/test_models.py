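import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from connectropy import BinaryGraph
from connectropy.models import (
    ConfigurationModel,
    DegreeCorrectedSBM,
    ErdosRenyiModel,
    HyperbolicS1Model,
    ensemble_entropy,
)
from conftest import graph_from_edges, random_connected_graph


def planted_two_block(n_per_block=30, p_in=0.5, p_out=0.02, seed=42):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_block
    b = np.repeat([0, 1], n_per_block)
    P = np.where(b[:, None] == b[None, :], p_in, p_out)
    iu, ju = np.triu_indices(n, 1)
    A = np.zeros((n, n), int)
    e = rng.random(iu.size) < P[iu, ju]
    A[iu[e], ju[e]] = 1
    A[ju[e], iu[e]] = 1
    return BinaryGraph(A), b


class TestErdosRenyi:
    def test_preserves_counts(self):
        g = random_connected_graph(10, 0.45, np.random.default_rng(0))
        model = ErdosRenyiModel().fit(g)
        for s in model.sample(20, seed=1):
            assert s.n_nodes == g.n_nodes
            assert s.n_edges == g.n_edges

    def test_empty_graph_degenerate(self):
        g = BinaryGraph(np.zeros((5, 5), dtype=int))
        model = ErdosRenyiModel().fit(g)
        assert all(s.n_edges == 0 for s in model.sample(5, seed=0))

    def test_mean_degree(self):
        # N=10, M=20: mean degree is 2M/N = 4 in every realization
        g = graph_from_edges(10, [])
        model = ErdosRenyiModel()
        model.n_nodes_, model.n_edges_ = 10, 20
        degs = [s.degrees.mean() for s in model.sample(200, seed=2)]
        assert np.allclose(degs, 4.0)

    def test_seed_determinism(self):
        g = random_connected_graph(12, 0.3, np.random.default_rng(1))
        m = ErdosRenyiModel().fit(g)
        a = [s.A for s in m.sample(3, seed=9)]
        b = [s.A for s in m.sample(3, seed=9)]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestConfigurationModel:
    def test_star_is_unique_realization(self, star4):
        model = ConfigurationModel().fit(star4)
        for s in model.sample(50, seed=0):
            assert np.array_equal(s.A, star4.A)

    def test_degree_sequence_exact_and_simple(self):
        g = random_connected_graph(20, 0.25, np.random.default_rng(2))
        model = ConfigurationModel().fit(g)
        for s in model.sample(20, seed=3):
            assert np.array_equal(s.degrees, g.degrees)
            assert np.diagonal(s.A).sum() == 0
            assert s.A.max() <= 1

    def test_six_cycle_reaches_both_realizations(self):
        """Degree sequence (2,)*6 has two simple families: C6 and 2×C3.

        Both must appear, at frequencies consistent with an independent
        swap-chain oracle run with the same proposal kernel.
        """
        g = graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        model = ConfigurationModel().fit(g)
        n_samp = 1500
        mine = np.array(
            [s.is_connected() for s in model.sample(n_samp, seed=4)]
        )

        # independent oracle: same chain, separate implementation on sets
        rng = np.random.default_rng(99)
        oracle = []
        for _ in range(n_samp):
            edges = [(i, (i + 1) % 6) for i in range(6)]
            eset = {tuple(sorted(e)) for e in edges}
            for _ in range(10 * len(edges)):
                i1, i2 = rng.integers(0, len(edges), 2)
                if i1 == i2:
                    continue
                u, v = edges[i1]
                x, y = edges[i2]
                if rng.random() < 0.5:
                    x, y = y, x
                if u == x or v == y:
                    continue
                e1 = tuple(sorted((u, x)))
                e2 = tuple(sorted((v, y)))
                if e1 in eset or e2 in eset:
                    continue
                eset.discard(tuple(sorted((u, v))))
                eset.discard(tuple(sorted(edges[i2])))
                eset.update((e1, e2))
                edges[i1], edges[i2] = e1, e2
            A = np.zeros((6, 6), int)
            for a, b in eset:
                A[a, b] = A[b, a] = 1
            oracle.append(BinaryGraph(A).is_connected())
        oracle = np.array(oracle)
        assert 0 < mine.mean() < 1  # both families appear
        p_pool = (mine.mean() + oracle.mean()) / 2
        se = np.sqrt(2 * p_pool * (1 - p_pool) / n_samp)
        assert abs(mine.mean() - oracle.mean()) < 3 * se


class TestDegreeCorrectedSBM:
    def test_planted_partition_recovery(self):
        g, b = planted_two_block()
        model = DegreeCorrectedSBM(random_state=0).fit(g)
        assert adjusted_rand_score(b, model.block_assignment_) == 1.0

    def test_description_length_beats_singletons_and_one_block(self):
        g, b = planted_two_block(seed=7)
        model = DegreeCorrectedSBM(random_state=0).fit(g)
        A = g.A.astype(np.int64)
        M = g.n_edges
        k = g.degrees.astype(float)
        # DL of the all-in-one-block partition
        m1 = np.array([[2.0 * M]])
        dl_one = model._dl(m1, np.array([k.sum()]), g.n_nodes, M)
        assert model.description_length_ < dl_one

    def test_single_block_kernel_expected_degrees(self):
        g = random_connected_graph(30, 0.2, np.random.default_rng(3))
        model = DegreeCorrectedSBM(max_B=1, n_restarts=1, random_state=0)
        # force B = 1 by merging everything
        model.fit(g)
        model.block_assignment_ = np.zeros(g.n_nodes, dtype=int)
        model.n_blocks_ = 1
        model.edge_counts_ = np.array([[2.0 * g.n_edges]])
        model.block_degrees_ = np.array([float(g.degrees.sum())])
        omega = model.expected_multiplicity()
        # collapsed Bernoulli expectation per node
        exp_deg = (1 - np.exp(-omega)).sum(axis=1)
        samples = model.sample(400, seed=5)
        mean_deg = np.mean([s.degrees for s in samples], axis=0)
        se = np.sqrt(exp_deg / 400) + 1e-9
        assert (np.abs(mean_deg - exp_deg) < 4 * se + 0.1).all()

    def test_sampled_block_counts_match_kernel(self):
        g, b = planted_two_block(seed=5)
        model = DegreeCorrectedSBM(random_state=1).fit(g)
        bvec = model.block_assignment_
        B = model.n_blocks_
        omega = model.expected_multiplicity()
        onehot = np.zeros((g.n_nodes, B))
        onehot[np.arange(g.n_nodes), bvec] = 1.0
        expected = onehot.T @ (1 - np.exp(-omega)) @ onehot
        counts = np.zeros((B, B))
        n_draw = 300
        for s in model.sample(n_draw, seed=6):
            counts += onehot.T @ s.A @ onehot
        counts /= n_draw
        sd = np.sqrt(expected / n_draw) + 1e-9
        assert (np.abs(counts - expected) < 4 * sd + 0.5).all()
        # sparse inter-block counts also match the fitted e_rs directly
        inter_fit = model.edge_counts_[0, 1]
        assert abs(counts[0, 1] - inter_fit) < 4 * np.sqrt(inter_fit / n_draw) + 0.5

    def test_samples_are_simple(self):
        g, _ = planted_two_block(seed=9)
        model = DegreeCorrectedSBM(random_state=2).fit(g)
        for s in model.sample(5, seed=7):
            assert np.diagonal(s.A).sum() == 0
            assert s.A.max() <= 1


class TestHyperbolicS1:
    def _synthetic(self, n=120, mean_k=10.0, beta=2.5, seed=1):
        rng = np.random.default_rng(seed)
        kappa = mean_k * rng.uniform(0.5, 1.5, n)
        theta = rng.uniform(0, 2 * np.pi, n)
        model = HyperbolicS1Model.from_embedding(kappa, theta, beta, 1.0)
        chi = HyperbolicS1Model._chi(theta, kappa)
        model.mu_ = HyperbolicS1Model()._calibrate_mu(chi, beta, mean_k)
        return model, kappa, theta

    def test_beta_infinity_threshold_limit(self):
        model, kappa, theta = self._synthetic(n=40)
        model.beta_ = 1e6
        p = model.edge_probabilities()
        chi = HyperbolicS1Model._chi(theta, kappa)
        hard = (chi < model.mu_).astype(float)
        np.fill_diagonal(hard, 0)
        # far from the threshold the probability is exactly 0/1
        away = np.abs(chi - model.mu_) > 1e-3 * model.mu_
        assert np.abs(p[away] - hard[away]).max() < 1e-6

    def test_sampled_mean_degree_matches_input(self):
        model, _, _ = self._synthetic(n=100)
        g = model.sample(1, seed=3)[0]
        from connectropy.io import largest_component

        g = largest_component(g)
        fit = HyperbolicS1Model(random_state=0).fit(g)
        degs = [s.degrees.mean() for s in fit.sample(100, seed=4)]
        assert abs(np.mean(degs) - g.degrees.mean()) / g.degrees.mean() < 0.05

    def test_requires_connected(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            HyperbolicS1Model().fit(g)


class TestEnsembleEntropy:
    def test_single_subject_single_realization(self):
        g = random_connected_graph(15, 0.3, np.random.default_rng(0))
        model = ErdosRenyiModel().fit(g)
        taus = np.geomspace(0.1, 100, 10)
        ens = ensemble_entropy([model], 1, "crw", taus, seed=0)
        assert ens.samples.shape[0] == 1

    def test_pool_size_subjects_times_realizations(self):
        rng = np.random.default_rng(1)
        models = [
            ErdosRenyiModel().fit(random_connected_graph(15, 0.3, rng))
            for _ in range(3)
        ]
        ens = ensemble_entropy(models, 4, "crw", np.geomspace(0.1, 10, 5), 0)
        assert ens.samples.shape == (12, 5)

    def test_erm_cm_overlap_on_homogeneous_degrees(self):
        """On a near-regular graph ERM and CM ensembles nearly coincide."""
        g = graph_from_edges(16, [(i, (i + d) % 16) for i in range(16) for d in (1, 2)])
        taus = np.geomspace(0.5, 50, 8)
        er = ensemble_entropy([ErdosRenyiModel().fit(g)], 60, "crw", taus, 0)
        cm = ensemble_entropy([ConfigurationModel().fit(g)], 60, "crw", taus, 1)
        se = np.sqrt(er.sd**2 / 60 + cm.sd**2 / 60)
        assert (np.abs(er.mean - cm.mean) <= 2 * se + 0.05).all()

    def test_determinism(self):
        g = random_connected_graph(15, 0.3, np.random.default_rng(2))
        m = ErdosRenyiModel().fit(g)
        taus = np.geomspace(0.1, 10, 5)
        a = ensemble_entropy([m], 5, "crw", taus, seed=11)
        b = ensemble_entropy([m], 5, "crw", taus, seed=11)
        assert np.array_equal(a.samples, b.samples)


def test_sklearn_get_set_params_round_trip():
    model = DegreeCorrectedSBM(max_B=4, n_restarts=3, random_state=1)
    params = model.get_params()
    clone = DegreeCorrectedSBM().set_params(**params)
    assert clone.get_params() == params
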