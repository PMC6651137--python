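import numpy as np
import pytest
import scipy.stats

from netprop.diffusion import (
    DiffusionResult,
    composite_score,
    diffuse,
    diffuse_closed_form,
    normalize_columns,
    permutation_pvalues,
    score_genes,
    select_core_extension,
    top_neighbor_means,
)
from netprop.errors import ConvergenceError, ValidationError
from netprop.interactome import Interactome, normalize
from netprop.layers import build_matrix
from netprop.module_detection import rank_genes

from conftest import random_network


class TestDiffuse:
    def test_zero_seed_is_fixed_point(self, triangle):
        W = normalize(triangle)
        Xss = diffuse(W, np.zeros((3, 2)))
        assert np.all(Xss == 0)

    def test_two_node_closed_form_value(self):
        # (1-a)(I-aW)^-1 x0 on a single edge with x0=(1,0), a=0.7
        net = Interactome.from_edges([("a", "b", 900)])
        W = normalize(net)
        Xss = diffuse(W, np.array([[1.0], [0.0]]), alpha=0.7, tol=1e-9)
        assert Xss[:, 0] == pytest.approx([0.58824, 0.41176], abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_linear_solve_oracle(self, seed):
        net = random_network(30, 0.15, seed=seed)
        W = normalize(net).W.toarray()
        rng = np.random.default_rng(seed)
        X0 = rng.choice([0.0, 0.5, 1.0], size=(net.n_nodes, 3), p=[0.8, 0.1, 0.1])
        tol = 1e-8
        Xss = diffuse(W, X0, alpha=0.7, tol=tol)
        oracle = np.linalg.solve(np.eye(net.n_nodes) - 0.7 * W, 0.3 * X0)
        assert np.max(np.abs(Xss - oracle)) < tol * 10

    def test_non_convergence_error_carries_residual(self, triangle):
        W = normalize(triangle)
        with pytest.raises(ConvergenceError) as err:
            diffuse(W, np.array([[1.0], [0.0], [0.0]]), alpha=0.99,
                    tol=1e-14, max_iter=3)
        assert err.value.residual > 0

    def test_alpha_out_of_range_rejected(self, triangle):
        with pytest.raises(ValidationError):
            diffuse(normalize(triangle), np.ones((3, 1)), alpha=1.0)

    def test_linearity(self):
        net = random_network(20, 0.2, seed=4)
        W = normalize(net)
        rng = np.random.default_rng(4)
        A = rng.random((net.n_nodes, 2))
        B = rng.random((net.n_nodes, 2))
        lhs = diffuse_closed_form(W, 2.0 * A + 3.0 * B)
        rhs = 2.0 * diffuse_closed_form(W, A) + 3.0 * diffuse_closed_form(W, B)
        assert np.allclose(lhs, rhs)

    def test_monotonicity_in_seed(self):
        # raising one X0 entry never lowers any steady-state entry
        net = random_network(15, 0.25, seed=5)
        W = normalize(net)
        X0 = np.zeros((net.n_nodes, 1))
        base = diffuse_closed_form(W, X0)
        X0[7, 0] = 1.0
        bumped = diffuse_closed_form(W, X0)
        assert np.all(bumped >= base - 1e-12)


class TestClosedForm:
    def test_isolated_node_keeps_seed_fraction(self):
        net = Interactome.from_edges([("a", "b", 900)], extra_nodes=["z"])
        W = normalize(net)
        X0 = np.zeros((3, 1))
        X0[net.index["z"], 0] = 1.0
        Xss = diffuse_closed_form(W, X0, alpha=0.7)
        assert Xss[net.index["z"], 0] == pytest.approx(0.3)

    def test_symmetric_seed_gives_symmetric_result(self, star_graph):
        W = normalize(star_graph)
        X0 = np.zeros((4, 1))
        for leaf in ("x", "y", "z"):
            X0[star_graph.index[leaf], 0] = 1.0
        Xss = diffuse_closed_form(W, X0)
        leaves = [star_graph.index[l] for l in ("x", "y", "z")]
        assert np.allclose(Xss[leaves, 0], Xss[leaves[0], 0])

    @pytest.mark.parametrize("seed", [6, 7])
    def test_agrees_with_iterative(self, seed):
        net = random_network(30, 0.15, seed=seed)
        W = normalize(net)
        X0 = np.random.default_rng(seed).random((net.n_nodes, 3))
        assert np.allclose(
            diffuse_closed_form(W, X0), diffuse(W, X0, tol=1e-10), atol=1e-8
        )


class TestNormalizeColumns:
    def test_divides_by_column_max(self):
        X = np.array([[2.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        out = normalize_columns(X)
        assert out[:, 0].tolist() == [1.0, 0.5, 0.0]

    def test_zero_column_unchanged(self):
        out = normalize_columns(np.zeros((3, 2)))
        assert np.all(out == 0)

    def test_nonzero_columns_peak_at_one(self):
        X = np.random.default_rng(0).random((10, 3))
        assert np.allclose(normalize_columns(X).max(axis=0), 1.0)


class TestTopNeighborMeans:
    def net_with_scores(self):
        # hub c with neighbors a,b,d,e
        net = Interactome.from_edges(
            [("c", "a", 900), ("c", "b", 900), ("c", "d", 900), ("c", "e", 900)],
            extra_nodes=["iso"],
        )
        scores = {"a": 0.9, "b": 0.5, "d": 0.1, "e": 0.05, "c": 0.7, "iso": 1.0}
        X = np.array([[scores[g]] for g in net.nodes])
        return net, X

    def test_mean_of_top_three(self):
        net, X = self.net_with_scores()
        Y = top_neighbor_means(net, X, m=3)
        assert Y[net.index["c"], 0] == pytest.approx((0.9 + 0.5 + 0.1) / 3)

    def test_fewer_than_m_neighbors_averages_all(self):
        net, X = self.net_with_scores()
        Y = top_neighbor_means(net, X, m=3)
        # leaf 'a' has only neighbor c with score 0.7
        assert Y[net.index["a"], 0] == pytest.approx(0.7)

    def test_isolated_gene_scores_zero(self):
        net, X = self.net_with_scores()
        Y = top_neighbor_means(net, X, m=3)
        assert Y[net.index["iso"], 0] == 0.0

    def test_gene_not_its_own_neighbor(self):
        net, X = self.net_with_scores()
        # even with a huge own score, c's term uses only a,b,d,e
        X[net.index["c"], 0] = 100.0
        Y = top_neighbor_means(net, X, m=3)
        assert Y[net.index["c"], 0] == pytest.approx((0.9 + 0.5 + 0.1) / 3)


class TestCompositeScore:
    def test_product_of_sums(self):
        x = np.array([[1.0, 0.5, 0.0]])
        y = np.array([[0.2, 0.1, 0.3]])
        assert composite_score(x, y)[0] == pytest.approx(0.9)

    def test_isolated_seeded_gene_scores_zero(self):
        net = Interactome.from_edges([("a", "b", 900)], extra_nodes=["z"])
        W = normalize(net)
        X0 = np.zeros((3, 1))
        X0[net.index["z"], 0] = 1.0
        res = score_genes(net, W, X0)
        assert res.d[net.index["z"]] == 0.0

    def test_zero_rows_score_zero(self):
        assert composite_score(np.zeros((2, 3)), np.ones((2, 3))).tolist() == [0, 0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            composite_score(np.zeros((2, 3)), np.zeros((3, 2)))


class TestPermutationPvalues:
    def test_identical_rows_give_p_one(self):
        net = random_network(12, 0.3, seed=8)
        W = normalize(net)
        X0 = np.full((net.n_nodes, 2), 0.5)
        p = permutation_pvalues(W, net, X0, n_perm=20, seed=1)
        assert np.all(p == 1.0)

    def test_add_one_lower_bound(self, default_dataset):
        net, layers, truth = default_dataset
        X0 = build_matrix(layers, net)
        p = permutation_pvalues(normalize(net), net, X0, n_perm=49, seed=2)
        assert p.min() >= 1 / 50
        assert np.all(p <= 1.0)

    def test_seed_required(self, triangle):
        with pytest.raises(ValidationError, match="seed"):
            permutation_pvalues(normalize(triangle), triangle, np.ones((3, 1)), n_perm=5)

    def test_null_pvalues_approximately_uniform(self):
        # random seeds carry no network signal: p ~ U(0,1); p-values
        # within one run share permutations, so pool independent
        # replicate datasets for a stable KS estimate
        pool = []
        for seed in range(6):
            net = random_network(200, 0.05, seed=seed)
            X0 = np.random.default_rng(seed).random((net.n_nodes, 3))
            pool.append(
                permutation_pvalues(
                    normalize(net), net, X0, n_perm=100, seed=seed + 50
                )
            )
        ks = scipy.stats.kstest(np.concatenate(pool), "uniform").statistic
        assert ks < 0.1

    def test_invariant_to_input_edge_order(self):
        # node indexing is canonical (sorted labels), so the edge-list
        # order of the input cannot change any p-value
        net = random_network(15, 0.3, seed=10)
        W = normalize(net)
        X0 = np.random.default_rng(10).random((net.n_nodes, 2))
        p1 = permutation_pvalues(W, net, X0, n_perm=30, seed=4)
        shuffled = list(net.scores.items())
        np.random.default_rng(11).shuffle(shuffled)
        net2 = Interactome.from_edges((a, b, s) for (a, b), s in shuffled)
        assert net2.nodes == net.nodes
        p2 = permutation_pvalues(normalize(net2), net2, X0, n_perm=30, seed=4)
        assert np.array_equal(p1, p2)


class TestSelectCoreExtension:
    def make_result(self, genes, scores, pvals):
        n = len(genes)
        return DiffusionResult(
            genes=tuple(genes), layer_names=("G",),
            Xss=np.array(scores)[:, None], Xstar=np.zeros((n, 1)),
            Y=np.zeros((n, 1)), d=np.array(scores, dtype=float),
            alpha=0.7, iterations=1, residual=0.0,
            p=np.array(pvals), statistic="d",
        )

    def test_core_genes_never_selected(self):
        # b and c beat the core minimum but a itself is excluded
        res = self.make_result(["a", "b", "c"], [0.8, 0.9, 1.0], [0.01] * 3)
        out = select_core_extension(res, core={"a"})
        assert "a" not in out and out == {"b", "c"}

    def test_no_significant_gene_gives_empty_set(self):
        res = self.make_result(["a", "b"], [1.0, 2.0], [0.5, 0.5])
        assert select_core_extension(res, core={"a"}) == set()

    def test_score_comparability_rule(self):
        res = self.make_result(
            ["core1", "core2", "hi", "lo"], [0.8, 0.6, 0.7, 0.1], [0.01] * 4
        )
        assert select_core_extension(res, core={"core1", "core2"}) == {"hi"}

    def test_empty_core_rejected(self):
        res = self.make_result(["a"], [1.0], [0.01])
        with pytest.raises(ValidationError):
            select_core_extension(res, core=set())

    def test_planted_recovery_precision(self, default_dataset):
        # single-layer analysis: a "core" list mixing module genes with
        # scattered background genes (weakly connected, so the core
        # minimum is attainable) plus peripheral evidence at 0.5;
        # selected genes should be planted-module members
        net, layers, truth = default_dataset
        planted = set(truth["planted"])
        rng = np.random.default_rng(12)
        core = set(rng.choice(sorted(planted), size=30, replace=False))
        background = sorted(set(net.nodes) - planted)
        core |= set(rng.choice(background, size=20, replace=False))
        minor = (planted | set(rng.choice(background, size=30, replace=False))) - core
        X0 = np.zeros((net.n_nodes, 1))
        for g in core:
            X0[net.index[g], 0] = 1.0
        for g in minor:
            X0[net.index[g], 0] = 0.5
        res = score_genes(
            net, normalize(net), X0, n_perm=199, seed=5, statistic="xss"
        )
        out = select_core_extension(res, core=core)
        assert out
        precision = len(out & planted) / len(out)
        assert precision >= 0.8
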