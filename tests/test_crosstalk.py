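import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dynreg import crosstalk as xt
from dynreg import synthetic as synth


def _toy_network(nodes, edges, node_p=None, edge_scores=None):
    node_p = node_p if node_p is not None else np.full(len(nodes), 0.5)
    idx = {g: i for i, g in enumerate(nodes)}
    u = np.array([idx[a] for a, _ in edges], dtype=int)
    v = np.array([idx[b] for _, b in edges], dtype=int)
    edge_p = np.full(len(edges), 0.5)
    net = xt.WeightedPPINetwork(
        nodes=list(nodes), node_p=np.asarray(node_p, dtype=float),
        edges_u=u, edges_v=v, edge_p=edge_p,
        edge_scores=np.zeros(len(edges)),
    )
    net.edge_scores = (np.asarray(edge_scores, dtype=float)
                       if edge_scores is not None else net.recompute_scores())
    return net


class TestEdgeScore:
    def test_unit_pvalues_score_zero(self):
        assert xt.edge_score(1.0, 1.0, 1.0) == 0.0

    def test_fisher_closed_form(self):
        assert xt.edge_score(0.05, 0.05, 0.05) == pytest.approx(-6 * np.log(0.05),
                                                                abs=1e-12)

    def test_zero_pvalue_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            s = xt.edge_score(0.0, 0.5, 0.5)
        assert np.isfinite(s) and s > 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            xt.edge_score(1.5, 0.5, 0.5)

    @given(st.tuples(*[st.floats(1e-12, 1.0) for _ in range(3)]),
           st.integers(0, 2), st.floats(0.01, 0.99))
    def test_strictly_decreasing_in_each_argument(self, ps, which, shrink):
        """Multiplying any one p-value by a factor < 1 strictly increases S."""
        base = xt.edge_score(*ps)
        smaller = list(ps)
        smaller[which] = smaller[which] * shrink
        assert xt.edge_score(*smaller) > base

    def test_monotone_over_many_random_triples(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            ps = rng.uniform(1e-8, 1.0, size=3)
            which = rng.integers(3)
            smaller = ps.copy()
            smaller[which] *= rng.uniform(0.05, 0.95)
            assert xt.edge_score(*smaller) > xt.edge_score(*ps)


class TestWeightNetwork:
    def test_perfectly_correlated_pair_tiny_pvalue(self):
        truth = synth.generate_truth(n_genes=10, n_tfs=3, targets_per_tf=3, seed=1)
        ds = synth.generate_expression(truth, noise_sd=0.0, seed=2)
        # noiseless: any two co-regulated genes are perfectly correlated
        shared = sorted(truth.prior.targets_of(truth.tfs[0]))[:2]
        net = xt.weight_network({(shared[0], shared[1])}, ds, stage=4.0)
        assert net.edge_p[0] < 1e-6

    def test_pearson_test_matches_t_transform(self):
        """p for r over n=6 samples equals the closed-form t transform."""
        r = 0.5
        n = 6
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t), n - 2)
        xu = np.array([[0.0, 1.0, 2.0, 3.0, 4.0, 5.0]])
        # construct a partner series with exactly r = 0.5 against xu
        base = xu[0] - xu[0].mean()
        orth = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        orth -= orth @ base / (base @ base) * base
        y = r * base / np.linalg.norm(base) + np.sqrt(1 - r**2) * orth / np.linalg.norm(orth)
        p = xt._pearson_test_p(xu, y[None, :], n)
        assert p[0] == pytest.approx(expected, rel=1e-10)

    def test_constant_gene_edges_get_unit_p(self):
        truth = synth.generate_truth(n_genes=10, n_tfs=3, targets_per_tf=3, seed=1)
        ds = synth.generate_expression(truth, noise_sd=0.1, seed=2)
        ds.values[0, :] = 5.0  # make one gene constant
        edge = (ds.genes[0], ds.genes[1])
        with pytest.warns(UserWarning, match="constant"):
            net = xt.weight_network({edge}, ds, stage=4.0)
        assert net.edge_p[0] == 1.0

    def test_unmeasured_edges_dropped(self):
        truth = synth.generate_truth(n_genes=10, n_tfs=3, targets_per_tf=3, seed=1)
        ds = synth.generate_expression(truth, noise_sd=0.1, seed=2)
        edges = {(ds.genes[0], ds.genes[1]), ("ghost1", "ghost2")}
        net = xt.weight_network(edges, ds, stage=4.0)
        assert net.n_edges == 1


class TestOverlapScore:
    def test_disjoint_pathways_no_edges(self):
        net = _toy_network(["a", "b", "c", "d"], [("a", "b")])
        idx, c = xt.overlap_score({"c"}, {"d"}, net)
        assert idx == [] and c == 0.0

    def test_single_qualifying_edge(self):
        net = _toy_network(["a", "b", "c"], [("a", "b"), ("b", "c")],
                           edge_scores=[10.0, 7.0])
        idx, c = xt.overlap_score({"a"}, {"b"}, net)
        assert idx == [0] and c == 10.0

    def test_matches_exhaustive_edge_scan(self):
        rng = np.random.default_rng(23)
        nodes = [f"n{i}" for i in range(30)]
        pairs = {tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(60)}
        edges = sorted(pairs)
        scores = rng.uniform(0, 5, size=len(edges))
        net = _toy_network(nodes, edges, edge_scores=scores)
        pi = set(rng.choice(nodes, 8, replace=False))
        pj = set(rng.choice(nodes, 8, replace=False))  # may intersect pi
        idx, c = xt.overlap_score(pi, pj, net)
        expected = sum(
            s for (a, b), s in zip(edges, scores)
            if (a in pi and b in pj) or (a in pj and b in pi)
        )
        assert c == pytest.approx(expected, abs=1e-12)
        # intersection edges count once
        assert len(idx) == len(set(idx))

    def test_symmetric_in_pathway_order(self):
        rng = np.random.default_rng(29)
        nodes = [f"n{i}" for i in range(20)]
        edges = sorted({tuple(sorted(rng.choice(nodes, 2, replace=False)))
                        for _ in range(40)})
        net = _toy_network(nodes, edges)
        pi = set(rng.choice(nodes, 6, replace=False))
        pj = set(rng.choice(nodes, 6, replace=False))
        _, c1 = xt.overlap_score(pi, pj, net)
        _, c2 = xt.overlap_score(pj, pi, net)
        assert c1 == c2


class TestPermutationPvalue:
    def test_zero_observed_score_short_circuits(self):
        net = _toy_network(["a", "b", "c", "d"], [("a", "b")])
        res = xt.permutation_pvalue({"c"}, {"d"}, net, B=100, seed=1)
        assert res.p_value == 1.0 and res.empty_overlap

    def test_add_one_estimator_floor(self):
        """An observed score no random draw reaches gives p = 1/(B+1)."""
        nodes = [f"n{i}" for i in range(200)]
        edges = [("n0", "n1")]
        net = _toy_network(nodes, edges, edge_scores=[50.0])
        res = xt.permutation_pvalue({"n0"}, {"n1"}, net, B=999, seed=3)
        # singleton sets: a random draw ties only by picking exactly these two
        # nodes (prob ~ 2/200^2 per draw); absent under this seed
        assert res.p_value == pytest.approx(1 / 1000)

    def test_pvalue_never_zero_and_reproducible(self):
        rng = np.random.default_rng(31)
        nodes = [f"n{i}" for i in range(50)]
        edges = sorted({tuple(sorted(rng.choice(nodes, 2, replace=False)))
                        for _ in range(120)})
        net = _toy_network(nodes, edges)
        pi = set(rng.choice(nodes, 10, replace=False))
        pj = set(rng.choice(nodes, 10, replace=False))
        r1 = xt.permutation_pvalue(pi, pj, net, B=500, seed=7)
        r2 = xt.permutation_pvalue(pi, pj, net, B=500, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 501
        assert 0 < r1.p_value <= 1

    def test_planted_boost_detected(self):
        edges, pathways, planted = synth.generate_ppi_pathways(
            n_genes=600, n_pathways=20, pathway_size=25, n_planted_pairs=2,
            cross_edge_boost=20.0, seed=17, base_edge_prob=0.002,
            disjoint_pathways=True,
        )
        truth = synth.generate_truth(n_genes=600, n_tfs=20, targets_per_tf=8,
                                     amplitude=0.0, seed=8)
        ds = synth.generate_expression(truth, noise_sd=0.1, seed=9)
        net = xt.weight_network(edges, ds, stage=4.0)
        universe = set().union(*pathways.pathways.values())
        for a, b in planted:
            res = xt.permutation_pvalue(pathways.pathways[a], pathways.pathways[b],
                                        net, B=2000, seed=5, universe=universe)
            assert res.p_value <= 0.01


class TestCrosstalkDynamics:
    def test_stage_table_shape_and_flags(self):
        edges, pathways, _ = synth.generate_ppi_pathways(
            n_genes=150, n_pathways=4, pathway_size=20, n_planted_pairs=1,
            cross_edge_boost=15.0, seed=3, base_edge_prob=0.01,
        )
        truth = synth.generate_truth(n_genes=150, n_tfs=10, targets_per_tf=5, seed=4)
        ds = synth.generate_expression(truth, noise_sd=0.1, seed=5)
        names = sorted(pathways.pathways)
        pairs = [(names[0], names[1]), (names[2], names[3])]
        table = xt.crosstalk_dynamics(pairs, pathways, edges, ds, B=200, seed=11)
        assert len(table) == len(pairs) * 3
        assert set(table["stage"]) == {4.0, 12.0, 24.0}
        assert ((table["p"] < 0.1) == table["significant"]).all()

    def test_deterministic_and_pair_order_invariant(self):
        edges, pathways, _ = synth.generate_ppi_pathways(
            n_genes=150, n_pathways=4, pathway_size=20, seed=3, base_edge_prob=0.01,
        )
        truth = synth.generate_truth(n_genes=150, n_tfs=10, targets_per_tf=5, seed=4)
        ds = synth.generate_expression(truth, noise_sd=0.1, seed=5)
        names = sorted(pathways.pathways)
        pairs = [(names[0], names[1]), (names[2], names[3])]
        t1 = xt.crosstalk_dynamics(pairs, pathways, edges, ds, B=200, seed=11)
        t2 = xt.crosstalk_dynamics(pairs[::-1], pathways, edges, ds, B=200, seed=11)
        key = ["pathway_i", "pathway_j", "stage"]
        m1 = t1.set_index(key)["p"].sort_index()
        m2 = t2.set_index(key)["p"].sort_index()
        assert (m1 == m2).all()

    def test_missing_stage_errors(self):
        edges, pathways, _ = synth.generate_ppi_pathways(
            n_genes=100, n_pathways=3, pathway_size=15, seed=3, base_edge_prob=0.01,
        )
        truth = synth.generate_truth(n_genes=100, n_tfs=6, targets_per_tf=4, seed=4)
        ds = synth.generate_expression(truth, noise_sd=0.1, seed=5)
        names = sorted(pathways.pathways)
        with pytest.raises(ValueError, match="missing"):
            xt.crosstalk_dynamics([(names[0], names[1])], pathways, edges, ds,
                                  B=50, seed=1, stages=[99.0])
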