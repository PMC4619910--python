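"""Pearson all-pairs, correlation p-values, adjustment, network building."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from coexmir.expression import ExpressionMatrix
from coexmir.network import (
    CoexpressionNetwork,
    adjust_pvalues,
    build_network,
    compare_networks,
    coexpression_network,
    correlation_pvalue,
    edge_density,
    network_stats,
    pearson_all_pairs,
)
from coexmir.simulate import SimulationConfig, simulate_expression


def _matrix(values, n_per_group=3):
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    samples = [f"null_{i}" for i in range(n_per_group)] + [
        f"mir142_{i}" for i in range(n_per_group)
    ]
    conds = {s: ("null" if s.startswith("null") else "mir142") for s in samples}
    return ExpressionMatrix.from_arrays(values, [f"g{i}" for i in range(n_genes)], samples, conds)


class TestPearsonAllPairs:
    def test_collinear_and_anticollinear(self):
        m = _matrix([[1, 2, 3, 0, 0, 1], [2, 4, 6, 0, 1, 0], [3, 2, 1, 1, 0, 0]])
        pairs = pearson_all_pairs(m, "null").set_index(["gene_a", "gene_b"])["r"]
        assert pairs[("g0", "g1")] == pytest.approx(1.0)
        assert pairs[("g0", "g2")] == pytest.approx(-1.0)

    def test_direct_covariance_example(self):
        # r((1,2,4),(1,3,4)) = cov/sd_x/sd_y = 13/14
        m = _matrix([[1, 2, 4, 0, 1, 0], [1, 3, 4, 1, 0, 0]])
        pairs = pearson_all_pairs(m, "null")
        assert pairs["r"].iloc[0] == pytest.approx(13 / 14)

    def test_zero_variance_genes_dropped(self):
        m = _matrix([[1, 1, 1, 0, 1, 0], [1, 2, 3, 1, 0, 0], [4, 5, 9, 0, 0, 1]])
        pairs = pearson_all_pairs(m, "null")
        assert set(pairs["gene_a"]) | set(pairs["gene_b"]) == {"g1", "g2"}
        assert len(pairs) == 1

    def test_pair_count_is_g_choose_2(self, rng):
        m = _matrix(rng.normal(size=(50, 6)))
        assert len(pearson_all_pairs(m, "mir142")) == 50 * 49 // 2

    def test_agrees_with_per_pair_loop_oracle(self, rng):
        values = rng.normal(size=(50, 6))
        m = _matrix(values)
        pairs = pearson_all_pairs(m, "null").set_index(["gene_a", "gene_b"])["r"]
        sub = values[:, :3]
        for i in range(50):
            for j in range(i + 1, 50):
                expected = sps.pearsonr(sub[i], sub[j])[0]
                key = tuple(sorted((f"g{i}", f"g{j}")))  # pairs are lexicographic
                assert pairs[key] == pytest.approx(expected, abs=1e-12)


class TestCorrelationPvalue:
    def test_null_value(self):
        assert correlation_pvalue(0.0, 3) == pytest.approx(1.0)
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_df1_closed_form(self):
        # for n=3 (df=1): p = 1 - (2/pi) * arctan(|t|)
        r = 0.9998
        t = r * math.sqrt(1 / (1 - r * r))
        expected = 1 - (2 / math.pi) * math.atan(t)
        assert correlation_pvalue(r, 3) == pytest.approx(expected, rel=1e-10)
        assert correlation_pvalue(r, 3) == pytest.approx(0.012732, abs=1e-6)

    def test_perfect_correlation_convention(self):
        assert correlation_pvalue(1.0, 3) == 0.0
        assert correlation_pvalue(-1.0, 5) == 0.0

    def test_strictly_decreasing_in_abs_r(self):
        rs = np.linspace(0.01, 0.99, 50)
        ps = correlation_pvalue(rs, 5)
        assert np.all(np.diff(ps) < 0)

    def test_rejects_small_n(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 2)


class TestAdjustPvalues:
    def test_single_p_unchanged_any_method(self):
        for method in ("bonferroni", "holm", "hochberg", "bh"):
            assert adjust_pvalues([0.05], method)[0] == pytest.approx(0.05)

    def test_bonferroni_caps_at_one(self):
        assert adjust_pvalues([0.5, 0.6, 0.7], "bonferroni")[0] == 1.0

    def test_bh_step_up_example(self):
        # min over tail of p*m/rank: all three collapse to 0.03
        out = adjust_pvalues([0.01, 0.02, 0.03], "bh")
        assert out == pytest.approx([0.03, 0.03, 0.03])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_method_ordering_invariants(self, pvals):
        raw = np.asarray(pvals)
        bh = adjust_pvalues(raw, "bh")
        holm = adjust_pvalues(raw, "holm")
        bonf = adjust_pvalues(raw, "bonferroni")
        assert np.all(bh >= raw - 1e-12)
        assert np.all(holm >= bh - 1e-12)
        assert np.all(bonf >= holm - 1e-12)
        for adjusted in (bh, holm, bonf):
            assert np.all(adjusted <= 1.0 + 1e-12)


class TestBuildNetwork:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])

    def test_negative_correlation_excluded_in_both_modes(self):
        pairs = self._pairs([("a", "b", -0.9999)])
        pairs["p_adj"] = [1e-9]
        for kwargs in ({"mode": "r-threshold", "r_min": -1.0}, {"mode": "adjusted-p", "alpha": 0.5}):
            net = build_network(pairs, "null", **kwargs)
            assert net.graph.number_of_edges() == 0

    def test_empty_retained_set_gives_empty_network(self):
        net = build_network(self._pairs([("a", "b", 0.5)]), "null", r_min=0.9998)
        stats = network_stats(net)
        assert (stats.n_nodes, stats.n_edges, stats.density) == (0, 0, 0.0)
        assert stats.degenerate
        assert net.r_min_retained is None

    def test_r_threshold_monotone_in_r_min(self, rng):
        pairs = self._pairs(
            [(f"a{i}", f"b{i}", r) for i, r in enumerate(rng.uniform(-1, 1, 200))]
        )
        previous = None
        for r_min in (0.0, 0.5, 0.9, 0.9998):
            net = build_network(pairs, "null", r_min=r_min)
            if previous is not None:
                assert net.nodes <= previous.nodes
                assert net.edges <= previous.edges
            previous = net

    def test_r_min_retained_reported(self):
        pairs = self._pairs([("a", "b", 0.9999), ("c", "d", 0.99985)])
        net = build_network(pairs, "null", r_min=0.9998)
        assert net.r_min_retained == pytest.approx(0.99985)

    def test_zero_noise_clique_recovered_exactly(self):
        """A planted zero-noise 5-clique is the entire r>=0.9998 network."""
        config = SimulationConfig(
            n_genes=5, modules_null=(5,), modules_mir142=(), n_de_genes=0,
            clique_noise_sd=0.0, background_sd=0.5, utr_length_range=(50, 60),
            rng_seed=0,
        )
        matrix, truth = simulate_expression(config)
        net = coexpression_network(matrix, "null")
        clique = truth.cliques["null"][0]
        assert net.nodes == set(clique)
        assert len(net.edges) == 10
        for _, _, data in net.graph.edges(data=True):
            assert data["r"] == pytest.approx(1.0, abs=1e-9)


class TestNetworkStats:
    @pytest.mark.parametrize("n,e,density", [(57, 217, 0.136), (52, 158, 0.119)])
    def test_published_network_densities(self, n, e, density):
        assert round(edge_density(n, e), 3) == density

    def test_complete_graph_density_one(self):
        import networkx as nx

        net = CoexpressionNetwork("x", nx.complete_graph(4), 1.0)
        assert network_stats(net).density == pytest.approx(1.0)


class TestCompareNetworks:
    def _net(self, edges, condition="x"):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(edges)
        return CoexpressionNetwork(condition, g, 1.0)

    def test_identity(self):
        net = self._net([("a", "b"), ("b", "c")])
        report = compare_networks(net, net)
        assert report["node_jaccard"] == report["edge_jaccard"] == 1.0

    def test_containment_arithmetic(self):
        small = self._net([("a", "b")])
        big = self._net([("a", "b"), ("c", "d")])
        report = compare_networks(small, big)
        assert report["node_jaccard"] == pytest.approx(0.5)
        assert report["edge_jaccard"] == pytest.approx(0.5)

    def test_symmetric(self):
        a = self._net([("a", "b")])
        b = self._net([("b", "c")])
        fwd, rev = compare_networks(a, b), compare_networks(b, a)
        assert fwd == rev
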