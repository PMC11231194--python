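"""Multi-objective scoring, quantile pruning, centrality baselines, comparison."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ctpflow import (
    build_ctp,
    centrality_scores,
    compare_models,
    objectives,
    optimize_centrality,
    optimize_moo,
    screen,
    simple_de,
)


def _path_net():
    # PPI path A - B - C over three targets
    return build_ctp(
        ["c1", "c2", "c3"],
        [("c1", "A"), ("c2", "B"), ("c3", "C")],
        ["Z"],
        [("A", "B"), ("B", "C")],
    )


def _brute_betweenness(edges, nodes):
    """Fraction of shortest paths through each node, enumerated by hand."""
    g = nx.Graph(edges)
    g.add_nodes_from(nodes)
    out = {v: 0.0 for v in nodes}
    pairs = list(combinations(sorted(nodes), 2))
    for s, t in pairs:
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            out[v] += sum(1 for p in paths if v in p) / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2
    return {v: x / norm for v, x in out.items()}


class TestObjectives:
    def test_minmax_endpoints_for_ct_degree(self):
        net = build_ctp(
            [f"c{i}" for i in range(1, 7)],
            [("c1", "A")] + [(f"c{i}", "B") for i in range(1, 6)],
            ["Z"], [],
        )
        obj = objectives(net)
        assert obj.loc["A", "o_compound"] == 0.0
        assert obj.loc["B", "o_compound"] == 1.0

    def test_gene_absent_from_de_has_zero_dysregulation(self):
        net = build_ctp(["c1", "c2"], [("c1", "A"), ("c2", "B")], ["Z"], [])
        de = pd.DataFrame({"logfc": [2.0], "fdr": [0.01]},
                          index=pd.Index(["A"], name="gene"))
        obj = objectives(net, de)
        assert obj.loc["B", "o_dysreg"] == 0.0
        assert obj.loc["A", "o_dysreg"] == 1.0

    def test_constant_objective_maps_to_zeros(self):
        net = build_ctp(["c1", "c2"], [("c1", "A"), ("c2", "B")], ["Z"], [])
        obj = objectives(net)
        assert (obj["o_pathogenic"] == 0.0).all()

    def test_ecp_bonus_in_pathogenic_objective(self):
        net = build_ctp(["c1", "c2"], [("c1", "A"), ("c2", "B")], ["B", "P"],
                        [("A", "P")])
        obj = objectives(net)
        # A: 1 pathogenic neighbor; B: ECP bonus 1 -> equal raw, both map together
        assert obj.loc["A", "o_pathogenic"] == obj.loc["B", "o_pathogenic"]


class TestPruning:
    def test_identity_at_keep_quantile_one(self):
        net = _path_net()
        opt = optimize_moo(net, keep_quantile=1.0)
        assert opt.network.targets == net.targets
        assert set(opt.network.ct_edges) == set(net.ct_edges)
        assert set(opt.scores) == net.targets

    def test_quantile_retains_top_half_of_four(self):
        net = build_ctp(
            ["c1"], [("c1", t) for t in "ABCD"], ["Z"], [],
        )
        obj = pd.DataFrame(
            {"o_compound": [0.1, 0.2, 0.8, 0.9],
             "o_pathogenic": [0.1, 0.2, 0.8, 0.9],
             "o_dysreg": [0.1, 0.2, 0.8, 0.9]},
            index=["A", "B", "C", "D"],
        )
        opt = optimize_moo(net, obj=obj, keep_quantile=0.5)
        assert opt.network.targets == {"C", "D"}

    def test_scores_within_unit_interval(self, bundle):
        rep = screen(bundle.compounds)
        net = build_ctp(rep.passed, bundle.ct_edges, bundle.pathogenic, bundle.ppi)
        de = simple_de(bundle.expression)
        opt = optimize_moo(net, de=de, keep_quantile=0.5)
        vals = np.array(list(opt.scores.values()))
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_pruning_monotone_in_keep_quantile(self, bundle):
        rep = screen(bundle.compounds)
        net = build_ctp(rep.passed, bundle.ct_edges, bundle.pathogenic, bundle.ppi)
        kept = [optimize_moo(net, keep_quantile=q).network.targets
                for q in (0.2, 0.5, 0.9)]
        assert kept[0] <= kept[1] <= kept[2]

    def test_pp_edges_need_a_retained_target_or_ecp_endpoint(self, bundle):
        rep = screen(bundle.compounds)
        net = build_ctp(rep.passed, bundle.ct_edges, bundle.pathogenic, bundle.ppi)
        opt = optimize_moo(net, keep_quantile=0.3)
        retained, ecp = opt.network.targets, net.ecp
        for a, b in opt.network.pp_edges:
            assert {a, b} <= retained | net.pathogenic
            assert a in retained or b in retained or a in ecp or b in ecp

    def test_zero_dysreg_uniform_ct_degree_reduces_to_pathogenic_ranking(self):
        net = build_ctp(
            ["c1", "c2", "c3", "c4"],
            [("c1", "T1"), ("c2", "T2"), ("c3", "T3"), ("c4", "T4")],
            ["P1", "P2", "P3"],
            [("T1", "P1"), ("T1", "P2"), ("T1", "P3"),
             ("T2", "P1"), ("T2", "P2"), ("T3", "P1")],
        )
        opt = optimize_moo(net, weights=(1.0, 1.0, 0.0), keep_quantile=1.0)
        order = sorted(opt.scores, key=opt.scores.get, reverse=True)
        assert order == ["T1", "T2", "T3", "T4"]


class TestCentrality:
    def test_degree_ranks_path_middle_highest(self):
        s = centrality_scores(_path_net(), "degree")
        assert s.idxmax() == "B"

    def test_betweenness_matches_brute_force_enumeration(self):
        net = _path_net()
        oracle = _brute_betweenness(net.pp_edges, net.proteins)
        assert oracle["B"] == pytest.approx(1 / 3)  # 1 of 3 node pairs, n=4 layer
        g = nx.Graph(); g.add_nodes_from(net.proteins); g.add_edges_from(net.pp_edges)
        raw = nx.betweenness_centrality(g, normalized=True)
        for v in net.proteins:
            assert raw[v] == pytest.approx(oracle[v])
        s = centrality_scores(net, "betweenness")
        assert s.idxmax() == "B" and s["B"] == 1.0

    def test_isolated_nodes_score_zero_closeness(self):
        net = build_ctp(["c1", "c2"], [("c1", "A"), ("c2", "B")], ["Z"],
                        [("A", "B")])
        s = centrality_scores(net, "closeness")
        # Z is isolated; A and B tie, so min-max sends the isolated node to 0
        g = nx.Graph(); g.add_nodes_from(net.proteins); g.add_edges_from(net.pp_edges)
        assert nx.closeness_centrality(g)["Z"] == 0.0


@pytest.fixture(scope="module")
def setup(bundle):
    rep = screen(bundle.compounds)
    net = build_ctp(rep.passed, bundle.ct_edges, bundle.pathogenic, bundle.ppi)
    de = simple_de(bundle.expression)
    opts = [optimize_moo(net, de=de)] + [
        optimize_centrality(net, m) for m in ("degree", "closeness", "betweenness")
    ]
    return net, de, opts


class TestCompareModels:
    def test_permutation_invariant_to_model_order(self, setup, bundle):
        net, de, opts = setup
        a = compare_models(opts, net.ecp, de=de, pathways=bundle.pathways)
        b = compare_models(opts[::-1], net.ecp, de=de, pathways=bundle.pathways)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_retained_sets_give_identical_rows(self, setup, bundle):
        net, de, opts = setup
        moo = opts[0]
        clone = type(moo)(network=moo.network, scores=moo.scores, model="clone")
        rep = compare_models([moo, clone], net.ecp, de=de, pathways=bundle.pathways)
        assert rep.loc["moo"].equals(rep.loc["clone"])

    def test_retaining_all_ecps_attains_coverage_bound(self, setup):
        net, de, opts = setup
        rep = compare_models(opts, net.ecp, de=de)
        assert rep["ecp_coverage"].max() <= len(net.ecp)
        full = optimize_moo(net, de=de, keep_quantile=1.0)
        rep2 = compare_models([full], net.ecp, de=de)
        assert rep2.loc["moo", "ecp_coverage"] == len(net.ecp)

    def test_correlation_unavailable_below_three_samples(self, setup, bundle):
        net, de, opts = setup
        expr = bundle.expression
        small = type(expr)(values=expr.values.iloc[:, :2],
                           groups=expr.groups.iloc[:2])
        rep = compare_models(opts[:1], net.ecp, de=de, expr=small)
        assert np.isnan(rep.loc["moo", "avg_regulating_intensity"])
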