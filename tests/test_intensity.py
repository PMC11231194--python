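"""Intensity-flow equations, combination selection against brute force,
pathway conservation, and the scaling/submodularity invariants."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctpflow import (
    CTPNetwork,
    GeneSetCollection,
    OptimizedNetwork,
    compound_intensity,
    cumulative_ranking,
    gene_intensity,
    make_worked_toy,
    pathway_intensity,
    select_combination,
)


def _opt(compounds, targets, pathogenic, ct, pp, scores):
    net = CTPNetwork(
        compounds=set(compounds), targets=set(targets), pathogenic=set(pathogenic),
        ct_edges={e: None for e in ct},
        pp_edges={(min(a, b), max(a, b)) for a, b in pp},
    )
    return OptimizedNetwork(network=net, scores=dict(scores), model="moo")


def _random_instance(rng, n_compounds, n_genes):
    """Compounds hitting random subsets of ECP genes with random scores."""
    genes = [f"G{i}" for i in range(n_genes)]
    scores = {g: float(rng.uniform(0.05, 1.0)) for g in genes}
    compounds = [f"c{i:02d}" for i in range(n_compounds)]
    ct = []
    for c in compounds:
        k = int(rng.integers(1, n_genes + 1))
        for g in rng.choice(genes, size=k, replace=False):
            ct.append((c, str(g)))
    return _opt(compounds, genes, genes, ct, [], scores)


def _brute_force_minimal(reachable, weights, threshold):
    """Independent oracle: exhaustive subset enumeration, smallest size first."""
    ids = sorted(reachable)
    total = sum(weights[g] for g in set().union(*(reachable[c] for c in ids)))
    goal = threshold * total - 1e-12
    for m in range(1, len(ids) + 1):
        best = max(
            (sum(weights[g] for g in set().union(*(reachable[c] for c in sub)))
             for sub in combinations(ids, m)),
        )
        if best >= goal:
            return m, total
    raise AssertionError("unreachable: full set always meets the threshold")


class TestGeneIntensity:
    def test_ecp_carries_its_own_score(self):
        opt = _opt(["c1"], ["K"], ["K"], [("c1", "K")], [], {"K": 0.7})
        gi = gene_intensity(opt)
        assert gi.table.loc["K", "intensity"] == pytest.approx(0.7, abs=1e-12)

    def test_non_target_gene_averages_neighbor_scores(self):
        opt = _opt(["c1", "c2"], ["T1", "T2"], ["K"],
                   [("c1", "T1"), ("c2", "T2")],
                   [("K", "T1"), ("K", "T2")],
                   {"T1": 0.4, "T2": 0.8})
        gi = gene_intensity(opt)
        assert gi.table.loc["K", "intensity"] == pytest.approx(0.6, abs=1e-12)
        assert gi.contributors["K"] == {"T1", "T2"}

    def test_isolated_pathogenic_gene_scores_zero(self):
        opt = _opt(["c1"], ["T1"], ["K"], [("c1", "T1")], [], {"T1": 0.5})
        gi = gene_intensity(opt)
        assert gi.table.loc["K", "intensity"] == 0.0
        assert gi.table.loc["K", "n_targets"] == 0

    def test_missing_score_is_fatal(self):
        opt = _opt(["c1"], ["T1"], ["K"], [("c1", "T1")], [], {})
        with pytest.raises(ValueError, match="score"):
            gene_intensity(opt)


class TestCompoundIntensity:
    def test_direct_ecp_targets_sum(self):
        opt = _opt(["c1"], ["K1", "K2"], ["K1", "K2"],
                   [("c1", "K1"), ("c1", "K2")], [], {"K1": 0.6, "K2": 0.3})
        gi = gene_intensity(opt)
        ci = compound_intensity(opt, gi)
        assert ci.table.loc["c1", "intensity"] == pytest.approx(0.9)

    def test_one_hop_ppi_reachability(self):
        # c1 -> T1; T1 -- K1 (pathogenic, intensity 0.5 = T1's score)
        opt = _opt(["c1"], ["T1"], ["K1"], [("c1", "T1")], [("T1", "K1")],
                   {"T1": 0.5})
        gi = gene_intensity(opt)
        ci = compound_intensity(opt, gi)
        assert ci.reachable["c1"] == {"K1"}
        assert ci.table.loc["c1", "intensity"] == pytest.approx(0.5)

    def test_compound_with_empty_reach_scores_zero(self):
        opt = _opt(["c1", "c2"], ["T1", "K"], ["K"],
                   [("c1", "K"), ("c2", "T1")], [], {"T1": 0.5, "K": 0.3})
        gi = gene_intensity(opt)
        ci = compound_intensity(opt, gi)
        assert ci.table.loc["c2", "intensity"] == 0.0

    def test_reachable_sets_subset_of_pathogenic(self, bundle):
        from ctpflow import build_ctp, optimize_moo, screen, simple_de
        rep = screen(bundle.compounds)
        net = build_ctp(rep.passed, bundle.ct_edges, bundle.pathogenic, bundle.ppi)
        opt = optimize_moo(net, de=simple_de(bundle.expression))
        gi = gene_intensity(opt)
        ci = compound_intensity(opt, gi)
        for s in ci.reachable.values():
            assert s <= opt.network.pathogenic


class TestSelectCombination:
    def test_worked_toy_minimal_pair(self, toy):
        gi = gene_intensity(toy.optimized)
        ci = compound_intensity(toy.optimized, gi)
        sel = select_combination(ci, gi, threshold=0.9, solver="exact")
        assert sel.total == pytest.approx(1.4)
        assert sel.selected == ("A", "B")
        assert sel.selected_size == 2

    def test_low_threshold_selects_single_best(self, toy):
        gi = gene_intensity(toy.optimized)
        ci = compound_intensity(toy.optimized, gi)
        sel = select_combination(ci, gi, threshold=0.3, solver="exact")
        assert sel.selected == ("A",)

    def test_single_compound_covering_everything(self):
        opt = _opt(["c1"], ["K"], ["K"], [("c1", "K")], [], {"K": 1.0})
        gi = gene_intensity(opt)
        ci = compound_intensity(opt, gi)
        for thr in (0.1, 0.9, 1.0):
            assert select_combination(ci, gi, threshold=thr).selected_size == 1

    def test_exact_limit_enforced(self, toy):
        gi = gene_intensity(toy.optimized)
        ci = compound_intensity(toy.optimized, gi)
        with pytest.raises(ValueError, match="greedy"):
            select_combination(ci, gi, solver="exact", exact_limit=2)

    @pytest.mark.parametrize("rep", range(10))
    def test_exact_matches_independent_brute_force(self, rep):
        rng = np.random.default_rng(1000 + rep)
        opt = _random_instance(rng, int(rng.integers(3, 9)), int(rng.integers(3, 8)))
        gi = gene_intensity(opt)
        ci = compound_intensity(opt, gi)
        sel = select_combination(ci, gi, threshold=0.9, solver="exact")
        oracle_size, oracle_total = _brute_force_minimal(
            ci.reachable, gi.table["intensity"].to_dict(), 0.9)
        assert sel.selected_size == oracle_size
        assert sel.total == pytest.approx(oracle_total)
        assert sel.selected_intensity >= 0.9 * sel.total - 1e-9

    @pytest.mark.parametrize("rep", range(10))
    def test_greedy_meets_threshold_and_never_beats_exact(self, rep):
        rng = np.random.default_rng(2000 + rep)
        opt = _random_instance(rng, int(rng.integers(3, 13)), int(rng.integers(3, 10)))
        gi = gene_intensity(opt)
        ci = compound_intensity(opt, gi)
        exact = select_combination(ci, gi, threshold=0.9, solver="exact")
        greedy = select_combination(ci, gi, threshold=0.9, solver="greedy")
        assert greedy.selected_size >= exact.selected_size
        assert greedy.selected_intensity >= 0.9 * greedy.total - 1e-9

    def test_per_size_optima_nondecreasing(self, toy):
        gi = gene_intensity(toy.optimized)
        ci = compound_intensity(toy.optimized, gi)
        sel = select_combination(ci, gi, threshold=1.0, solver="exact")
        vals = [r["intensity"] for r in sel.per_size]
        assert vals == sorted(vals)

    @given(st.integers(0, 9))
    def test_union_intensity_monotone_and_submodular(self, seed):
        rng = np.random.default_rng(seed)
        opt = _random_instance(rng, 5, 6)
        gi = gene_intensity(opt)
        ci = compound_intensity(opt, gi)
        w = gi.table["intensity"].to_dict()

        def f(subset):
            covered = set().union(*(ci.reachable[c] for c in subset)) if subset else set()
            return sum(w[g] for g in covered)

        ids = sorted(ci.reachable)
        subsets = list(chain.from_iterable(combinations(ids, m) for m in range(len(ids))))
        for sub in subsets[:40]:
            sub = set(sub)
            rest = [c for c in ids if c not in sub]
            for c in rest:
                assert f(sub | {c}) >= f(sub) - 1e-12           # monotone
            if len(rest) >= 2:
                c1, c2 = rest[0], rest[1]
                lhs = f(sub | {c1}) - f(sub)
                rhs = f(sub | {c2, c1}) - f(sub | {c2})
                assert lhs >= rhs - 1e-12                        # submodular

    def test_scaling_scores_preserves_selection(self, toy):
        gi = gene_intensity(toy.optimized)
        ci = compound_intensity(toy.optimized, gi)
        sel = select_combination(ci, gi, threshold=0.9, solver="exact")
        scaled = OptimizedNetwork(
            network=toy.optimized.network,
            scores={k: 3.7 * v for k, v in toy.optimized.scores.items()},
            model="moo",
        )
        gi2 = gene_intensity(scaled)
        ci2 = compound_intensity(scaled, gi2)
        sel2 = select_combination(ci2, gi2, threshold=0.9, solver="exact")
        assert sel2.selected == sel.selected
        assert sel2.total == pytest.approx(3.7 * sel.total)
        pd.testing.assert_index_equal(ci2.table.index, ci.table.index)


class TestPathwayIntensity:
    def test_multiplicity_downweighting(self):
        # g (0.6) in two pathways contributes 0.3 each; h (0.4) in one
        opt = _opt(["c"], ["G", "H"], ["G", "H"],
                   [("c", "G"), ("c", "H")], [], {"G": 0.6, "H": 0.4})
        gi = gene_intensity(opt)
        coll = GeneSetCollection(
            sets={"P1": frozenset({"G", "H"}), "P2": frozenset({"G"})})
        pw = pathway_intensity(gi, coll).set_index("pathway")
        assert pw.loc["P1", "intensity"] == pytest.approx(0.7)
        assert pw.loc["P2", "intensity"] == pytest.approx(0.3)

    def test_conservation_identity(self, bundle):
        from ctpflow import build_ctp, optimize_moo, screen, simple_de
        rep = screen(bundle.compounds)
        net = build_ctp(rep.passed, bundle.ct_edges, bundle.pathogenic, bundle.ppi)
        opt = optimize_moo(net, de=simple_de(bundle.expression))
        gi = gene_intensity(opt)
        pw = pathway_intensity(gi, bundle.pathways)
        counts = bundle.pathways.membership_counts()
        annotated = [g for g in gi.table.index if counts.get(g, 0) > 0]
        assert pw["intensity"].sum() == pytest.approx(
            gi.table.loc[annotated, "intensity"].sum(), abs=1e-9)

    def test_pathway_disjoint_from_pathogenic_scores_zero(self, toy):
        gi = gene_intensity(toy.optimized)
        coll = GeneSetCollection(sets={"P0": frozenset({"Q1", "Q2"})})
        pw = pathway_intensity(gi, coll)
        assert pw["intensity"].iloc[0] == 0.0

    def test_cumulative_ranking_reaches_total(self, toy):
        gi = gene_intensity(toy.optimized)
        ci = compound_intensity(toy.optimized, gi)
        cum = cumulative_ranking(ci, gi)
        assert cum["cumulative_intensity"].iloc[-1] == pytest.approx(1.4)
        assert (cum["increased_intensity"] >= 0).all()
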