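"""Interaction-intensity flow on pathogenic genes, compounds and pathways.

All intensity flows descend from the per-target optimization scores s of the
pruned network.  A pathogenic gene that is itself a retained target carries
its own score; a pathogenic gene that is not a target carries the mean score
of the retained targets it interacts with through PPI edges (zero when it has
none).  A compound's intensity is the summed intensity of the pathogenic genes
it reaches — its direct pathogenic targets plus one-hop PPI neighbors of its
targets.  Combinations of compounds are scored on the union of their reached
gene sets so no gene is counted twice, which makes the combination objective
monotone and submodular and the selection a maximum-coverage problem: an
exact enumerator is available for small compound sets and a deterministic
greedy solver for the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .io import GeneSetCollection
from .optimize import OptimizedNetwork

logger = logging.getLogger("ctpflow")

_EPS = 1e-12


@dataclass
class GeneIntensityTable:
    """Per-pathogenic-gene intensity with the contributing target sets."""

    table: pd.DataFrame                       # index: gene; intensity, n_targets
    contributors: dict[str, frozenset[str]]

    def intensity(self) -> pd.Series:
        return self.table["intensity"]


@dataclass
class CompoundIntensityTable:
    """Per-compound intensity with each compound's reachable pathogenic set."""

    table: pd.DataFrame                       # index: compound; intensity, n_genes
    reachable: dict[str, frozenset[str]]


@dataclass
class CombinationResult:
    solver: str
    threshold: float
    total: float
    per_size: list[dict] = field(default_factory=list)   # size, members, intensity
    selected: tuple[str, ...] = ()
    selected_intensity: float = 0.0

    @property
    def selected_size(self) -> int:
        return len(self.selected)


def gene_intensity(opt: OptimizedNetwork) -> GeneIntensityTable:
    """Intensity flow of every pathogenic gene in the optimized network."""
    net = opt.network
    scores = opt.scores
    for t in net.targets:
        if t not in scores:
            raise ValueError(f"retained target {t!r} lacks an optimization score")
    adj = net.pp_neighbors()
    rows = []
    contributors: dict[str, frozenset[str]] = {}
    for k in sorted(net.pathogenic):
        if k in net.targets:
            tk = frozenset({k})
            val = float(scores[k])
        else:
            tk = frozenset(nb for nb in adj.get(k, ()) if nb in net.targets)
            val = (sum(scores[j] for j in tk) / len(tk)) if tk else 0.0
        contributors[k] = tk
        rows.append({"gene": k, "intensity": val, "n_targets": len(tk)})
    table = pd.DataFrame(rows, columns=["gene", "intensity", "n_targets"]).set_index("gene")
    return GeneIntensityTable(table=table, contributors=contributors)


def compound_intensity(opt: OptimizedNetwork, gi: GeneIntensityTable) -> CompoundIntensityTable:
    """Summed pathogenic-gene intensity reached by each compound.

    The reachable set of compound i is its direct pathogenic targets plus the
    pathogenic genes sharing a PPI edge with at least one of its targets.
    """
    net = opt.network
    intensity = gi.table["intensity"]
    adj = net.pp_neighbors()
    targets_of: dict[str, set[str]] = {c: set() for c in net.compounds}
    for (c, t) in net.ct_edges:
        targets_of[c].add(t)
    rows = []
    reachable: dict[str, frozenset[str]] = {}
    for c in sorted(net.compounds):
        tset = targets_of[c]
        if not tset:
            logger.info("compound_intensity: compound %s has no retained targets", c)
        ci: set[str] = {t for t in tset if t in net.pathogenic}
        for t in tset:
            ci |= {nb for nb in adj.get(t, ()) if nb in net.pathogenic}
        reachable[c] = frozenset(ci)
        rows.append({
            "compound": c,
            "intensity": float(sum(intensity[k] for k in ci)),
            "n_genes": len(ci),
        })
    table = (
        pd.DataFrame(rows, columns=["compound", "intensity", "n_genes"])
        .set_index("compound")
        .sort_values("intensity", ascending=False, kind="mergesort")
    )
    return CompoundIntensityTable(table=table, reachable=reachable)


def _union_intensity(members, reachable, weights) -> float:
    covered: set[str] = set()
    for c in members:
        covered |= reachable[c]
    return float(sum(weights[k] for k in covered))


def select_combination(
    ci: CompoundIntensityTable,
    gi: GeneIntensityTable,
    threshold: float = 0.9,
    solver: str = "greedy",
    exact_limit: int = 15,
) -> CombinationResult:
    """Smallest compound combination reaching ``threshold`` of the total.

    The total is the union intensity of all compounds.  The exact solver
    enumerates every combination per size m = 1, 2, … and stops at the first
    size whose optimal (maximal-union) combination reaches the threshold,
    breaking ties lexicographically on sorted member ids.  The greedy solver
    adds the compound with the largest marginal union gain (ties: larger
    single-compound intensity, then smaller id) until the threshold is met.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if solver not in ("exact", "greedy"):
        raise ValueError(f"solver must be 'exact' or 'greedy', got {solver!r}")
    weights = gi.table["intensity"].to_dict()
    reachable = ci.reachable
    ids = sorted(reachable)
    if not ids:
        raise ValueError("no compounds to select from")
    total = _union_intensity(ids, reachable, weights)
    goal = threshold * total - _EPS
    result = CombinationResult(solver=solver, threshold=threshold, total=total)
    if total == 0.0:
        result.selected = ()
        return result

    if solver == "exact":
        if len(ids) > exact_limit:
            raise ValueError(
                f"{len(ids)} compounds exceeds exact_limit={exact_limit}; use solver='greedy'"
            )
        for m in range(1, len(ids) + 1):
            best_members, best_val = None, -1.0
            for members in combinations(ids, m):
                val = _union_intensity(members, reachable, weights)
                if val > best_val + _EPS:   # strict: first (lexicographic) max wins
                    best_members, best_val = members, val
            result.per_size.append({"size": m, "members": list(best_members),
                                    "intensity": best_val})
            if best_val >= goal:
                result.selected = tuple(best_members)
                result.selected_intensity = best_val
                break
        return result

    # greedy maximum coverage
    chosen: list[str] = []
    covered: set[str] = set()
    value = 0.0
    remaining = set(ids)
    single = ci.table["intensity"].to_dict()
    while remaining and value < goal:
        best_c, best_key = None, None
        for c in sorted(remaining):
            gain = sum(weights[k] for k in reachable[c] - covered)
            key = (-gain, -single[c], c)
            if best_key is None or key < best_key:
                best_c, best_key = c, key
        chosen.append(best_c)
        covered |= reachable[best_c]
        value = float(sum(weights[k] for k in covered))
        remaining.discard(best_c)
        result.per_size.append({"size": len(chosen), "members": list(chosen),
                                "intensity": value})
    result.selected = tuple(chosen)
    result.selected_intensity = value
    return result


def cumulative_ranking(ci: CompoundIntensityTable, gi: GeneIntensityTable) -> pd.DataFrame:
    """Greedy cumulative-intensity table over all compounds.

    One row per compound in greedy order with its marginal (increased)
    intensity and the running cumulative union intensity — the tabular
    equivalent of a cumulative-intensity plot with a 90 % line.
    """
    weights = gi.table["intensity"].to_dict()
    reachable = ci.reachable
    single = ci.table["intensity"].to_dict()
    remaining = set(reachable)
    covered: set[str] = set()
    cumulative = 0.0
    rows = []
    while remaining:
        best_c, best_key = None, None
        for c in sorted(remaining):
            gain = sum(weights[k] for k in reachable[c] - covered)
            key = (-gain, -single[c], c)
            if best_key is None or key < best_key:
                best_c, best_key = c, key
        gain = sum(weights[k] for k in reachable[best_c] - covered)
        covered |= reachable[best_c]
        cumulative += gain
        rows.append({"compound": best_c, "increased_intensity": float(gain),
                     "cumulative_intensity": float(cumulative)})
        remaining.discard(best_c)
    return pd.DataFrame(rows, columns=["compound", "increased_intensity",
                                       "cumulative_intensity"])


def pathway_intensity(
    gi: GeneIntensityTable,
    genesets: GeneSetCollection,
    top: int | None = None,
) -> pd.DataFrame:
    """Cumulative intensity flow per pathway, ranked descending.

    Each pathogenic gene contributes its intensity divided by the number of
    pathways it belongs to (n_k^p), so the total over pathways conserves the
    total intensity of pathway-annotated pathogenic genes.
    """
    intensity = gi.table["intensity"]
    counts = genesets.membership_counts()
    rows = []
    for name, members in genesets.sets.items():
        val = 0.0
        n_genes = 0
        for k in members:
            if k in intensity.index and counts[k] > 0:
                val += float(intensity[k]) / counts[k]
                n_genes += 1
        rows.append({"pathway": name, "intensity": val, "n_pathogenic": n_genes})
    out = (
        pd.DataFrame(rows, columns=["pathway", "intensity", "n_pathogenic"])
        .sort_values(["intensity", "pathway"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    out["rank"] = range(1, len(out) + 1)
    if top is not None:
        out = out.head(top)
    return out
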