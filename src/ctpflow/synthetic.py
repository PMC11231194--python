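"""Seeded synthetic inputs with planted ground truth.

The generator emulates the inputs of a multi-herb screening study — a
compound property table with herb membership, predicted compound–target
edges, a disease (pathogenic) gene list, a PPI edge list, pathway/GO gene
sets in GMT, and a case/control log2 expression matrix — with every quantity
of interest planted so recovery is checkable:

* screening labels are decided first and properties sampled conditional on
  the label, so the planted pass set is recovered exactly by the rule screen;
* the essential common proteins (ECPs) are a designated subset of the targets
  and every target is guaranteed at least one compound–target edge, so the
  ECP set computed from the emitted files equals the planted one;
* differential expression is planted on a subset of ECPs with a fixed log2
  effect size and Gaussian noise;
* compounds attach preferentially to ECP targets and ECPs receive extra PPI
  links to pathogenic genes (the planted high-signal structure a
  multi-objective optimizer should recover), while a few decoy hub targets
  receive many PPI links to non-disease targets (high centrality, no disease
  signal).

The same seed yields a byte-identical file bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CompoundRecord,
    CTPNetwork,
    ExpressionMatrix,
    GeneSetCollection,
    PropertyVector,
    write_compound_table,
    write_de_table,
    write_expression,
    write_gene_list,
    write_gmt,
)
from .optimize import OptimizedNetwork
from .screen import default_rules

_RULE_BOUNDS = {
    # field: (passing sampler bounds, failing sampler bounds)
    "mw": ((150.0, 500.0), (501.0, 900.0)),
    "logp": ((-2.0, 5.0), (5.2, 9.0)),
    "ob": ((30.0, 95.0), (1.0, 29.5)),
    "caco2": ((0.4, 1.6), (-1.0, 0.35)),
    "tpsa": ((10.0, 60.0), (61.0, 160.0)),
}
_INT_BOUNDS = {
    "n_hd": ((0, 5), (6, 12)),
    "n_ha": ((0, 10), (11, 18)),
    "n_rot": ((0, 10), (11, 22)),
}


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic bundle.

    Sizes default to a desk-scale analogue of an eight-herb prescription
    screen: 200 compounds over 8 herbs with a pass fraction of 0.22
    (comparable to rule-based ADMET screens of herbal compound libraries),
    150 predicted targets, 200 disease genes with a fifth of them reachable
    as targets (the ECP layer), an Erdős–Rényi PPI background, and a
    10-vs-10 case/control expression matrix with log2 effects of 2.0 and
    residual SD 0.5 planted on 40 % of the ECPs.
    """

    seed: int
    n_herbs: int = 8
    compounds_per_herb: int = 25
    shared_compound_rate: float = 0.15
    pass_fraction: float = 0.22
    n_targets: int = 150
    n_pathogenic: int = 200
    ecp_fraction: float = 0.2
    targets_per_compound: tuple[int, int] = (3, 10)
    ppi_edge_prob: float = 0.01
    ecp_ppi_links: int = 4
    n_decoy_hubs: int = 5
    hub_degree: int = 30
    signal_preference: float = 0.6
    n_pathways: int = 40
    pathway_size: tuple[int, int] = (10, 30)
    n_gobp: int = 120
    gobp_size: tuple[int, int] = (10, 25)
    n_samples: int = 10
    de_fraction: float = 0.4
    de_effect_size: float = 2.0
    noise_sd: float = 0.5

    @property
    def n_compounds(self) -> int:
        return self.n_herbs * self.compounds_per_herb

    @property
    def n_ecp(self) -> int:
        return int(round(self.ecp_fraction * self.n_pathogenic))

    def validate(self) -> None:
        for name in ("shared_compound_rate", "pass_fraction", "ecp_fraction",
                     "de_fraction", "signal_preference"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_herbs", "compounds_per_herb", "n_targets", "n_pathogenic",
                     "n_pathways", "n_gobp", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_ecp > self.n_targets:
            raise ValueError(
                f"infeasible config: ecp_fraction*n_pathogenic={self.n_ecp} "
                f"exceeds n_targets={self.n_targets}"
            )
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples per group")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    passers: frozenset[str]
    ecp: frozenset[str]
    de_genes: dict[str, float]          # gene -> true signed log2 fold change
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "passers": sorted(self.passers),
            "ecp": sorted(self.ecp),
            "de_genes": {g: self.de_genes[g] for g in sorted(self.de_genes)},
            "config": self.config,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SyntheticBundle:
    compounds: list[CompoundRecord]
    ct_edges: pd.DataFrame
    pathogenic: list[str]
    ppi: pd.DataFrame
    pathways: GeneSetCollection
    gobp: GeneSetCollection
    expression: ExpressionMatrix
    truth: SyntheticTruth


def _sample_properties(rng: np.random.Generator, passing: bool) -> PropertyVector:
    kwargs: dict = {}
    for f, ((lo, hi), _) in _RULE_BOUNDS.items():
        kwargs[f] = round(float(rng.uniform(lo, hi)), 3)
    for f, ((lo, hi), _) in _INT_BOUNDS.items():
        kwargs[f] = int(rng.integers(lo, hi + 1))
    kwargs["hepatotoxic"] = False
    if not passing:
        fields = list(_RULE_BOUNDS) + list(_INT_BOUNDS) + ["hepatotoxic"]
        n_viol = int(rng.integers(1, 4))
        for f in rng.choice(fields, size=n_viol, replace=False):
            if f == "hepatotoxic":
                kwargs["hepatotoxic"] = True
            elif f in _RULE_BOUNDS:
                lo, hi = _RULE_BOUNDS[f][1]
                kwargs[f] = round(float(rng.uniform(lo, hi)), 3)
            else:
                lo, hi = _INT_BOUNDS[f][1]
                kwargs[f] = int(rng.integers(lo, hi + 1))
    return PropertyVector(**kwargs)


def simulate_expression(
    genes: list[str],
    de_effects: dict[str, float],
    n_samples: int,
    noise_sd: float,
    rng: np.random.Generator,
    base_range: tuple[float, float] = (4.0, 10.0),
) -> ExpressionMatrix:
    """Log2-scale case/control matrix with planted mean shifts on ``de_effects``."""
    n = len(genes)
    mu = rng.uniform(*base_range, size=n)
    delta = np.array([de_effects.get(g, 0.0) for g in genes])
    case = mu[:, None] + delta[:, None] + rng.normal(0.0, noise_sd, size=(n, n_samples))
    control = mu[:, None] + rng.normal(0.0, noise_sd, size=(n, n_samples))
    cols = [f"case_{i+1:02d}" for i in range(n_samples)] + \
           [f"control_{i+1:02d}" for i in range(n_samples)]
    values = pd.DataFrame(np.hstack([case, control]), index=genes, columns=cols).round(4)
    groups = pd.Series(
        ["case"] * n_samples + ["control"] * n_samples, index=cols, name="group"
    )
    return ExpressionMatrix(values=values, groups=groups)


def _random_sets(rng, prefix: str, n_sets: int, size_range: tuple[int, int],
                 pool: list[str], disease_pool: list[str], category: str) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        name = f"{prefix}{i+1:04d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if rng.random() < 0.3 and disease_pool:
            n_dis = min(len(disease_pool), max(1, int(round(0.4 * size))))
            members = set(rng.choice(disease_pool, size=n_dis, replace=False))
            rest = [g for g in pool if g not in members]
            extra = rng.choice(rest, size=min(size - n_dis, len(rest)), replace=False)
            members |= set(extra)
        else:
            members = set(rng.choice(pool, size=min(size, len(pool)), replace=False))
        sets[name] = frozenset(str(g) for g in members)
        descriptions[name] = f"synthetic {category} set"
    return GeneSetCollection(sets=sets, descriptions=descriptions, category=category)


def generate(config: GeneratorConfig, out_dir: str | Path | None = None) -> SyntheticBundle:
    """Generate the full file bundle; optionally write it under ``out_dir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- compounds: label first, then properties conditional on the label
    n = config.n_compounds
    ids = [f"CMP{i+1:04d}" for i in range(n)]
    herbs = [f"Herb{chr(ord('A') + (i // config.compounds_per_herb) % 26)}"
             for i in range(n)]
    herb_names = sorted(set(herbs))
    herb_sets: list[set[str]] = [{h} for h in herbs]
    n_shared = int(round(config.shared_compound_rate * n))
    for idx in rng.choice(n, size=n_shared, replace=False):
        extra = rng.choice(herb_names, size=int(rng.integers(1, 3)), replace=False)
        herb_sets[idx] |= set(extra)
    n_pass = int(round(config.pass_fraction * n))
    pass_idx = set(rng.choice(n, size=n_pass, replace=False).tolist())
    compounds = [
        CompoundRecord(
            compound_id=ids[i],
            name=f"compound-{ids[i]}",
            herbs=frozenset(herb_sets[i]),
            properties=_sample_properties(rng, i in pass_idx),
        )
        for i in range(n)
    ]
    passers = sorted(ids[i] for i in pass_idx)

    # --- gene layers
    targets = [f"GT{i+1:04d}" for i in range(config.n_targets)]
    ecp = sorted(rng.choice(targets, size=config.n_ecp, replace=False).tolist())
    n_extra = config.n_pathogenic - config.n_ecp
    pathogenic = sorted(ecp + [f"GP{i+1:04d}" for i in range(n_extra)])

    # --- compound-target edges: every target covered, then preferential draws
    lo, hi = config.targets_per_compound
    edge_set: set[tuple[str, str]] = set()
    for t in targets:
        c = passers[int(rng.integers(len(passers)))]
        edge_set.add((c, t))
    ecp_arr = np.array(ecp)
    target_arr = np.array(targets)
    for c in passers:
        k = int(rng.integers(lo, hi + 1))
        for _ in range(k * 4):
            if sum(1 for e in edge_set if e[0] == c) >= k:
                break
            pool = ecp_arr if rng.random() < config.signal_preference else target_arr
            t = str(pool[int(rng.integers(len(pool)))])
            edge_set.add((c, t))
    ct_edges = pd.DataFrame(sorted(edge_set), columns=["source", "target"])

    # --- PPI: ER background + planted ECP-disease links + decoy hubs
    proteins = sorted(set(targets) | set(pathogenic))
    m = len(proteins)
    iu, ju = np.triu_indices(m, k=1)
    mask = rng.random(iu.shape[0]) < config.ppi_edge_prob
    pp_set = {(proteins[a], proteins[b]) for a, b in zip(iu[mask], ju[mask])}
    for g in ecp:
        partners = rng.choice(pathogenic, size=min(config.ecp_ppi_links, len(pathogenic)),
                              replace=False)
        for p in partners:
            if p != g:
                pp_set.add((min(g, p), max(g, p)))
    non_disease = [t for t in targets if t not in set(pathogenic)]
    hubs = rng.choice(non_disease, size=min(config.n_decoy_hubs, len(non_disease)),
                      replace=False)
    for h in hubs:
        partners = rng.choice(non_disease, size=min(config.hub_degree, len(non_disease)),
                              replace=False)
        for p in partners:
            if p != h:
                pp_set.add((min(h, p), max(h, p)))
    ppi = pd.DataFrame(sorted(pp_set), columns=["source", "target"])

    # --- gene sets
    pathways = _random_sets(rng, "PW", config.n_pathways, config.pathway_size,
                            proteins, pathogenic, "pathway")
    gobp = _random_sets(rng, "BP", config.n_gobp, config.gobp_size,
                        proteins, pathogenic, "gobp")

    # --- expression with DE planted on a subset of ECPs
    n_de = int(round(config.de_fraction * len(ecp)))
    de_genes = sorted(rng.choice(ecp, size=n_de, replace=False).tolist()) if n_de else []
    signs = rng.choice([-1.0, 1.0], size=len(de_genes))
    de_effects = {g: float(s * config.de_effect_size) for g, s in zip(de_genes, signs)}
    expression = simulate_expression(
        proteins, de_effects, config.n_samples, config.noise_sd, rng
    )

    truth = SyntheticTruth(
        passers=frozenset(passers),
        ecp=frozenset(ecp),
        de_genes=de_effects,
        config=asdict(config),
    )
    bundle = SyntheticBundle(
        compounds=compounds, ct_edges=ct_edges, pathogenic=pathogenic,
        ppi=ppi, pathways=pathways, gobp=gobp, expression=expression, truth=truth,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_compound_table(bundle.compounds, out / "compounds.tsv")
    bundle.ct_edges.to_csv(out / "ct_edges.tsv", sep="\t", index=False)
    write_gene_list(bundle.pathogenic, out / "pathogenic_genes.tsv")
    bundle.ppi.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
    write_gmt(bundle.pathways, out / "pathways.gmt")
    write_gmt(bundle.gobp, out / "gobp.gmt")
    write_expression(bundle.expression, out / "expression.tsv", out / "sample_groups.tsv")
    (out / "truth.json").write_text(bundle.truth.to_json() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# fixed worked toy
# ---------------------------------------------------------------------------

@dataclass
class ToyBundle:
    """The fixed three-compound / three-gene worked example.

    Compounds A, B, C target the ECPs G1–G3 (A→{G1,G2}, B→{G2,G3}, C→{G3});
    the planted optimization scores are 0.5, 0.5, 0.4, so the compound
    intensities are A=1.0, B=0.9, C=0.4, the union total is 1.4, and the
    smallest combination reaching 90 % of the total is {A, B}.
    """

    compounds: list[CompoundRecord]
    ct_edges: pd.DataFrame
    pathogenic: list[str]
    ppi: pd.DataFrame
    pathways: GeneSetCollection
    de: pd.DataFrame
    expression: ExpressionMatrix
    optimized: OptimizedNetwork


_TOY_SCORES = {"G1": 0.5, "G2": 0.5, "G3": 0.4}
_TOY_CT = [("A", "G1"), ("A", "G2"), ("B", "G2"), ("B", "G3"), ("C", "G3")]


def make_worked_toy(out_dir: str | Path | None = None) -> ToyBundle:
    """Build (and optionally write) the fixed worked toy; byte-stable."""
    props = PropertyVector(mw=300.0, n_hd=2, n_ha=4, logp=2.5, n_rot=3,
                           ob=50.0, caco2=0.8, tpsa=40.0, hepatotoxic=False)
    compounds = [
        CompoundRecord("A", "toy-A", frozenset({"HerbX"}), props),
        CompoundRecord("B", "toy-B", frozenset({"HerbX"}), props),
        CompoundRecord("C", "toy-C", frozenset({"HerbY"}), props),
    ]
    ct_edges = pd.DataFrame(_TOY_CT, columns=["source", "target"])
    pathogenic = ["G1", "G2", "G3"]
    ppi = pd.DataFrame(columns=["source", "target"])
    pathways = GeneSetCollection(
        sets={"PW1": frozenset({"G1", "G2"}), "PW2": frozenset({"G2", "G3"})},
        descriptions={"PW1": "toy pathway 1", "PW2": "toy pathway 2"},
        category="pathway",
    )
    de = pd.DataFrame(
        {"logfc": [2.0, 2.0, 1.6], "pvalue": [1e-4, 1e-4, 5e-4],
         "fdr": [1e-3, 1e-3, 2e-3]},
        index=pd.Index(["G1", "G2", "G3"], name="gene"),
    )
    de.attrs["provenance"] = "loaded"
    values = pd.DataFrame(
        {
            "case_01": [8.1, 7.9, 6.6], "case_02": [7.8, 8.2, 6.4],
            "case_03": [8.0, 8.1, 6.5],
            "control_01": [6.0, 6.1, 5.0], "control_02": [5.9, 5.8, 4.9],
            "control_03": [6.1, 6.0, 4.8],
        },
        index=pd.Index(["G1", "G2", "G3"], name="gene"),
    )
    groups = pd.Series(
        ["case"] * 3 + ["control"] * 3, index=values.columns, name="group"
    )
    expression = ExpressionMatrix(values=values, groups=groups)
    net = CTPNetwork(
        compounds={"A", "B", "C"},
        targets={"G1", "G2", "G3"},
        pathogenic=set(pathogenic),
        ct_edges={e: None for e in _TOY_CT},
        pp_edges=set(),
    )
    optimized = OptimizedNetwork(network=net, scores=dict(_TOY_SCORES),
                                 model="moo", config={"planted": True})
    bundle = ToyBundle(
        compounds=compounds, ct_edges=ct_edges, pathogenic=pathogenic, ppi=ppi,
        pathways=pathways, de=de, expression=expression, optimized=optimized,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_compound_table(compounds, out / "compounds.tsv")
        ct_edges.to_csv(out / "ct_edges.tsv", sep="\t", index=False)
        write_gene_list(pathogenic, out / "pathogenic_genes.tsv")
        ppi.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
        write_gmt(pathways, out / "pathways.gmt")
        write_de_table(de, out / "de_table.tsv")
        write_expression(expression, out / "expression.tsv", out / "sample_groups.tsv")
        from .io import write_network
        write_network(net, out / "optimized_nodes.tsv", out / "optimized_edges.tsv",
                      scores=_TOY_SCORES)
    return bundle
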