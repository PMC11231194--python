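"""Network optimization: multi-objective target scoring and centrality baselines.

The multi-objective model (label ``moo``) scores every target gene on three
axes — association with compounds, association with disease genes, and
transcriptional dysregulation — each min–max normalized over the target set,
and combines them as a weighted mean (equal weights by default).  Pruning
keeps targets whose score reaches the requested upper quantile, with ties at
the boundary retained.  Degree, closeness and betweenness centralities serve
as baseline scoring models; path-based centralities are computed on the
protein–protein subgraph so that compound nodes do not distort shortest paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import enrich, top_terms
from .io import CTPNetwork, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("ctpflow")

CENTRALITY_MODELS = ("degree", "closeness", "betweenness")


@dataclass
class OptimizedNetwork:
    """A pruned C-T-P network with per-target scores in [0, 1]."""

    network: CTPNetwork
    scores: dict[str, float]
    model: str
    config: dict = field(default_factory=dict)


def _minmax(raw: pd.Series, name: str) -> pd.Series:
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("objective %r is constant over targets; set to 0 for all", name)
        return pd.Series(0.0, index=raw.index)
    return (raw - lo) / (hi - lo)


def objectives(net: CTPNetwork, de: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-target objective vector (o_compound, o_pathogenic, o_dysreg).

    o_compound: incident compound–target edge count, or the sum of prediction
    scores when any edge carries one.  o_pathogenic: number of PPI neighbors
    that are disease genes, plus one if the gene is itself an ECP.  o_dysreg:
    |logFC| from the DE table, zero for genes without a DE entry.  Each axis is
    min–max normalized over the target set (a constant axis maps to zeros).
    """
    targets = sorted(net.targets)
    if not targets:
        raise ValueError("network has no target genes")
    use_scores = any(v is not None for v in net.ct_edges.values())
    o_comp = pd.Series(0.0, index=targets)
    for (c, t), score in net.ct_edges.items():
        o_comp[t] += (score if (use_scores and score is not None) else 1.0)
    adj = net.pp_neighbors()
    ecp = net.ecp
    o_path = pd.Series(
        [sum(1 for nb in adj.get(t, ()) if nb in net.pathogenic) + (1.0 if t in ecp else 0.0)
         for t in targets],
        index=targets, dtype=float,
    )
    if de is not None:
        logfc = de["logfc"].abs()
        o_dys = pd.Series([float(logfc.get(t, 0.0)) for t in targets], index=targets)
    else:
        o_dys = pd.Series(0.0, index=targets)
    return pd.DataFrame({
        "o_compound": _minmax(o_comp, "o_compound"),
        "o_pathogenic": _minmax(o_path, "o_pathogenic"),
        "o_dysreg": _minmax(o_dys, "o_dysreg"),
    })


def _prune(net: CTPNetwork, scores: pd.Series, keep_quantile: float, model: str,
           config: dict) -> OptimizedNetwork:
    if not (0.0 < keep_quantile <= 1.0):
        raise ValueError(f"keep_quantile must be in (0, 1], got {keep_quantile}")
    thr = float(np.quantile(scores.to_numpy(), 1.0 - keep_quantile))
    retained = set(scores.index[scores >= thr])
    if not retained:
        raise ValueError(
            f"no targets retained at keep_quantile={keep_quantile}; raise the quantile"
        )
    ecp = net.ecp
    ct = {(c, t): s for (c, t), s in net.ct_edges.items() if t in retained}
    keep_nodes = retained | net.pathogenic
    pp = {
        (a, b) for (a, b) in net.pp_edges
        if a in keep_nodes and b in keep_nodes
        and (a in retained or b in retained or a in ecp or b in ecp)
    }
    sub = CTPNetwork(
        compounds=set(net.compounds),
        targets=retained,
        pathogenic=set(net.pathogenic),
        ct_edges=ct,
        pp_edges=pp,
    )
    return OptimizedNetwork(
        network=sub,
        scores={t: float(scores[t]) for t in retained},
        model=model,
        config={**config, "keep_quantile": keep_quantile},
    )


def optimize_moo(
    net: CTPNetwork,
    de: pd.DataFrame | None = None,
    keep_quantile: float = 0.5,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    obj: pd.DataFrame | None = None,
) -> OptimizedNetwork:
    """Score targets with the multi-objective model and prune the network."""
    if obj is None:
        obj = objectives(net, de)
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or w.sum() <= 0:
        raise ValueError("weights must be three non-negative numbers with positive sum")
    s = obj.to_numpy() @ (w / w.sum())
    scores = pd.Series(s, index=obj.index)
    return _prune(net, scores, keep_quantile, "moo",
                  {"weights": list(map(float, w))})


def centrality_scores(net: CTPNetwork, model: str) -> pd.Series:
    """Raw centrality of each target gene, min–max normalized over targets.

    Closeness and betweenness are computed on the protein–protein subgraph
    (component-wise closeness; isolated nodes score zero).  Degree adds the
    compound–target degree on top of the PPI degree.
    """
    if model not in CENTRALITY_MODELS:
        raise ValueError(f"unknown centrality model {model!r}")
    g = nx.Graph()
    g.add_nodes_from(net.proteins)
    g.add_edges_from(net.pp_edges)
    targets = sorted(net.targets)
    if model == "degree":
        ctdeg = net.ct_degree()
        raw = {t: g.degree(t) + ctdeg.get(t, 0) for t in targets}
    elif model == "closeness":
        cc = nx.closeness_centrality(g)
        raw = {t: cc[t] for t in targets}
    else:
        bc = nx.betweenness_centrality(g, normalized=True)
        raw = {t: bc[t] for t in targets}
    return _minmax(pd.Series(raw, dtype=float), model)


def optimize_centrality(
    net: CTPNetwork, model: str, keep_quantile: float = 0.5
) -> OptimizedNetwork:
    """Prune with a centrality score in place of the multi-objective score."""
    scores = centrality_scores(net, model)
    return _prune(net, scores, keep_quantile, model, {})


def compare_models(
    opts: list[OptimizedNetwork],
    ecp: set[str],
    de: pd.DataFrame | None = None,
    expr: ExpressionMatrix | None = None,
    pathways: GeneSetCollection | None = None,
    gobp: GeneSetCollection | None = None,
    top_pathways: int = 100,
    top_gobp: int = 1000,
    min_term_size: int = 10,
) -> pd.DataFrame:
    """Five-aspect comparison of optimization models.

    Per model: (1) ECP coverage of the retained target set; (2) overlap of the
    model's top enriched pathways with the reference top list enriched from the
    ECP set; (3) the same for GO biological processes; (4) average regulating
    intensity — mean Pearson correlation over expression profiles of gene
    pairs joined by a retained PPI edge; (5) cumulative differential
    expression — the sum of |logFC| over retained ECPs.  Metrics whose inputs
    are absent are reported as NaN.
    """
    labels = [o.model for o in opts]
    if len(set(labels)) != len(labels):
        raise ValueError("model labels must be unique")

    ref_kegg = ref_gobp = None
    if pathways is not None:
        ref_kegg = set(top_terms(
            enrich(ecp, pathways, min_term_size=min_term_size), top_pathways))
    if gobp is not None:
        ref_gobp = set(top_terms(
            enrich(ecp, gobp, min_term_size=min_term_size), top_gobp))

    n_corr_samples = 0 if expr is None else expr.values.shape[1]
    rows = {}
    for opt in opts:
        genes = opt.network.targets
        row: dict[str, float] = {"ecp_coverage": float(len(genes & ecp))}
        for key, coll, ref, top_n in (
            ("kegg_top_overlap", pathways, ref_kegg, top_pathways),
            ("gobp_top_overlap", gobp, ref_gobp, top_gobp),
        ):
            if coll is None:
                row[key] = float("nan")
                continue
            model_top = set(top_terms(
                enrich(genes, coll, min_term_size=min_term_size), top_n))
            row[key] = float(len(model_top & ref))
        if expr is None or n_corr_samples < 3:
            row["avg_regulating_intensity"] = float("nan")
        else:
            vals = expr.values
            corrs = []
            n_skipped = 0
            for a, b in opt.network.pp_edges:
                if a in vals.index and b in vals.index:
                    x = vals.loc[a].to_numpy(dtype=float)
                    y = vals.loc[b].to_numpy(dtype=float)
                    if x.std() > 0 and y.std() > 0:
                        corrs.append(float(np.corrcoef(x, y)[0, 1]))
                        continue
                n_skipped += 1
            if n_skipped:
                logger.info("compare_models[%s]: %d pp pairs lacked usable expression",
                            opt.model, n_skipped)
            row["avg_regulating_intensity"] = float(np.mean(corrs)) if corrs else float("nan")
        if de is None:
            row["cumulative_abs_logfc"] = float("nan")
        else:
            retained_ecp = genes & ecp
            row["cumulative_abs_logfc"] = float(
                de["logfc"].abs().reindex(sorted(retained_ecp)).fillna(0.0).sum()
            )
        rows[opt.model] = row
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "model"
    return report.sort_index()
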