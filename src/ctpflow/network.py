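"""Assembly of the tripartite compound–target–pathogenic-gene (C-T-P) network.

Predicted compound–target edges (the union over prediction sources,
deduplicated upstream) are merged with protein–protein interactions.  The
protein layer is the union of predicted targets and disease genes; PPI edges
are kept only when both endpoints belong to that layer.  Genes that are both
targets and disease genes are the essential common proteins (ECPs).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Iterable

import pandas as pd

from .io import CTPNetwork, normalize_gene

logger = logging.getLogger("ctpflow")


@dataclass(frozen=True)
class NetworkStats:
    n_compounds: int
    n_targets: int
    n_pathogenic: int
    n_ecp: int
    n_ct_edges: int
    n_pp_edges: int

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


def _iter_edges(edges) -> Iterable[tuple[str, str, float | None]]:
    if isinstance(edges, pd.DataFrame):
        has_score = "score" in edges.columns
        for row in edges.itertuples(index=False):
            score = getattr(row, "score", None) if has_score else None
            if score is not None and pd.isna(score):
                score = None
            yield str(row.source), str(row.target), score
    else:
        for e in edges:
            if len(e) == 2:
                yield str(e[0]), str(e[1]), None
            else:
                yield str(e[0]), str(e[1]), e[2]


def build_ctp(
    pass_compounds: Iterable[str],
    ct_edges,
    pathogenic: Iterable[str],
    ppi,
) -> CTPNetwork:
    """Build the C-T-P network from the screened pass set.

    ``ct_edges`` and ``ppi`` accept DataFrames (``source, target[, score]``)
    or iterables of pairs/triples.  Compound–target edges whose compound is
    not in the pass set are dropped with a warning count; PPI edges are
    restricted to pairs with both endpoints in the protein layer.
    """
    compounds = {str(c) for c in pass_compounds}
    if not compounds:
        raise ValueError("empty compound pass set")
    path_set = {normalize_gene(g) for g in pathogenic}
    if not path_set:
        raise ValueError("empty pathogenic gene list")

    ct: dict[tuple[str, str], float | None] = {}
    n_dropped = 0
    for c, t, score in _iter_edges(ct_edges):
        t = normalize_gene(t)
        if c not in compounds:
            n_dropped += 1
            continue
        key = (c, t)
        if key in ct and ct[key] is None:
            ct[key] = score
        else:
            ct.setdefault(key, score)
    if n_dropped:
        logger.warning("build_ctp: dropped %d ct edges referencing non-pass compounds", n_dropped)

    targets = {t for (_, t) in ct}
    proteins = targets | path_set

    pp: set[tuple[str, str]] = set()
    for a, b, _ in _iter_edges(ppi):
        a, b = normalize_gene(a), normalize_gene(b)
        if a == b:
            continue
        if a in proteins and b in proteins:
            pp.add((min(a, b), max(a, b)))

    return CTPNetwork(
        compounds=compounds, targets=targets, pathogenic=path_set,
        ct_edges=ct, pp_edges=pp,
    )


def network_stats(net: CTPNetwork) -> NetworkStats:
    return NetworkStats(
        n_compounds=len(net.compounds),
        n_targets=len(net.targets),
        n_pathogenic=len(net.pathogenic),
        n_ecp=len(net.ecp),
        n_ct_edges=len(net.ct_edges),
        n_pp_edges=len(net.pp_edges),
    )
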