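"""Hypergeometric over-representation analysis and a minimal two-group DE test.

The enrichment p-value for a term is the upper-tail hypergeometric
probability P[X >= k] of drawing at least the observed overlap when the query
is sampled without replacement from the universe; Benjamini–Hochberg controls
the FDR across the surviving terms.  Terms with fewer than ``min_term_size``
in-universe genes are removed before testing.

``simple_de`` is a deliberately plain differential-expression summary for
synthetic runs — per-gene log2 fold change (difference of group means on
log2-scale values) with a Welch t-test and BH adjustment.  Precomputed DE
tables from dedicated tools can be supplied instead wherever a DE table is
consumed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection, normalize_gene

logger = logging.getLogger("ctpflow")


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    min_term_size: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``universe`` defaults to all genes annotated anywhere in the collection.
    Query genes outside the universe are dropped with a warning.  Returns one
    row per surviving term sorted by (fdr, pvalue, term).
    """
    if not query:
        raise ValueError("empty query gene set")
    query = {normalize_gene(g) for g in query}
    if universe is None:
        universe = collection.all_genes()
    else:
        universe = {normalize_gene(g) for g in universe}
    if not universe:
        raise ValueError("empty universe")
    outside = query - universe
    if outside:
        logger.warning("enrich: dropped %d query genes outside the universe", len(outside))
        query = query & universe
    if not query:
        raise ValueError("no query genes inside the universe")

    M, N = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        m = len(in_universe)
        if m < min_term_size:
            continue
        overlap = in_universe & query
        k = len(overlap)
        # P[X >= k] for X ~ Hypergeom(M, m, N); sf(k-1) includes k itself
        p = float(stats.hypergeom.sf(k - 1, M, m, N))
        rows.append({
            "term": name,
            "overlap": k,
            "term_size": m,
            "query_size": N,
            "universe_size": M,
            "pvalue": min(1.0, p),
            "genes": ";".join(sorted(overlap)),
        })
    res = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "query_size",
                       "universe_size", "pvalue", "genes"],
    )
    if res.empty:
        res["fdr"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
        return res
    res["fdr"] = multipletests(res["pvalue"].to_numpy(), method="fdr_bh")[1]
    res["significant"] = res["fdr"] <= fdr_threshold
    res = res.sort_values(["fdr", "pvalue", "term"]).reset_index(drop=True)
    return res


def top_terms(res: pd.DataFrame, n: int) -> list[str]:
    """First ``n`` terms under the documented sort; ties at the cut retained."""
    if res.empty or n <= 0:
        return []
    if len(res) <= n:
        return list(res["term"])
    cut_key = (res["fdr"].iloc[n - 1], res["pvalue"].iloc[n - 1])
    keep = [
        i for i in range(len(res))
        if i < n or (res["fdr"].iloc[i], res["pvalue"].iloc[i]) == cut_key
    ]
    if len(keep) > n:
        logger.info("top_terms: %d terms tied at the cut; returning %d", len(keep) - n, len(keep))
    return list(res["term"].iloc[keep])


def simple_de(expr: ExpressionMatrix, logfc_threshold: float = 1.0,
              fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Two-group DE summary: logFC = mean(case) − mean(control), Welch t, BH.

    Expression values are assumed to be on the log2 scale, so the difference
    of group means is the log2 fold change.  A gene with zero variance in both
    groups gets p = 1 (logged).  The significance flag requires
    |logFC| > ``logfc_threshold`` and FDR < ``fdr_threshold``.
    """
    case = expr.samples("case")
    control = expr.samples("control")
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least 2 samples per group")
    x = expr.values[case].to_numpy(dtype=float)
    y = expr.values[control].to_numpy(dtype=float)
    logfc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(x, y, axis=1, equal_var=False)
    degenerate = (x.std(axis=1) == 0) & (y.std(axis=1) == 0)
    if degenerate.any():
        logger.info("simple_de: %d zero-variance genes assigned p=1", int(degenerate.sum()))
    pvals = np.where(np.isnan(pvals) | degenerate, 1.0, pvals)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    de = pd.DataFrame(
        {"logfc": logfc, "pvalue": pvals, "fdr": fdr},
        index=expr.values.index,
    )
    de["significant"] = (de["logfc"].abs() > logfc_threshold) & (de["fdr"] < fdr_threshold)
    de.index.name = "gene"
    de.attrs["provenance"] = "computed"
    return de
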