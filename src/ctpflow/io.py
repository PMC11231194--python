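"""Domain types and tabular/GMT readers and writers.

All pipeline stages exchange plain text files: TSV/CSV tables for compounds,
edges, differential-expression summaries and expression matrices, and GMT for
gene sets.  Gene identifiers live in a single namespace per run and are
case-normalized (upper-cased) exactly once, at load time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("ctpflow")

#: The nine screenable physicochemical / ADMET fields, in canonical order.
PROPERTY_FIELDS = (
    "mw", "n_hd", "n_ha", "logp", "n_rot", "ob", "caco2", "tpsa", "hepatotoxic",
)

_INT_FIELDS = {"n_hd", "n_ha", "n_rot"}


def normalize_gene(g: str) -> str:
    """Case-normalize a gene identifier (single namespace per run)."""
    return str(g).strip().upper()


def _delimiter(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass(frozen=True)
class PropertyVector:
    """The nine properties the rule-based screen inspects.

    ``ob`` is predicted human oral bioavailability in percent, ``caco2`` the
    predicted Caco-2 permeability on the supplied (log) scale, ``tpsa`` the
    topological polar surface area in Å².  Any field may be ``None`` (missing);
    the screen treats missing values conservatively.
    """

    mw: float | None = None
    n_hd: int | None = None
    n_ha: int | None = None
    logp: float | None = None
    n_rot: int | None = None
    ob: float | None = None
    caco2: float | None = None
    tpsa: float | None = None
    hepatotoxic: bool | None = None

    def get(self, name: str):
        if name not in PROPERTY_FIELDS:
            raise KeyError(f"unknown property {name!r}")
        return getattr(self, name)

    def missing_fields(self) -> list[str]:
        return [f for f in PROPERTY_FIELDS if getattr(self, f) is None]


@dataclass
class CompoundRecord:
    """One compound with its herb membership and screenable properties."""

    compound_id: str
    name: str
    herbs: frozenset[str]
    properties: PropertyVector
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValueError(f"compound {self.compound_id}: empty herb set")


@dataclass
class CTPNetwork:
    """Tripartite compound–target–pathogenic-gene network.

    Proteins are the union of predicted targets (T) and disease genes (P);
    genes in both are the essential common proteins (ECPs).  ``ct_edges`` maps
    (compound_id, target) to an optional prediction score; ``pp_edges`` holds
    undirected, deduplicated protein pairs as sorted tuples with no self-loops.
    """

    compounds: set[str]
    targets: set[str]
    pathogenic: set[str]
    ct_edges: dict[tuple[str, str], float | None]
    pp_edges: set[tuple[str, str]]

    @property
    def proteins(self) -> set[str]:
        return self.targets | self.pathogenic

    @property
    def ecp(self) -> set[str]:
        return self.targets & self.pathogenic

    def pp_neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {p: set() for p in self.proteins}
        for a, b in self.pp_edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def ct_degree(self) -> dict[str, int]:
        """Number of compounds predicted to hit each target."""
        deg = {t: 0 for t in self.targets}
        for (_, t) in self.ct_edges:
            deg[t] += 1
        return deg


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or GO terms) under one category label."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    category: str = "geneset"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out

    def membership_counts(self) -> dict[str, int]:
        """Per-gene number of sets the gene belongs to (n_k^p)."""
        counts: dict[str, int] = {}
        for members in self.sets.values():
            for g in members:
                counts[g] = counts.get(g, 0) + 1
        return counts


@dataclass
class ExpressionMatrix:
    """genes × samples expression values with case/control sample labels."""

    values: pd.DataFrame           # index: gene, columns: sample ids
    groups: pd.Series              # index: sample id, values: 'case'|'control'

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene rows in expression matrix")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    if s in ("", "nan", "na", "none"):
        return None
    raise ValueError(f"cannot parse boolean value {v!r}")


def _parse_num(v, as_int: bool):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip().lower() in ("", "nan", "na", "none"):
        return None
    x = float(v)
    if as_int:
        i = int(round(x))
        if i < 0:
            raise ValueError(f"negative count {v!r}")
        return i
    return x


def read_compound_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    herb_sep: str = ";",
) -> list[CompoundRecord]:
    """Read a compound property table into merged :class:`CompoundRecord` s.

    The table needs a ``compound_id`` column, either a ``herb`` column (one
    herb per row; rows with the same id are merged) or a ``herbs`` column
    (``herb_sep``-separated list), and the nine property columns named as in
    :data:`PROPERTY_FIELDS` (remappable through ``column_map``).  Rows sharing
    a ``compound_id`` must agree on every property; their herb sets are
    unioned into one record.
    """
    cmap = dict(column_map or {})

    def col(name: str) -> str:
        return cmap.get(name, name)

    df = pd.read_csv(path, sep=_delimiter(path), dtype={col("compound_id"): str})
    if col("compound_id") not in df.columns:
        raise ValueError(f"missing required column {col('compound_id')!r} in {path}")
    herb_mode = None
    if col("herb") in df.columns:
        herb_mode = "herb"
    elif col("herbs") in df.columns:
        herb_mode = "herbs"
    else:
        raise ValueError(f"missing required column 'herb' or 'herbs' in {path}")
    for f in PROPERTY_FIELDS:
        if col(f) not in df.columns:
            raise ValueError(f"missing required property column {col(f)!r} in {path}")

    records: dict[str, CompoundRecord] = {}
    n_merged = 0
    for _, row in df.iterrows():
        cid = str(row[col("compound_id")]).strip()
        if not cid:
            raise ValueError(f"empty compound_id in {path}")
        if herb_mode == "herb":
            herbs = frozenset({str(row[col("herb")]).strip()})
        else:
            herbs = frozenset(
                h.strip() for h in str(row[col("herbs")]).split(herb_sep) if h.strip()
            )
        kwargs = {}
        for f in PROPERTY_FIELDS:
            v = row[col(f)]
            kwargs[f] = _parse_bool(v) if f == "hepatotoxic" else _parse_num(v, f in _INT_FIELDS)
        props = PropertyVector(**kwargs)
        name = str(row[col("name")]) if col("name") in df.columns and not pd.isna(row[col("name")]) else cid
        smiles = None
        if col("smiles") in df.columns and not pd.isna(row[col("smiles")]):
            smiles = str(row[col("smiles")])
        if cid in records:
            prev = records[cid]
            if prev.properties != props:
                raise ValueError(
                    f"duplicate compound_id {cid!r} with conflicting properties in {path}"
                )
            records[cid] = CompoundRecord(
                compound_id=cid,
                name=prev.name,
                herbs=prev.herbs | herbs,
                properties=props,
                smiles=prev.smiles or smiles,
            )
            n_merged += 1
        else:
            records[cid] = CompoundRecord(cid, name, herbs, props, smiles)
    if n_merged:
        logger.info("read_compound_table: merged %d duplicate rows by compound_id", n_merged)
    return list(records.values())


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: r.compound_id):
        row = {
            "compound_id": r.compound_id,
            "name": r.name,
            "herbs": ";".join(sorted(r.herbs)),
        }
        for f in PROPERTY_FIELDS:
            v = r.properties.get(f)
            row[f] = "" if v is None else v
        row["smiles"] = r.smiles or ""
        rows.append(row)
    cols = ["compound_id", "name", "herbs", *PROPERTY_FIELDS, "smiles"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_delimiter(path), index=False)


def read_edge_list(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a two-column edge list (optional third ``score`` column).

    ``kind='ct'`` keeps compound ids verbatim and normalizes the target gene;
    ``kind='pp'`` normalizes both endpoints, drops self-loops (with a warning
    count) and deduplicates unordered pairs.  Returns columns
    ``source, target[, score]``.
    """
    if kind not in ("ct", "pp"):
        raise ValueError(f"kind must be 'ct' or 'pp', got {kind!r}")
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least two columns")
    out = pd.DataFrame({
        "source": df.iloc[:, 0].astype(str).str.strip(),
        "target": df.iloc[:, 1].astype(str).str.strip(),
    })
    for i, (s, t) in enumerate(zip(out["source"], out["target"]), start=2):
        if not s or not t or s.lower() == "nan" or t.lower() == "nan":
            raise ValueError(f"{path}: malformed row at line {i}")
    has_score = "score" in df.columns
    if has_score:
        out["score"] = pd.to_numeric(df["score"], errors="coerce")
    out["target"] = out["target"].map(normalize_gene)
    if kind == "pp":
        out["source"] = out["source"].map(normalize_gene)
        loops = out["source"] == out["target"]
        if loops.any():
            logger.warning("read_edge_list: dropped %d self-loop pp edges", int(loops.sum()))
            out = out[~loops]
        lo = out[["source", "target"]].min(axis=1)
        hi = out[["source", "target"]].max(axis=1)
        out = out.assign(source=lo, target=hi)
    out = out.drop_duplicates(subset=["source", "target"]).reset_index(drop=True)
    return out


def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene id per line (or first column of a table with header 'gene')."""
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.split("\t")[0].strip()
            if not g or g.lower() == "gene":
                continue
            genes.append(normalize_gene(g))
    seen: set[str] = set()
    out = []
    for g in genes:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\n")
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_gmt(path: str | Path, category: str = "geneset") -> GeneSetCollection:
    """Read a standard GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT line needs >=3 fields")
            name, desc, *genes = fields
            genes = [normalize_gene(g) for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: empty member list")
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, category=category)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table (gene, logfc, fdr[, pvalue])."""
    df = pd.read_csv(path, sep=_delimiter(path))
    for c in ("gene", "logfc", "fdr"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    df["gene"] = df["gene"].map(normalize_gene)
    if df["gene"].duplicated().any():
        raise ValueError(f"{path}: duplicate genes in DE table")
    bad = (df["fdr"] < 0) | (df["fdr"] > 1)
    if bad.any():
        raise ValueError(f"{path}: fdr outside [0,1]")
    df = df.set_index("gene")
    df.attrs["provenance"] = "loaded"
    return df


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.reset_index().rename(columns={"index": "gene"}).to_csv(
        path, sep=_delimiter(path), index=False
    )


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep=_delimiter(matrix_path), index_col=0)
    values.index = [normalize_gene(g) for g in values.index]
    gdf = pd.read_csv(groups_path, sep=_delimiter(groups_path))
    if "sample" not in gdf.columns or "group" not in gdf.columns:
        raise ValueError(f"{groups_path}: needs 'sample' and 'group' columns")
    groups = gdf.set_index("sample")["group"]
    bad = set(groups.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"{groups_path}: unknown group labels {sorted(bad)}")
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path) -> None:
    expr.values.to_csv(matrix_path, sep=_delimiter(matrix_path), index_label="gene")
    expr.groups.rename_axis("sample").rename("group").reset_index().to_csv(
        groups_path, sep=_delimiter(groups_path), index=False
    )


# ---------------------------------------------------------------------------
# network node/edge table export (round-trippable)
# ---------------------------------------------------------------------------

def write_network(
    net: CTPNetwork,
    nodes_path: str | Path,
    edges_path: str | Path,
    scores: Mapping[str, float] | None = None,
) -> None:
    """Write node and edge tables; ``scores`` attaches per-target s_moo values.

    The node table has ``id, node_type, role, s_moo`` where role is
    ``target`` / ``pathogenic`` / ``both`` for proteins and empty for
    compounds.  Reading the pair back reconstructs an equal network.
    """
    node_rows = []
    for c in sorted(net.compounds):
        node_rows.append({"id": c, "node_type": "compound", "role": "", "s_moo": ""})
    for p in sorted(net.proteins):
        if p in net.targets and p in net.pathogenic:
            role = "both"
        elif p in net.targets:
            role = "target"
        else:
            role = "pathogenic"
        s = "" if scores is None or p not in scores else repr(float(scores[p]))
        node_rows.append({"id": p, "node_type": "protein", "role": role, "s_moo": s})
    pd.DataFrame(node_rows, columns=["id", "node_type", "role", "s_moo"]).to_csv(
        nodes_path, sep=_delimiter(nodes_path), index=False
    )

    edge_rows = []
    for (c, t) in sorted(net.ct_edges):
        sc = net.ct_edges[(c, t)]
        edge_rows.append({
            "source": c, "target": t, "edge_type": "ct",
            "score": "" if sc is None else repr(float(sc)),
        })
    for (a, b) in sorted(net.pp_edges):
        edge_rows.append({"source": a, "target": b, "edge_type": "pp", "score": ""})
    pd.DataFrame(edge_rows, columns=["source", "target", "edge_type", "score"]).to_csv(
        edges_path, sep=_delimiter(edges_path), index=False
    )


def read_network(
    nodes_path: str | Path, edges_path: str | Path
) -> tuple[CTPNetwork, dict[str, float] | None]:
    """Inverse of :func:`write_network`; returns (network, s_moo scores or None)."""
    nodes = pd.read_csv(nodes_path, sep=_delimiter(nodes_path), dtype=str)
    edges = pd.read_csv(edges_path, sep=_delimiter(edges_path), dtype=str)
    compounds: set[str] = set()
    targets: set[str] = set()
    pathogenic: set[str] = set()
    scores: dict[str, float] = {}
    for _, row in nodes.iterrows():
        nid = str(row["id"])
        if row["node_type"] == "compound":
            compounds.add(nid)
            continue
        role = row["role"]
        if role in ("target", "both"):
            targets.add(nid)
        if role in ("pathogenic", "both"):
            pathogenic.add(nid)
        s = row.get("s_moo")
        if isinstance(s, str) and s.strip():
            scores[nid] = float(s)
    ct_edges: dict[tuple[str, str], float | None] = {}
    pp_edges: set[tuple[str, str]] = set()
    for _, row in edges.iterrows():
        s, t = str(row["source"]), str(row["target"])
        if row["edge_type"] == "ct":
            sc = row.get("score")
            ct_edges[(s, t)] = float(sc) if isinstance(sc, str) and sc.strip() else None
        else:
            pp_edges.add((min(s, t), max(s, t)))
    net = CTPNetwork(
        compounds=compounds, targets=targets, pathogenic=pathogenic,
        ct_edges=ct_edges, pp_edges=pp_edges,
    )
    return net, (scores or None)
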