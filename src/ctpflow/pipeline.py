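"""End-to-end orchestration: simulate/ingest → screen → network → optimize →
intensity → combination selection → pathway ranking → enrichment → model
comparison, under a single seeded configuration with plain-file intermediates
and a machine-readable run report.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .enrich import enrich, simple_de
from .intensity import (
    compound_intensity,
    cumulative_ranking,
    gene_intensity,
    pathway_intensity,
    select_combination,
)
from .io import (
    read_compound_table,
    read_de_table,
    read_edge_list,
    read_expression,
    read_gene_list,
    read_gmt,
    write_de_table,
    write_network,
)
from .network import build_ctp, network_stats
from .optimize import CENTRALITY_MODELS, compare_models, optimize_centrality, optimize_moo
from .screen import ScreenRule, default_rules, screen
from .synthetic import GeneratorConfig, generate, make_worked_toy, write_bundle


class PipelineError(RuntimeError):
    """A stage-level failure; the message names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    preset: str | None = None                 # 'toy' | 'default' | None
    inputs: dict[str, str] = field(default_factory=dict)
    generator: dict[str, Any] = field(default_factory=dict)
    rules: list[dict] | None = None
    keep_quantile: float = 0.5
    threshold: float = 0.9
    solver: str = "greedy"
    exact_limit: int = 15
    min_term_size: int = 10
    fdr: float = 0.05
    top_pathways: int = 20
    compare: bool = True

    def echo(self) -> dict:
        d = asdict(self)
        d.pop("out_dir")          # absolute paths must not leak into the report
        return d


def preset_config(preset: str, seed: int, out_dir: str) -> RunConfig:
    if preset == "toy":
        return RunConfig(seed=seed, out_dir=out_dir, preset="toy",
                         keep_quantile=1.0, solver="exact", min_term_size=1)
    if preset in ("default", "benchmark"):
        return RunConfig(seed=seed, out_dir=out_dir, preset="default")
    raise ValueError(f"unknown preset {preset!r}")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw or "out_dir" not in raw:
        raise ValueError(f"{path}: config needs 'seed' and 'out_dir'")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def _rules_from_config(cfg: RunConfig) -> list[ScreenRule]:
    if cfg.rules is None:
        return default_rules()
    return [ScreenRule(r["prop"], r["op"], r["threshold"]) for r in cfg.rules]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        return [_jsonify(v) for v in items]
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return None
    if hasattr(obj, "item"):
        return _jsonify(obj.item())
    return obj


def _require(inputs: dict[str, str], key: str, stage: str) -> str:
    if key not in inputs:
        raise PipelineError(stage, f"missing input path {key!r} in config")
    p = inputs[key]
    if not Path(p).exists():
        raise PipelineError(stage, f"input file not found: {p}")
    return p


def run_all(cfg: RunConfig) -> dict:
    """Run every stage, write all artifacts under ``cfg.out_dir``, return the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config": _jsonify(cfg.echo()),
        "warnings": [],
    }

    # --- stage: simulate / ingest -----------------------------------------
    toy = None
    de = None
    expression = None
    gobp = None
    if cfg.preset == "toy":
        toy = make_worked_toy(out / "inputs")
        compounds = toy.compounds
        ct_edges, pathogenic, ppi = toy.ct_edges, toy.pathogenic, toy.ppi
        pathways = toy.pathways
        de = toy.de
        expression = toy.expression
    elif cfg.preset in ("default", "benchmark"):
        gen = GeneratorConfig(seed=cfg.seed, **cfg.generator)
        bundle = generate(gen)
        write_bundle(bundle, out / "inputs")
        compounds = bundle.compounds
        ct_edges, pathogenic, ppi = bundle.ct_edges, bundle.pathogenic, bundle.ppi
        pathways, gobp = bundle.pathways, bundle.gobp
        expression = bundle.expression
    else:
        compounds = read_compound_table(_require(cfg.inputs, "compounds", "ingest"))
        ct_edges = read_edge_list(_require(cfg.inputs, "ct_edges", "build-net"), "ct")
        pathogenic = read_gene_list(_require(cfg.inputs, "pathogenic", "build-net"))
        ppi = read_edge_list(_require(cfg.inputs, "ppi", "build-net"), "pp")
        pathways = read_gmt(_require(cfg.inputs, "pathways", "pathway-rank"), "pathway")
        if "gobp" in cfg.inputs:
            gobp = read_gmt(_require(cfg.inputs, "gobp", "enrich"), "gobp")
        if "de_table" in cfg.inputs:
            de = read_de_table(_require(cfg.inputs, "de_table", "optimize"))
        if "expression" in cfg.inputs:
            expression = read_expression(
                _require(cfg.inputs, "expression", "compare-models"),
                _require(cfg.inputs, "sample_groups", "compare-models"),
            )

    # --- stage: screen -----------------------------------------------------
    try:
        sreport = screen(compounds, _rules_from_config(cfg))
    except ValueError as e:
        raise PipelineError("screen", str(e)) from e
    pd.DataFrame({"compound_id": sreport.passed}).to_csv(
        out / "pass_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"compound_id": c, "violations": ";".join(v)} for c, v in sorted(sreport.violations.items())]
    ).to_csv(out / "violations.tsv", sep="\t", index=False)
    report["screen"] = {
        "n_input": sreport.n_input,
        "n_pass": sreport.n_pass,
        "n_shared": sreport.n_shared,
        "per_herb": sreport.per_herb,
    }

    # --- stage: build-net --------------------------------------------------
    try:
        net = build_ctp(sreport.passed, ct_edges, pathogenic, ppi)
    except ValueError as e:
        raise PipelineError("build-net", str(e)) from e
    write_network(net, out / "ctp_nodes.tsv", out / "ctp_edges.tsv")
    report["network"] = network_stats(net).to_dict()

    # --- stage: differential expression -----------------------------------
    if de is None and expression is not None:
        try:
            de = simple_de(expression)
        except ValueError as e:
            raise PipelineError("de", str(e)) from e
    if de is not None:
        write_de_table(de, out / "de_table.tsv")
        report["de"] = {
            "provenance": de.attrs.get("provenance", "loaded"),
            "n_genes": int(len(de)),
            "n_significant": int(de["significant"].sum()) if "significant" in de else None,
        }

    # --- stage: optimize ---------------------------------------------------
    try:
        opt = optimize_moo(net, de=de, keep_quantile=cfg.keep_quantile)
    except ValueError as e:
        raise PipelineError("optimize", str(e)) from e
    write_network(opt.network, out / "optimized_nodes.tsv", out / "optimized_edges.tsv",
                  scores=opt.scores)
    report["optimized"] = {
        "model": opt.model,
        "keep_quantile": cfg.keep_quantile,
        **network_stats(opt.network).to_dict(),
    }

    # --- stage: intensity + select ----------------------------------------
    try:
        gi = gene_intensity(opt)
        ci = compound_intensity(opt, gi)
        sel = select_combination(ci, gi, threshold=cfg.threshold, solver=cfg.solver,
                                 exact_limit=cfg.exact_limit)
    except ValueError as e:
        raise PipelineError("intensity", str(e)) from e
    gi.table.reset_index().to_csv(out / "gene_intensity.tsv", sep="\t", index=False)
    ci.table.reset_index().to_csv(out / "compound_intensity.tsv", sep="\t", index=False)
    cum = cumulative_ranking(ci, gi)
    cum["threshold_line"] = cfg.threshold * sel.total
    cum.to_csv(out / "cumulative_intensity.tsv", sep="\t", index=False)
    report["selection"] = {
        "solver": sel.solver,
        "threshold": sel.threshold,
        "total_intensity": sel.total,
        "selected": sorted(sel.selected),
        "selected_size": sel.selected_size,
        "selected_intensity": sel.selected_intensity,
    }

    # --- stage: pathway-rank ----------------------------------------------
    pw = pathway_intensity(gi, pathways, top=cfg.top_pathways)
    pw.to_csv(out / "pathway_intensity.tsv", sep="\t", index=False)
    report["top_pathways"] = [
        {"pathway": r.pathway, "intensity": r.intensity}
        for r in pw.itertuples(index=False)
    ]

    # --- stage: enrich -----------------------------------------------------
    enr_report = {}
    try:
        kegg_res = enrich(net.ecp, pathways, min_term_size=cfg.min_term_size,
                          fdr_threshold=cfg.fdr)
        kegg_res.to_csv(out / "enrichment_pathways.tsv", sep="\t", index=False)
        enr_report["pathways_significant"] = int(kegg_res["significant"].sum()) if len(kegg_res) else 0
        if gobp is not None:
            gobp_res = enrich(net.ecp, gobp, min_term_size=cfg.min_term_size,
                              fdr_threshold=cfg.fdr)
            gobp_res.to_csv(out / "enrichment_gobp.tsv", sep="\t", index=False)
            enr_report["gobp_significant"] = int(gobp_res["significant"].sum()) if len(gobp_res) else 0
    except ValueError as e:
        raise PipelineError("enrich", str(e)) from e
    report["enrichment"] = enr_report

    # --- stage: compare-models --------------------------------------------
    if cfg.compare:
        try:
            opts = [opt] + [
                optimize_centrality(net, m, keep_quantile=cfg.keep_quantile)
                for m in CENTRALITY_MODELS
            ]
            comp = compare_models(
                opts, net.ecp, de=de, expr=expression,
                pathways=pathways, gobp=gobp,
                min_term_size=cfg.min_term_size,
            )
            comp.reset_index().to_csv(out / "model_comparison.tsv", sep="\t", index=False)
            report["comparison"] = _jsonify(comp.to_dict(orient="index"))
        except ValueError as e:
            raise PipelineError("compare-models", str(e)) from e

    # --- report + config snapshot -----------------------------------------
    (out / "config_snapshot.json").write_text(
        json.dumps(_jsonify(cfg.echo()), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    (out / "report.json").write_text(
        json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return report
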