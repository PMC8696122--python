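"""End-to-end orchestration: identify -> DE -> targets -> ceRNA -> enrichment.

A single YAML config names the input files and threshold bundle; every stage
writes its TSV/GraphML artifacts and the run ends with one report (JSON and
human-readable) carrying the headline numbers: lncRNA category counts and
percentages, per-comparison DE up/down counts with intersections, the
paper-convention sum and the deduplicated union, target-network edge counts
per mechanism, ceRNA node counts, and significant gene-set counts.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .annotation import ClassifyParams, classify_all, summarize_categories
from .cerna import (
    build_cerna_triplets,
    export_cerna_network,
    negative_coexpression_pairs,
)
from .enrichment import GeneSetCollection, gsea, ora_table, read_gmt, significant_sets
from .expression import (
    ExpressionMatrix,
    STAGES,
    compute_fpkm,
    differential_expression,
    summarize_de,
)
from .models import ValidationError
from .targets import antisense_pairs, cis_pairs, edges_to_frame, export_target_network, trans_pairs

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths plus the full threshold bundle (defaults are the study's)."""

    annotation: str = ""
    mrna_counts: str = ""
    lncrna_counts: str = ""
    mirna_counts: str = ""
    lengths: str = ""
    design: str = ""
    mirna_targets: str = ""
    gene_sets: str = ""
    out_dir: str = "lncnet_out"
    seed: int = 0
    log2fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    mirna_p_threshold: float = 0.05
    cis_window: int = 10_000
    trans_r_threshold: float = 0.9
    scc_threshold: float = -0.7
    pcc_threshold: float = 0.9
    sponge_alpha: float = 0.05
    nes_threshold: float = 1.0
    gsea_p_threshold: float = 0.05
    gsea_q_threshold: float = 0.25
    bidirectional_tss_window: int = 1_000
    intergenic_min_distance: int = 5_000
    de_only_targets: bool = True
    run_gsea: bool = False
    gsea_comparison: Optional[str] = None
    n_perm: int = 1000

    REQUIRED_PATHS = (
        "annotation",
        "mrna_counts",
        "lncrna_counts",
        "mirna_counts",
        "lengths",
        "design",
        "mirna_targets",
        "gene_sets",
    )


def validate_config(path: str) -> Tuple[Optional[PipelineConfig], List[str], List[str]]:
    """Parse a YAML config, reporting *every* violation (not fail-fast).

    Returns (config-or-None, errors, warnings); the config is None only when
    the file itself cannot be read or parsed.
    """
    errors: List[str] = []
    warnings: List[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config: {exc}"], []
    if not isinstance(raw, dict):
        return None, ["config must be a YAML mapping"], []

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in sorted(set(raw) - known):
        warnings.append(f"unknown key {key!r} ignored")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})

    for name in PipelineConfig.REQUIRED_PATHS:
        value = getattr(cfg, name)
        if not value:
            errors.append(f"required path {name!r} is missing")
        elif not os.path.exists(value):
            errors.append(f"{name}: no such file {value!r}")
    if cfg.scc_threshold >= 0:
        errors.append("scc_threshold must be negative")
    if not 0 < cfg.pcc_threshold <= 1:
        errors.append("pcc_threshold must lie in (0, 1]")
    if not 0 < cfg.trans_r_threshold <= 1:
        errors.append("trans_r_threshold must lie in (0, 1]")
    if cfg.cis_window <= 0:
        errors.append("cis_window must be positive")
    for name in ("fdr_threshold", "mirna_p_threshold", "sponge_alpha",
                 "gsea_p_threshold", "gsea_q_threshold"):
        v = getattr(cfg, name)
        if not 0 < v <= 1:
            errors.append(f"{name} must lie in (0, 1]")
    if cfg.log2fc_threshold < 0:
        errors.append("log2fc_threshold must be >= 0")
    return cfg, errors, warnings


def _stage(report: Dict, name: str, t0: float) -> None:
    elapsed = time.perf_counter() - t0
    logger.info("stage %s finished in %.2fs", name, elapsed)
    report.setdefault("stages", {})[name] = round(elapsed, 3)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage in order and write artifacts + report.

    Raises :class:`PipelineError` naming the failing stage; partial outputs
    are retained alongside a ``FAILED`` marker file.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report: Dict = {"thresholds": {
        "log2fc": config.log2fc_threshold,
        "fdr": config.fdr_threshold,
        "mirna_p": config.mirna_p_threshold,
        "cis_window": config.cis_window,
        "trans_r": config.trans_r_threshold,
        "scc": config.scc_threshold,
        "pcc": config.pcc_threshold,
        "sponge_alpha": config.sponge_alpha,
        "nes": config.nes_threshold,
        "gsea_p": config.gsea_p_threshold,
        "gsea_q": config.gsea_q_threshold,
    }, "seed": config.seed}
    logger.info("thresholds: %s", report["thresholds"])
    stage = "annotation"
    try:
        report.update(_run_stages(config, report))
    except Exception as exc:
        stage = getattr(exc, "lncnet_stage", stage)
        with open(os.path.join(config.out_dir, "FAILED"), "w") as fh:
            fh.write(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
        fh.write(render_report(report))
    return report


class PipelineError(RuntimeError):
    pass


def _tag(stage: str, exc: Exception) -> Exception:
    exc.lncnet_stage = stage
    return exc


def _run_stages(config: PipelineConfig, report: Dict) -> Dict:
    out: Dict = {}
    od = config.out_dir

    # --- stage 1: annotation / classification -----------------------------
    t0 = time.perf_counter()
    try:
        genes, lncs = lio.read_gtf(config.annotation)
        params = ClassifyParams(
            bidirectional_tss_window=config.bidirectional_tss_window,
            intergenic_min_distance=config.intergenic_min_distance,
        )
        records = classify_all(lncs, genes, params)
        counts, pct = summarize_categories(records)
        pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript.id,
                    "category": r.category,
                    "nearest_gene": r.nearest_gene_id or "",
                    "distance": "" if r.distance_bp is None else r.distance_bp,
                }
                for r in records
            ]
        ).to_csv(os.path.join(od, "lncrna_classification.tsv"), sep="\t", index=False)
        out["lncrna_categories"] = {"counts": counts, "percent": pct,
                                    "total": len(records)}
    except Exception as exc:
        raise _tag("annotation", exc)
    _stage(report, "annotation", t0)

    # --- stage 2: differential expression ---------------------------------
    t0 = time.perf_counter()
    try:
        lengths = lio.read_lengths(config.lengths)
        design = lio.read_design(config.design)
        matrices = {
            "mRNA": lio.read_matrix(config.mrna_counts),
            "lncRNA": lio.read_matrix(config.lncrna_counts),
            "miRNA": lio.read_matrix(config.mirna_counts),
        }
        stages_present = [s for s in STAGES if s in set(design["stage"])]
        comparisons = [
            (stages_present[i], stages_present[i + 1])
            for i in range(len(stages_present) - 1)
        ]
        de_tables: Dict[Tuple[str, str], pd.DataFrame] = {}
        out["de"] = {}
        for tissue, tdesign in design.groupby("tissue"):
            for cls, mat in matrices.items():
                em = ExpressionMatrix(
                    mat[tdesign.index], kind="counts", lengths=lengths
                )
                table = differential_expression(
                    em, tdesign, comparisons, feature_class=cls
                )
                de_tables[(tissue, cls)] = table
                out["de"].setdefault(tissue, {})[cls] = summarize_de(table)
        pd.concat(
            [t.assign(tissue=tissue) for (tissue, _), t in de_tables.items()],
            ignore_index=True,
        ).to_csv(os.path.join(od, "de_results.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise _tag("differential_expression", exc)
    _stage(report, "differential_expression", t0)

    # --- stage 3: lncRNA target assignment --------------------------------
    t0 = time.perf_counter()
    try:
        out["targets"] = {}
        fpkm = {
            cls: compute_fpkm(
                ExpressionMatrix(mat, kind="counts", lengths=lengths)
            ).values
            for cls, mat in matrices.items()
        }
        for tissue, tdesign in design.groupby("tissue"):
            if config.de_only_targets:
                de_lnc = set(
                    de_tables[(tissue, "lncRNA")].query("call != 'ns'")["feature_id"]
                )
                de_mrna = set(
                    de_tables[(tissue, "mRNA")].query("call != 'ns'")["feature_id"]
                )
            else:
                de_lnc = {t.id for t in lncs}
                de_mrna = {g.id for g in genes}
            sel_lncs = [t for t in lncs if t.id in de_lnc]
            sel_genes = [g for g in genes if g.id in de_mrna]
            edges = antisense_pairs(sel_lncs, sel_genes)
            edges += cis_pairs(sel_lncs, sel_genes, window=config.cis_window)
            cols = tdesign.index
            lnc_expr = fpkm["lncRNA"].loc[sorted(de_lnc & set(fpkm["lncRNA"].index)), cols]
            mrna_expr = fpkm["mRNA"].loc[sorted(de_mrna & set(fpkm["mRNA"].index)), cols]
            if len(lnc_expr) and len(mrna_expr):
                edges += trans_pairs(lnc_expr, mrna_expr, threshold=config.trans_r_threshold)
            n_nodes, n_edges = export_target_network(
                edges,
                os.path.join(od, f"targets_{tissue}.graphml"),
                os.path.join(od, f"targets_{tissue}.tsv"),
            )
            mech = edges_to_frame(edges)["mechanism"].value_counts().to_dict()
            out["targets"][tissue] = {
                "nodes": n_nodes,
                "edges": n_edges,
                "by_mechanism": {m: int(mech.get(m, 0)) for m in ("antisense", "cis", "trans")},
            }
    except Exception as exc:
        raise _tag("targets", exc)
    _stage(report, "targets", t0)

    # --- stage 4: ceRNA network -------------------------------------------
    t0 = time.perf_counter()
    try:
        targets_tbl = lio.read_mirna_targets(config.mirna_targets)
        out["cerna"] = {}
        for tissue, tdesign in design.groupby("tissue"):
            cols = tdesign.index
            mrna_pairs = negative_coexpression_pairs(
                fpkm["mRNA"][cols], fpkm["miRNA"][cols], targets_tbl,
                threshold=config.scc_threshold,
            )
            lnc_pairs = negative_coexpression_pairs(
                fpkm["lncRNA"][cols], fpkm["miRNA"][cols], targets_tbl,
                threshold=config.scc_threshold,
            )
            triplets = build_cerna_triplets(
                mrna_pairs,
                lnc_pairs,
                fpkm["mRNA"][cols],
                fpkm["lncRNA"][cols],
                universe_size=len(fpkm["miRNA"].index),
                alpha=config.sponge_alpha,
                pcc_threshold=config.pcc_threshold,
            )
            out["cerna"][tissue] = export_cerna_network(
                triplets,
                os.path.join(od, f"cerna_{tissue}.graphml"),
                os.path.join(od, f"cerna_{tissue}.tsv"),
            )
    except Exception as exc:
        raise _tag("cerna", exc)
    _stage(report, "cerna", t0)

    # --- stage 5: enrichment ----------------------------------------------
    t0 = time.perf_counter()
    try:
        collection = read_gmt(config.gene_sets)
        universe = set(matrices["mRNA"].index)
        out["enrichment"] = {}
        for tissue, _ in design.groupby("tissue"):
            table = de_tables[(tissue, "mRNA")]
            per_comp = {}
            for comp, grp in table.groupby("comparison"):
                de_ids = set(grp.query("call != 'ns'")["feature_id"])
                ora = ora_table(de_ids, collection, universe)
                ora.to_csv(
                    os.path.join(od, f"ora_{tissue}_{comp}.tsv"), sep="\t", index=False
                )
                per_comp[comp] = int((ora["p"] < 0.05).sum())
            out["enrichment"][tissue] = {"ora_significant": per_comp}
        if config.run_gsea:
            tissue = sorted(design["tissue"].unique())[0]
            tdesign = design[design["tissue"] == tissue]
            comp = config.gsea_comparison or f"{STAGES[0]}_vs_{STAGES[1]}"
            a, b = comp.split("_vs_")
            cols_a = list(tdesign.index[tdesign["stage"] == a])
            cols_b = list(tdesign.index[tdesign["stage"] == b])
            res = gsea(
                fpkm["mRNA"][cols_a + cols_b], cols_a, cols_b, collection,
                n_perm=config.n_perm, seed=config.seed,
            )
            res.to_csv(os.path.join(od, f"gsea_{tissue}_{comp}.tsv"), sep="\t", index=False)
            sig = significant_sets(
                res, config.nes_threshold, config.gsea_p_threshold, config.gsea_q_threshold
            )
            out["enrichment"]["gsea"] = {
                "tissue": tissue, "comparison": comp, "significant": int(len(sig)),
            }
    except Exception as exc:
        raise _tag("enrichment", exc)
    _stage(report, "enrichment", t0)
    return out


def render_report(report: Dict) -> str:
    """Human-readable summary of the JSON report."""
    lines = ["lncnet pipeline report", "=" * 22, ""]
    cat = report.get("lncrna_categories", {})
    if cat:
        lines.append(f"lncRNAs classified: {cat['total']}")
        for c, n in cat["counts"].items():
            pct = cat["percent"].get(c)
            lines.append(f"  {c:18s} {n:6d}" + (f"  ({pct}%)" if pct is not None else ""))
        lines.append("")
    for tissue, classes in report.get("de", {}).items():
        lines.append(f"[{tissue}] differential expression")
        for cls, summ in classes.items():
            for comp, c in summ["per_comparison"].items():
                lines.append(
                    f"  {cls:7s} {comp}: {c['total']} DE ({c['up']} up, {c['down']} down)"
                )
            lines.append(
                f"  {cls:7s} sum={summ['sum']} union={summ['union']} "
                f"intersections={summ['intersection']}"
            )
        lines.append("")
    for tissue, t in report.get("targets", {}).items():
        bm = t["by_mechanism"]
        lines.append(
            f"[{tissue}] target network: {t['edges']} edges "
            f"(antisense {bm['antisense']}, cis {bm['cis']}, trans {bm['trans']})"
        )
    for tissue, c in report.get("cerna", {}).items():
        if tissue == "gsea":
            continue
        lines.append(
            f"[{tissue}] ceRNA network: {c['n_triplets']} triplets over "
            f"{c['n_lncrna']} lncRNAs, {c['n_mirna']} miRNAs, {c['n_mrna']} mRNAs"
        )
    enr = report.get("enrichment", {})
    for tissue, e in enr.items():
        if tissue == "gsea":
            lines.append(
                f"GSEA [{e['tissue']} {e['comparison']}]: {e['significant']} significant sets"
            )
        else:
            lines.append(f"[{tissue}] ORA significant sets per comparison: "
                         f"{e['ora_significant']}")
    lines.append("")
    return "\n".join(lines)
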