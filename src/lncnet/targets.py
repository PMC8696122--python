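"""lncRNA target-gene assignment by antisense, cis and trans mechanisms.

* antisense: >=1 bp exonic overlap with a gene on the opposite strand
  (evidence = overlap bp);
* cis: non-overlapping gene within < 10 kb up- or downstream
  (evidence = gap bp, strict ``< window``);
* trans: |Pearson r| >= 0.9 between the lncRNA and gene expression profiles
  across all samples of one tissue (evidence = r, sign recorded).
"""
from __future__ import annotations

import logging
from typing import Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import exonic_overlap_bp, span_gap
from .models import GeneModel, TargetEdge, TranscriptModel, ValidationError
from .stats import pairwise_pearson

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 10_000
TRANS_R_THRESHOLD = 0.9


def antisense_pairs(
    lncs: Iterable[TranscriptModel], genes: Sequence[GeneModel]
) -> List[TargetEdge]:
    """Opposite-strand exonic-overlap edges."""
    edges = []
    for lnc in lncs:
        for g in genes:
            if g.chrom != lnc.chrom or g.strand == lnc.strand:
                continue
            bp = exonic_overlap_bp(lnc, g)
            if bp >= 1:
                edges.append(TargetEdge(lnc.id, g.id, "antisense", float(bp)))
    return edges


def cis_pairs(
    lncs: Iterable[TranscriptModel],
    genes: Sequence[GeneModel],
    window: int = CIS_WINDOW_BP,
) -> List[TargetEdge]:
    """Neighbourhood edges: span gap < ``window`` bp, spans disjoint.

    Overlapping lncRNA/gene pairs are the province of the antisense /
    sense-overlap logic and are excluded here.
    """
    if window <= 0:
        raise ValidationError("cis window must be positive")
    edges = []
    for lnc in lncs:
        for g in genes:
            if g.chrom != lnc.chrom:
                continue
            if min(lnc.end, g.end) > max(lnc.start, g.start):  # overlap
                continue
            gap = span_gap(lnc.span, g.span)
            if gap < window:
                edges.append(TargetEdge(lnc.id, g.id, "cis", float(gap)))
    return edges


def trans_pairs(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    threshold: float = TRANS_R_THRESHOLD,
) -> List[TargetEdge]:
    """Co-expression edges with |Pearson r| >= ``threshold`` (inclusive).

    Both matrices must share sample columns (>= 3 samples).  Zero-variance
    profiles are skipped with a warning.
    """
    if list(lnc_expr.columns) != list(gene_expr.columns):
        common = lnc_expr.columns.intersection(gene_expr.columns)
        if len(common) < 3:
            raise ValidationError("matrices must share >= 3 sample columns")
        lnc_expr = lnc_expr[common]
        gene_expr = gene_expr[common]
    if lnc_expr.shape[1] < 3:
        raise ValidationError("need >= 3 samples for trans correlation")
    r = pairwise_pearson(lnc_expr.to_numpy(float), gene_expr.to_numpy(float))
    n_nan = int(np.isnan(r).any(axis=1).sum())
    if n_nan:
        logger.warning("%d profile pair(s) with undefined correlation skipped", n_nan)
    edges = []
    ii, jj = np.where(np.abs(r) >= threshold)
    for i, j in zip(ii, jj):
        edges.append(
            TargetEdge(
                str(lnc_expr.index[i]),
                str(gene_expr.index[j]),
                "trans",
                float(r[i, j]),
                sign="positive" if r[i, j] >= 0 else "negative",
            )
        )
    return edges


def build_target_network(edges: Iterable[TargetEdge]) -> nx.MultiGraph:
    """Bipartite lncRNA/gene graph; parallel mechanism edges are retained."""
    g = nx.MultiGraph()
    for e in edges:
        g.add_node(e.lncrna_id, node_type="lncRNA", bipartite=0)
        g.add_node(e.gene_id, node_type="gene", bipartite=1)
        g.add_edge(
            e.lncrna_id,
            e.gene_id,
            key=e.mechanism,
            mechanism=e.mechanism,
            evidence=e.evidence,
            sign=e.sign or "",
        )
    return g


def edges_to_frame(edges: Iterable[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": e.lncrna_id,
                "gene_id": e.gene_id,
                "mechanism": e.mechanism,
                "evidence": e.evidence,
                "sign": e.sign or "",
            }
            for e in edges
        ],
        columns=["lncrna_id", "gene_id", "mechanism", "evidence", "sign"],
    )


def export_target_network(
    edges: Sequence[TargetEdge], graphml_path: str, tsv_path: str
) -> Tuple[int, int]:
    """Write GraphML + edge-list TSV; returns (n_nodes, n_edges)."""
    g = build_target_network(edges)
    nx.write_graphml(g, graphml_path)
    edges_to_frame(edges).to_csv(tsv_path, sep="\t", index=False)
    return g.number_of_nodes(), g.number_of_edges()
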