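"""Competing-endogenous-RNA (ceRNA) triplet inference.

An mRNA and a lncRNA form a ceRNA pair when (i) each is a predicted target
of, and strongly negatively co-expressed with (Spearman rho < -0.7), at least
one shared miRNA, (ii) the mRNA and lncRNA are strongly positively
co-expressed (Pearson r > 0.9), and (iii) the number of shared sponged
miRNAs is larger than expected by chance under a hypergeometric null
(upper-tail p < 0.05).  All inequalities are strict.

The hypergeometric universe defaults to the set of miRNAs present in the
miRNA expression matrix; K and n count each feature's *retained* (post-SCC
filter) miRNA partners.
"""
from __future__ import annotations

import itertools
import logging
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .models import CeRNATriplet, ValidationError
from .stats import hypergeom_tail, pearson_cc, spearman_cc

logger = logging.getLogger(__name__)

SCC_THRESHOLD = -0.7
PCC_THRESHOLD = 0.9
SPONGE_ALPHA = 0.05


def sponge_hypergeom_test(M: int, K: int, n: int, k: int) -> float:
    """Shared-sponge significance: P(X >= k) for X ~ Hypergeom(M, K, n).

    ``M`` — miRNA universe size; ``K`` / ``n`` — miRNA-partner counts of the
    two features; ``k`` — shared partners.
    """
    return hypergeom_tail(M, K, n, k)


def negative_coexpression_pairs(
    feature_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    mirna_targets: pd.DataFrame,
    threshold: float = SCC_THRESHOLD,
) -> pd.DataFrame:
    """(feature, miRNA) pairs that are predicted targets AND have SCC < threshold.

    ``mirna_targets`` must have columns ``mirna_id`` and ``target_id``.
    Returns a frame with columns mirna_id, feature_id, scc.
    """
    rows = []
    for mirna_id, target_id in mirna_targets[["mirna_id", "target_id"]].itertuples(
        index=False
    ):
        if target_id not in feature_expr.index:
            continue
        if mirna_id not in mirna_expr.index:
            logger.warning("miRNA %s absent from expression; pair skipped", mirna_id)
            continue
        rho = spearman_cc(
            feature_expr.loc[target_id].to_numpy(float),
            mirna_expr.loc[mirna_id].to_numpy(float),
        )
        if np.isnan(rho):
            logger.warning("undefined SCC for (%s, %s); skipped", target_id, mirna_id)
            continue
        if rho < threshold:
            rows.append({"mirna_id": mirna_id, "feature_id": target_id, "scc": rho})
    return pd.DataFrame(rows, columns=["mirna_id", "feature_id", "scc"])


def build_cerna_triplets(
    mrna_mirna_pairs: pd.DataFrame,
    lncrna_mirna_pairs: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    expr_lncrna: pd.DataFrame,
    universe_size: int,
    alpha: float = SPONGE_ALPHA,
    pcc_threshold: float = PCC_THRESHOLD,
) -> List[CeRNATriplet]:
    """Join SCC-filtered pair lists on shared miRNAs into ceRNA triplets.

    ``universe_size`` is the hypergeometric M (expressed miRNAs by default);
    K and n are each feature's retained-pair miRNA counts.
    """
    if universe_size <= 0:
        raise ValidationError("empty miRNA universe")

    def _index(pairs: pd.DataFrame) -> Dict[str, Dict[str, float]]:
        out: Dict[str, Dict[str, float]] = {}
        for mirna_id, feature_id, scc in pairs[
            ["mirna_id", "feature_id", "scc"]
        ].itertuples(index=False):
            out.setdefault(feature_id, {})[mirna_id] = scc
        return out

    by_mrna = _index(mrna_mirna_pairs)
    by_lnc = _index(lncrna_mirna_pairs)

    triplets: List[CeRNATriplet] = []
    for mrna_id in sorted(by_mrna):
        for lnc_id in sorted(by_lnc):
            shared = sorted(set(by_mrna[mrna_id]) & set(by_lnc[lnc_id]))
            if not shared:
                continue
            pcc = pearson_cc(
                expr_mrna.loc[mrna_id].to_numpy(float),
                expr_lncrna.loc[lnc_id].to_numpy(float),
            )
            if np.isnan(pcc) or not pcc > pcc_threshold:
                continue
            K = len(by_lnc[lnc_id])
            n = len(by_mrna[mrna_id])
            p = sponge_hypergeom_test(universe_size, K, n, len(shared))
            if not p < alpha:
                continue
            triplets.append(
                CeRNATriplet(
                    mrna_id=mrna_id,
                    lncrna_id=lnc_id,
                    mirna_ids=tuple(shared),
                    scc_mrna_mirna=min(by_mrna[mrna_id][m] for m in shared),
                    scc_lncrna_mirna=min(by_lnc[lnc_id][m] for m in shared),
                    pcc_mrna_lncrna=pcc,
                    k_shared=len(shared),
                    p_sponge=p,
                )
            )
    return triplets


def triplets_to_frame(triplets: Iterable[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mrna_id": t.mrna_id,
                "mirna_ids": ",".join(t.mirna_ids),
                "lncrna_id": t.lncrna_id,
                "scc_mrna_mirna": t.scc_mrna_mirna,
                "scc_lncrna_mirna": t.scc_lncrna_mirna,
                "pcc_mrna_lncrna": t.pcc_mrna_lncrna,
                "k_shared": t.k_shared,
                "p_sponge": t.p_sponge,
            }
            for t in triplets
        ],
        columns=[
            "mrna_id",
            "mirna_ids",
            "lncrna_id",
            "scc_mrna_mirna",
            "scc_lncrna_mirna",
            "pcc_mrna_lncrna",
            "k_shared",
            "p_sponge",
        ],
    )


def build_cerna_graph(triplets: Iterable[CeRNATriplet]) -> nx.Graph:
    """Tripartite mRNA / miRNA / lncRNA interaction graph."""
    g = nx.Graph()
    for t in triplets:
        g.add_node(t.mrna_id, node_type="mRNA")
        g.add_node(t.lncrna_id, node_type="lncRNA")
        g.add_edge(t.mrna_id, t.lncrna_id, interaction="cerna")
        for m in t.mirna_ids:
            g.add_node(m, node_type="miRNA")
            g.add_edge(t.mrna_id, m, interaction="targets")
            g.add_edge(t.lncrna_id, m, interaction="targets")
    return g


def network_counts(triplets: Sequence[CeRNATriplet]) -> Dict[str, int]:
    """Distinct-node counts: how many lncRNAs compete for how many miRNAs
    over how many mRNAs."""
    return {
        "n_mrna": len({t.mrna_id for t in triplets}),
        "n_lncrna": len({t.lncrna_id for t in triplets}),
        "n_mirna": len({m for t in triplets for m in t.mirna_ids}),
        "n_triplets": len(triplets),
    }


def export_cerna_network(
    triplets: Sequence[CeRNATriplet], graphml_path: str, tsv_path: str
) -> Dict[str, int]:
    """Write GraphML + triplet TSV; returns the distinct-node counts."""
    g = build_cerna_graph(triplets)
    nx.write_graphml(g, graphml_path)
    triplets_to_frame(triplets).to_csv(tsv_path, sep="\t", index=False)
    return network_counts(triplets)
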