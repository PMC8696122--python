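"""Gene-set enrichment: hypergeometric over-representation analysis (ORA)
and gene set enrichment analysis (GSEA) with signal-to-noise ranking and
phenotype-permutation normalization.

ORA shares the hypergeometric engine of the ceRNA sponge test.  GSEA ranks
genes by (mu_A - mu_B) / (sd_A + sd_B) with each sd floored at
max(0.2*|mu|, 0.2), computes the weighted Kolmogorov-Smirnov enrichment
score (ES), and normalizes against phenotype relabelings: NES = ES divided
by the mean |null ES| of matching sign, nominal p by the add-one permutation
convention, and FDR q by the standard signed tail-area method.  With few
replicates the relabeling space is tiny, so all distinct relabelings are
enumerated exhaustively whenever there are at most 500 of them.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .models import ValidationError
from .stats import hypergeom_tail

logger = logging.getLogger(__name__)

SN_SD_FLOOR_FRACTION = 0.2
SN_SD_FLOOR_ABS = 0.2
EXHAUSTIVE_PERMUTATION_LIMIT = 500


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional universe restriction."""

    sets: Dict[str, Set[str]]
    universe: Optional[Set[str]] = None
    categories: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        if self.universe is not None:
            self.sets = {
                name: members & self.universe for name, members in self.sets.items()
            }
            self.sets = {n: m for n, m in self.sets.items() if m}

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated members)."""
    sets: Dict[str, Set[str]] = {}
    cats: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed GMT line: {line[:80]!r}")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            sets[name] = set(members)
            cats[name] = desc
    return GeneSetCollection(sets=sets, categories=cats)


def write_gmt(collection: Mapping[str, Set[str]], path: str,
              descriptions: Optional[Mapping[str, str]] = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(collection[name])]) + "\n")


def ora_hypergeom(
    de_genes: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> Tuple[float, int]:
    """Upper-tail hypergeometric p and overlap count for a DE list vs a set.

    Genes outside the universe are dropped (with a warning for the DE list).
    """
    universe = set(universe)
    de = set(de_genes)
    if not de <= universe:
        logger.warning("%d DE gene(s) outside the universe dropped", len(de - universe))
        de &= universe
    gs = set(gene_set) & universe
    k = len(de & gs)
    p = hypergeom_tail(len(universe), len(gs), len(de), k)
    return p, k


def ora_table(
    de_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """ORA over a whole collection; raw p-values (threshold p < 0.05 applies)."""
    rows = []
    universe = set(universe)
    for name, members in sorted(collection.sets.items()):
        p, k = ora_hypergeom(de_genes, members, universe)
        rows.append(
            {"set": name, "size": len(members & universe), "overlap": k, "p": p}
        )
    return pd.DataFrame(rows, columns=["set", "size", "overlap", "p"])


def signal_to_noise_scores(
    expr: pd.DataFrame, cols_a: Sequence[str], cols_b: Sequence[str]
) -> pd.Series:
    """Per-gene signal-to-noise ratio (mu_A - mu_B) / (sd_A' + sd_B').

    Each group's sample sd is floored at max(0.2*|mu|, 0.2).  Requires >= 2
    samples per group.
    """
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("each phenotype group needs >= 2 samples")
    a = expr[list(cols_a)].to_numpy(float)
    b = expr[list(cols_b)].to_numpy(float)
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum.reduce(
        [a.std(axis=1, ddof=1), SN_SD_FLOOR_FRACTION * np.abs(mu_a),
         np.full_like(mu_a, SN_SD_FLOOR_ABS)]
    )
    sd_b = np.maximum.reduce(
        [b.std(axis=1, ddof=1), SN_SD_FLOOR_FRACTION * np.abs(mu_b),
         np.full_like(mu_b, SN_SD_FLOOR_ABS)]
    )
    return pd.Series((mu_a - mu_b) / (sd_a + sd_b), index=expr.index, name="s2n")


def signal_to_noise_rank(
    expr: pd.DataFrame, cols_a: Sequence[str], cols_b: Sequence[str]
) -> pd.Series:
    """Genes sorted by descending signal-to-noise score (stable tie-break in
    the input feature order)."""
    scores = signal_to_noise_scores(expr, cols_a, cols_b)
    return scores.sort_values(ascending=False, kind="stable")


def gsea_es(
    ranked_scores: pd.Series, gene_set: Iterable[str], weight: float = 1.0
) -> Tuple[float, np.ndarray]:
    """Weighted-KS enrichment score over a descending-ranked score list.

    Hits advance the running sum by |score|^weight normalized over the set;
    misses retreat by 1/(N - set size).  ES is the running sum's signed
    maximum deviation from zero.
    """
    gs = set(gene_set)
    in_set = ranked_scores.index.isin(gs)
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValidationError("gene set has no members in the ranked list")
    n = len(ranked_scores)
    w = np.abs(ranked_scores.to_numpy(float)) ** weight
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores are exactly zero: fall back to unweighted
        hit_w = in_set.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom
    if n > n_hit:
        steps = steps - (~in_set) / (n - n_hit)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def leading_edge(
    ranked_scores: pd.Series, gene_set: Iterable[str], weight: float = 1.0
) -> List[str]:
    """Set members at or before (after, for negative ES) the ES extremum."""
    es, running = gsea_es(ranked_scores, gene_set, weight)
    peak = int(np.argmax(np.abs(running)))
    gs = set(gene_set)
    ids = list(ranked_scores.index)
    if es >= 0:
        return [g for g in ids[: peak + 1] if g in gs]
    return [g for g in ids[peak:] if g in gs]


def _phenotype_relabelings(
    columns: Sequence[str], n_a: int, n_perm: int, rng: np.random.Generator
) -> List[Tuple[Tuple[str, ...], Tuple[str, ...]]]:
    """Distinct (group A, group B) relabelings, the observed one excluded.

    Exhaustive when at most ``EXHAUSTIVE_PERMUTATION_LIMIT`` distinct
    relabelings exist; otherwise ``n_perm`` draws without replacement of the
    label vector.
    """
    from math import comb

    total = comb(len(columns), n_a)
    observed = tuple(columns[:n_a])
    out = []
    if total - 1 <= max(EXHAUSTIVE_PERMUTATION_LIMIT, n_perm):
        for combo in itertools.combinations(columns, n_a):
            if combo == observed:
                continue
            rest = tuple(c for c in columns if c not in combo)
            out.append((combo, rest))
    else:
        seen = {tuple(sorted(observed))}
        cols = list(columns)
        while len(out) < n_perm:
            rng.shuffle(cols)
            combo = tuple(sorted(cols[:n_a]))
            if combo in seen:
                continue
            seen.add(combo)
            rest = tuple(c for c in columns if c not in combo)
            out.append((combo, rest))
    return out


def gsea(
    expr: pd.DataFrame,
    cols_a: Sequence[str],
    cols_b: Sequence[str],
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Full GSEA: ES, NES, nominal p and FDR q per gene set.

    Null ES come from phenotype relabelings (exhaustive for small designs).
    NES divides each ES by the mean |null ES| of its sign; nominal p uses the
    add-one convention over same-sign nulls; q follows the standard GSEA
    positive/negative tail-area normalization.  Deterministic for fixed seed.
    """
    if n_perm < 10:
        raise ValidationError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    columns = list(cols_a) + list(cols_b)
    ranked = signal_to_noise_rank(expr, cols_a, cols_b)
    names = sorted(collection.sets)
    observed = {}
    for name in names:
        observed[name], _ = gsea_es(ranked, collection.sets[name], weight)

    relabelings = _phenotype_relabelings(columns, len(cols_a), n_perm, rng)
    null_es: Dict[str, List[float]] = {name: [] for name in names}
    for ca, cb in relabelings:
        ranked_p = signal_to_noise_rank(expr, ca, cb)
        for name in names:
            es_p, _ = gsea_es(ranked_p, collection.sets[name], weight)
            null_es[name].append(es_p)

    rows = []
    all_null_nes: List[float] = []
    for name in names:
        es = observed[name]
        nulls = np.asarray(null_es[name])
        pos = nulls[nulls >= 0]
        neg = nulls[nulls < 0]
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = np.abs(neg).mean() if len(neg) else np.nan
        if es >= 0:
            nes = es / mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else np.nan
            same = pos
            n_extreme = int((same >= es).sum())
        else:
            nes = es / mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else np.nan
            same = neg
            n_extreme = int((same <= es).sum())
        p = (1 + n_extreme) / (1 + len(same)) if len(same) else 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = np.where(nulls >= 0, nulls / mean_pos, nulls / mean_neg)
        all_null_nes.extend(nn[np.isfinite(nn)].tolist())
        rows.append({"set": name, "size": len(collection.sets[name] & set(expr.index)),
                     "es": es, "nes": nes, "p": p})

    df = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p"])
    null_nes = np.asarray(all_null_nes)
    obs_nes = df["nes"].to_numpy(float)
    qs = []
    for nes in obs_nes:
        if not np.isfinite(nes):
            qs.append(np.nan)
            continue
        if nes >= 0:
            null_tail = (null_nes >= nes).sum() / max((null_nes >= 0).sum(), 1)
            obs_tail = (obs_nes[np.isfinite(obs_nes)] >= nes).sum() / max(
                (obs_nes[np.isfinite(obs_nes)] >= 0).sum(), 1
            )
        else:
            null_tail = (null_nes <= nes).sum() / max((null_nes < 0).sum(), 1)
            obs_tail = (obs_nes[np.isfinite(obs_nes)] <= nes).sum() / max(
                (obs_nes[np.isfinite(obs_nes)] < 0).sum(), 1
            )
        qs.append(min(1.0, null_tail / obs_tail) if obs_tail > 0 else np.nan)
    df["q"] = qs
    return df


def significant_sets(
    results: pd.DataFrame,
    nes_min: float = 1.0,
    p_max: float = 0.05,
    q_max: float = 0.25,
) -> pd.DataFrame:
    """GSEA significance filter: |NES| > 1, p < 0.05, q < 0.25 (all strict)."""
    keep = (
        (results["nes"].abs() > nes_min)
        & (results["p"] < p_max)
        & (results["q"] < q_max)
    )
    return results[keep.fillna(False)].reset_index(drop=True)
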