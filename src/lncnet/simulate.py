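"""Synthetic fixtures with planted ground truth.

Emulates a 2-tissue x 3-stage x 3-replicate RNA-seq design: negative-binomial
counts around a common baseline, planted stage-wise fold changes, lncRNAs
placed on a synthetic chromosome so that each satisfies exactly one
positional-category definition, cis/antisense target pairs built into the
geometry, and ceRNA triplets driven by a shared latent profile (the miRNA
anti-monotone to it, the mRNA and lncRNA monotone), so that at
``corr_strength = 1`` the planted Spearman/Pearson correlations are exact.

The default category mix follows the empirical proportions of the four
categories observed in the study system (intergenic / bidirectional /
antisense / sense-overlapping, renormalized; no intronic lncRNAs by
default, although the geometry supports planting them).
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as lio
from .enrichment import write_gmt
from .expression import STAGES, ExpressionMatrix
from .models import GeneModel, TranscriptModel, ValidationError

# chromosome layout (bp)
GENE_SPACING = 30_000
GENE_OFFSET = 50_000
GENE_EXONS_REL = ((0, 1_000), (2_000, 3_000), (4_000, 5_000))
GENE_LENGTH = 5_000
CIS_GAP = 6_000        # planted cis distance, inside the (5 kb, 10 kb) band
FAR_GAP = 12_000       # planted intergenic distance, beyond the 10 kb window
BIDIRECTIONAL_GAP = 200
CERNA_LOG2_AMPLITUDE = 1.5
MIRNA_LENGTH = 22

PLANTABLE_CATEGORIES = (
    "intergenic",
    "bidirectional",
    "intronic",
    "antisense",
    "sense_overlapping",
)

DEFAULT_CATEGORY_MIX = {
    "intergenic": 0.5633,
    "bidirectional": 0.1029,
    "intronic": 0.0,
    "antisense": 0.2218,
    "sense_overlapping": 0.1120,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults mirror the emulated design: two tissues (brain, pituitary),
    three ovarian stages (IV, V, VI), three replicates, negative-binomial
    counts with mean 100 and dispersion 0.05, planted |log2FC| = 2 for a
    fifth of the features, and ceRNA triplets with co-expression strength
    0.9.
    """

    seed: int = 0
    n_genes: int = 120
    n_lncrna: int = 60
    n_mirna: int = 30
    n_tissues: int = 2
    n_stages: int = 3
    n_reps: int = 3
    nb_dispersion: float = 0.05
    baseline_mean: float = 100.0
    planted_log2fc: float = 2.0
    frac_de: float = 0.2
    category_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    n_cerna_triplets: int = 8
    corr_strength: float = 0.9
    decoy_rate: float = 0.0
    frac_cis: float = 0.5
    library_cv: float = 0.2
    n_gene_sets: int = 6
    gene_set_size: int = 15

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirna", "n_tissues", "n_stages", "n_reps"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_lncrna < 0:
            raise ConfigurationError("n_lncrna must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be positive")
        if not 0 <= self.frac_de <= 1:
            raise ConfigurationError("frac_de must be in [0, 1]")
        if not 0 < self.corr_strength <= 1:
            raise ConfigurationError("corr_strength must be in (0, 1]")
        if not 0 <= self.decoy_rate <= 1:
            raise ConfigurationError("decoy_rate must be in [0, 1]")
        if self.n_stages > len(STAGES):
            raise ConfigurationError(f"at most {len(STAGES)} stages supported")
        unknown = set(self.category_mix) - set(PLANTABLE_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories in mix: {sorted(unknown)}")
        if any(v < 0 for v in self.category_mix.values()):
            raise ConfigurationError("category_mix proportions must be >= 0")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("category_mix must sum to 1")
        if self.n_lncrna > self.n_genes:
            raise ConfigurationError(
                "n_lncrna may not exceed n_genes (one host gene locus per lncRNA)"
            )


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for downstream recovery tests."""

    de_features: Dict[str, Dict[str, str]]  # comparison -> {feature_id: up|down}
    lncrna_category: Dict[str, str]
    target_pairs: Set[Tuple[str, str, str]]  # (lncrna_id, gene_id, mechanism)
    cerna_triplets: Set[Tuple[str, str, str]]  # (mrna_id, mirna_id, lncrna_id)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: List[GeneModel]
    lncrnas: List[TranscriptModel]
    truth: PlantedTruth
    mrna_counts: ExpressionMatrix
    lncrna_counts: ExpressionMatrix
    mirna_counts: ExpressionMatrix
    design: pd.DataFrame
    mirna_targets: pd.DataFrame
    gene_sets: Dict[str, Set[str]]


def _allocate_categories(mix: Mapping[str, float], n: int) -> Dict[str, int]:
    """Integer allocation by largest remainder, deterministic tie-break."""
    cats = [c for c in PLANTABLE_CATEGORIES if mix.get(c, 0) > 0]
    if n > 0 and not cats:
        raise ConfigurationError("category_mix allocates zero lncRNAs")
    raw = {c: mix[c] * n for c in cats}
    counts = {c: int(math.floor(raw[c])) for c in cats}
    rest = n - sum(counts.values())
    order = sorted(cats, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in order[:rest]:
        counts[c] += 1
    return counts


def _gene_models(config: SimulationConfig) -> List[GeneModel]:
    genes = []
    for i in range(config.n_genes):
        gid = f"G{i + 1:04d}"
        start = GENE_OFFSET + i * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        exons = tuple((start + s, start + e) for s, e in GENE_EXONS_REL)
        t = TranscriptModel(
            id=f"{gid}.t1", chrom="chr1", strand=strand, exons=exons, gene_id=gid
        )
        genes.append(
            GeneModel(
                id=gid,
                chrom="chr1",
                strand=strand,
                span=(start, start + GENE_LENGTH),
                transcripts=(t,),
                biotype="coding",
            )
        )
    return genes


def _place_lncrna(lnc_id: str, category: str, host: GeneModel, cis: bool) -> TranscriptModel:
    gs, ge = host.span
    if category == "antisense":
        strand = "-" if host.strand == "+" else "+"
        exons = ((gs + 500, gs + 1_200), (gs + 1_400, gs + 1_600))
    elif category == "sense_overlapping":
        strand = host.strand
        exons = ((gs + 500, gs + 1_200), (gs + 1_400, gs + 1_600))
    elif category == "intronic":
        strand = "-" if host.strand == "+" else "+"
        exons = ((gs + 1_050, gs + 1_200), (gs + 1_500, gs + 1_750))
    elif category == "bidirectional":
        if host.strand == "+":
            strand = "-"
            exons = ((gs - 800, gs - 500), (gs - 400, gs - BIDIRECTIONAL_GAP))
        else:
            strand = "+"
            exons = ((ge + BIDIRECTIONAL_GAP, ge + 400), (ge + 500, ge + 800))
    elif category == "intergenic":
        gap = CIS_GAP if cis else FAR_GAP
        strand = "+"
        exons = ((ge + gap, ge + gap + 300), (ge + gap + 350, ge + gap + 650))
    else:
        raise ConfigurationError(f"cannot plant category {category!r}")
    return TranscriptModel(id=lnc_id, chrom="chr1", strand=strand, exons=exons)


def generate_annotation(
    config: SimulationConfig,
) -> Tuple[List[GeneModel], List[TranscriptModel], PlantedTruth]:
    """Build gene models and category-planted lncRNAs on one synthetic chromosome.

    Every lncRNA has >= 2 exons and >= 200 exonic bp by construction; each is
    hosted at its own gene locus so the classifier recovers exactly the
    planted category.  Antisense lncRNAs yield planted antisense target
    pairs; bidirectional lncRNAs and the configured fraction of intergenic
    lncRNAs placed 5-10 kb from their host gene yield planted cis pairs.
    """
    genes = _gene_models(config)
    counts = (
        _allocate_categories(config.category_mix, config.n_lncrna)
        if config.n_lncrna
        else {}
    )
    lncs: List[TranscriptModel] = []
    truth = PlantedTruth(
        de_features={}, lncrna_category={}, target_pairs=set(), cerna_triplets=set()
    )
    idx = 0
    for category in PLANTABLE_CATEGORIES:
        n_cat = counts.get(category, 0)
        n_cis = round(config.frac_cis * n_cat) if category == "intergenic" else 0
        for j in range(n_cat):
            lnc_id = f"LNC{idx + 1:04d}"
            host = genes[idx]
            cis = category == "intergenic" and j < n_cis
            lnc = _place_lncrna(lnc_id, category, host, cis)
            lncs.append(lnc)
            truth.lncrna_category[lnc_id] = category
            if category == "antisense":
                truth.target_pairs.add((lnc_id, host.id, "antisense"))
            elif category == "bidirectional" or cis:
                truth.target_pairs.add((lnc_id, host.id, "cis"))
            idx += 1
    return genes, lncs, truth


def _sample_index(config: SimulationConfig) -> pd.DataFrame:
    tissues = ["brain", "pituitary"] + [
        f"tissue{i}" for i in range(3, config.n_tissues + 1)
    ]
    rows = []
    for tissue in tissues[: config.n_tissues]:
        for stage in STAGES[: config.n_stages]:
            for rep in range(1, config.n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}_{stage}_r{rep}",
                        "tissue": tissue,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _plant_de(
    ids: Sequence[str], config: SimulationConfig, truth: PlantedTruth
) -> None:
    """Assign frac_de of ``ids`` to the stage comparisons, alternating direction."""
    if config.n_stages < 2:
        return
    comparisons = [
        f"{STAGES[i]}_vs_{STAGES[i + 1]}" for i in range(config.n_stages - 1)
    ]
    n_de = int(round(config.frac_de * len(ids)))
    chosen = list(ids[:n_de])
    for comp in comparisons:
        truth.de_features.setdefault(comp, {})
    for i, fid in enumerate(chosen):
        comp = comparisons[i % len(comparisons)]
        truth.de_features[comp][fid] = "up" if (i // len(comparisons)) % 2 == 0 else "down"


def _log2_mean_matrix(
    ids: Sequence[str],
    design: pd.DataFrame,
    config: SimulationConfig,
    truth: PlantedTruth,
) -> pd.DataFrame:
    base = math.log2(config.baseline_mean)
    lm = pd.DataFrame(base, index=list(ids), columns=design.index, dtype=float)
    stages = list(STAGES[: config.n_stages])
    for comp, feats in truth.de_features.items():
        a, b = comp.split("_vs_")
        shifted = stages[stages.index(b):]  # step change persists downstream
        cols = design.index[design["stage"].isin(shifted)]
        for fid, direction in feats.items():
            if fid in lm.index:
                delta = config.planted_log2fc if direction == "up" else -config.planted_log2fc
                lm.loc[fid, cols] += delta
    return lm


def _draw_counts(
    log2_means: pd.DataFrame,
    lib_factor: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    mu = (2.0 ** log2_means.to_numpy(float)) * lib_factor[None, :]
    if config.nb_dispersion == 0:
        counts = mu  # deterministic limit: expected counts, no sampling step
    else:
        r = 1.0 / config.nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    return pd.DataFrame(
        counts.astype(float), index=log2_means.index, columns=log2_means.columns
    )


def generate_expression(
    config: SimulationConfig, truth: PlantedTruth
) -> Tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Draw mRNA / lncRNA / miRNA count matrices with the planted structure.

    Planted DE features shift by ``planted_log2fc`` from the later stage of
    their comparison onward.  Each planted ceRNA triplet shares a latent
    profile: the mRNA and lncRNA follow it on the log2 scale, the miRNA
    follows its negation, with independent Gaussian admixture scaled by
    ``sqrt(1 - corr_strength^2)``.  Library sizes vary uniformly within
    +-``library_cv`` around nominal.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng([config.seed, 1])
    design = _sample_index(config)
    n_samples = len(design)

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    lnc_ids = sorted(truth.lncrna_category)
    mirna_ids = [f"MIR{i + 1:03d}" for i in range(config.n_mirna)]

    # DE planting on the head of each id list; ceRNA features on the tail.
    n_trip = config.n_cerna_triplets
    if n_trip:
        if min(len(gene_ids), len(lnc_ids), len(mirna_ids)) < n_trip:
            raise ConfigurationError("n_cerna_triplets exceeds available features")
        trip_mrna = gene_ids[-n_trip:]
        trip_lnc = lnc_ids[-n_trip:]
        trip_mirna = mirna_ids[-n_trip:]
        for m, mi, l in zip(trip_mrna, trip_mirna, trip_lnc):
            truth.cerna_triplets.add((m, mi, l))
            truth.target_pairs.add((l, m, "trans"))
    de_pool = {
        "mrna": gene_ids[: len(gene_ids) - n_trip],
        "lnc": lnc_ids[: len(lnc_ids) - n_trip] if lnc_ids else [],
        "mirna": mirna_ids[: len(mirna_ids) - n_trip],
    }
    if not truth.de_features:
        for ids in de_pool.values():
            _plant_de(ids, config, truth)

    lm_mrna = _log2_mean_matrix(gene_ids, design, config, truth)
    lm_lnc = _log2_mean_matrix(lnc_ids, design, config, truth)
    lm_mirna = _log2_mean_matrix(mirna_ids, design, config, truth)

    c = config.corr_strength
    mix = math.sqrt(max(0.0, 1.0 - c * c))
    for m, mi, l in sorted(truth.cerna_triplets):
        z = rng.standard_normal(n_samples)
        eps = rng.standard_normal((3, n_samples))
        lm_mrna.loc[m] += CERNA_LOG2_AMPLITUDE * (c * z + mix * eps[0])
        lm_lnc.loc[l] += CERNA_LOG2_AMPLITUDE * (c * z + mix * eps[1])
        lm_mirna.loc[mi] += CERNA_LOG2_AMPLITUDE * (-c * z + mix * eps[2])

    lib = rng.uniform(1.0 - config.library_cv, 1.0 + config.library_cv, n_samples)
    mrna_counts = _draw_counts(lm_mrna, lib, config, rng)
    lnc_counts = _draw_counts(lm_lnc, lib, config, rng)
    mirna_counts = _draw_counts(lm_mirna, lib, config, rng)
    return (
        ExpressionMatrix(mrna_counts, "counts"),
        ExpressionMatrix(lnc_counts, "counts"),
        ExpressionMatrix(mirna_counts, "counts"),
        design,
    )


def generate_mirna_targets(
    config: SimulationConfig,
    truth: PlantedTruth,
    decoy_rate: Optional[float] = None,
) -> pd.DataFrame:
    """miRNA-target table: every planted triplet's two edges, plus decoys.

    Each non-planted (miRNA, feature) combination enters independently with
    probability ``decoy_rate``.
    """
    rate = config.decoy_rate if decoy_rate is None else decoy_rate
    rng = np.random.default_rng([config.seed, 2])
    planted = set()
    rows = []
    for m, mi, l in sorted(truth.cerna_triplets):
        rows.append({"mirna_id": mi, "target_id": m, "target_class": "mRNA"})
        rows.append({"mirna_id": mi, "target_id": l, "target_class": "lncRNA"})
        planted.add((mi, m))
        planted.add((mi, l))
    mirna_ids = [f"MIR{i + 1:03d}" for i in range(config.n_mirna)]
    features = [(f"G{i + 1:04d}", "mRNA") for i in range(config.n_genes)] + [
        (lid, "lncRNA") for lid in sorted(truth.lncrna_category)
    ]
    if rate > 0:
        for mi in mirna_ids:
            draws = rng.random(len(features))
            for (fid, cls), u in zip(features, draws):
                if (mi, fid) not in planted and u < rate:
                    rows.append({"mirna_id": mi, "target_id": fid, "target_class": cls})
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"])


def generate_gene_sets(
    config: SimulationConfig, truth: PlantedTruth
) -> Dict[str, Set[str]]:
    """GMT fixture: the planted up/down mRNA sets plus random decoy sets."""
    rng = np.random.default_rng([config.seed, 3])
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    sets: Dict[str, Set[str]] = {}
    last = f"{STAGES[config.n_stages - 2]}_vs_{STAGES[config.n_stages - 1]}" if config.n_stages >= 2 else None
    if last and last in truth.de_features:
        up = {f for f, d in truth.de_features[last].items() if d == "up" and f in gene_ids}
        down = {f for f, d in truth.de_features[last].items() if d == "down" and f in gene_ids}
        if up:
            sets[f"planted_up_{last}"] = up
        if down:
            sets[f"planted_down_{last}"] = down
    size = min(config.gene_set_size, len(gene_ids))
    for i in range(config.n_gene_sets):
        members = rng.choice(gene_ids, size=size, replace=False)
        sets[f"random_set_{i + 1:02d}"] = set(members.tolist())
    return sets


def feature_lengths(
    genes: Sequence[GeneModel], lncrnas: Sequence[TranscriptModel]
) -> pd.Series:
    lengths = {}
    for g in genes:
        lengths[g.id] = float(sum(e - s for s, e in g.exons))
    for t in lncrnas:
        lengths[t.id] = float(t.length)
    return pd.Series(lengths, name="length")


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator for one config; the one-stop entry point."""
    genes, lncs, truth = generate_annotation(config)
    mrna, lnc, mirna, design = generate_expression(config, truth)
    targets = generate_mirna_targets(config, truth)
    gene_sets = generate_gene_sets(config, truth)
    lengths = feature_lengths(genes, lncs)
    lengths = pd.concat(
        [lengths, pd.Series({m: float(MIRNA_LENGTH) for m in mirna.features})]
    )
    lengths.name = "length"
    mrna.lengths = lengths
    lnc.lengths = lengths
    mirna.lengths = lengths
    return SyntheticDataset(
        config=config,
        genes=genes,
        lncrnas=lncs,
        truth=truth,
        mrna_counts=mrna,
        lncrna_counts=lnc,
        mirna_counts=mirna,
        design=design,
        mirna_targets=targets,
        gene_sets=gene_sets,
    )


def write_truth(truth: PlantedTruth, path: str) -> None:
    """Serialize the planted truth as a single TSV manifest."""
    rows = []
    for comp in sorted(truth.de_features):
        for fid in sorted(truth.de_features[comp]):
            rows.append(
                {"record": "de", "comparison": comp, "id1": fid,
                 "id2": "", "id3": "", "label": truth.de_features[comp][fid]}
            )
    for lid in sorted(truth.lncrna_category):
        rows.append({"record": "category", "comparison": "", "id1": lid,
                     "id2": "", "id3": "", "label": truth.lncrna_category[lid]})
    for lid, gid, mech in sorted(truth.target_pairs):
        rows.append({"record": "target_pair", "comparison": "", "id1": lid,
                     "id2": gid, "id3": "", "label": mech})
    for m, mi, l in sorted(truth.cerna_triplets):
        rows.append({"record": "cerna_triplet", "comparison": "", "id1": m,
                     "id2": mi, "id3": l, "label": ""})
    pd.DataFrame(rows, columns=["record", "comparison", "id1", "id2", "id3", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path: str) -> PlantedTruth:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    truth = PlantedTruth(
        de_features={}, lncrna_category={}, target_pairs=set(), cerna_triplets=set()
    )
    for rec in df.itertuples(index=False):
        if rec.record == "de":
            truth.de_features.setdefault(rec.comparison, {})[rec.id1] = rec.label
        elif rec.record == "category":
            truth.lncrna_category[rec.id1] = rec.label
        elif rec.record == "target_pair":
            truth.target_pairs.add((rec.id1, rec.id2, rec.label))
        elif rec.record == "cerna_triplet":
            truth.cerna_triplets.add((rec.id1, rec.id2, rec.id3))
    return truth


def write_fixtures(dataset: SyntheticDataset, out_dir: str) -> Dict[str, str]:
    """Write every fixture file; returns a name -> path map.

    Byte-identical output for identical configs (all randomness is derived
    from the config seed).
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "annotation": os.path.join(out_dir, "annotation.gtf"),
        "mrna_counts": os.path.join(out_dir, "mrna_counts.tsv"),
        "lncrna_counts": os.path.join(out_dir, "lncrna_counts.tsv"),
        "mirna_counts": os.path.join(out_dir, "mirna_counts.tsv"),
        "lengths": os.path.join(out_dir, "feature_lengths.tsv"),
        "design": os.path.join(out_dir, "design.tsv"),
        "mirna_targets": os.path.join(out_dir, "mirna_targets.tsv"),
        "gene_sets": os.path.join(out_dir, "gene_sets.gmt"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    lio.write_gtf(paths["annotation"], dataset.genes, dataset.lncrnas)
    lio.write_matrix(dataset.mrna_counts.values, paths["mrna_counts"])
    lio.write_matrix(dataset.lncrna_counts.values, paths["lncrna_counts"])
    lio.write_matrix(dataset.mirna_counts.values, paths["mirna_counts"])
    lio.write_lengths(dataset.mrna_counts.lengths, paths["lengths"])
    lio.write_design(dataset.design, paths["design"])
    lio.write_mirna_targets(dataset.mirna_targets, paths["mirna_targets"])
    write_gmt(dataset.gene_sets, paths["gene_sets"])
    write_truth(dataset.truth, paths["truth"])
    return paths
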