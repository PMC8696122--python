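"""Novel-transcript filtering, coding-potential consensus and positional
classification of lncRNAs.

A candidate transcript is kept as "novel" when it has at least two exons and
at least 200 bp of exonic sequence.  Candidates called noncoding by all three
coding-potential sources (two ab initio predictors and a protein-database
search) form the lncRNA set, which is then classified into five positional
categories relative to the reference genes plus a residual "other" class.

Category geometry (all distances configurable through :class:`ClassifyParams`):

* ``antisense`` — >=1 bp exonic overlap with a gene on the opposite strand;
* ``sense_overlapping`` — exonic overlap on the same strand;
* ``intronic`` — transcript wholly inside a single intron of a gene (either
  strand), without exonic overlap;
* ``bidirectional`` — non-overlapping, TSS within 1 kb of a gene TSS,
  divergently oriented;
* ``intergenic`` — farther than 5 kb from every gene;
* ``other`` — everything remaining.

Rules are applied in that priority order, so every lncRNA receives exactly
one label.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .models import (
    LNCRNA_CATEGORIES,
    CodingPotentialCall,
    GeneModel,
    Interval,
    LncRNARecord,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

MIN_TRANSCRIPT_LENGTH = 200
MIN_EXON_COUNT = 2

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class ClassifyParams:
    """Distance thresholds for positional classification (bp)."""

    bidirectional_tss_window: int = 1_000
    intergenic_min_distance: int = 5_000


def filter_novel_transcripts(
    transcripts: Iterable[TranscriptModel],
    min_length: int = MIN_TRANSCRIPT_LENGTH,
    min_exons: int = MIN_EXON_COUNT,
) -> Tuple[List[TranscriptModel], List[Tuple[str, str]]]:
    """Keep transcripts with >= ``min_exons`` exons and >= ``min_length`` exonic bp.

    Returns the kept list and a rejection log of ``(transcript_id, rule)``
    pairs, where rule is ``"exon_count"`` or ``"length"`` (exon count is
    checked first).
    """
    kept: List[TranscriptModel] = []
    rejected: List[Tuple[str, str]] = []
    for t in transcripts:
        if t.n_exons < min_exons:
            rejected.append((t.id, "exon_count"))
        elif t.length < min_length:
            rejected.append((t.id, "length"))
        else:
            kept.append(t)
    return kept, rejected


def consensus_noncoding(calls: Iterable[CodingPotentialCall]) -> Set[str]:
    """Transcripts judged noncoding by *all three* sources (set intersection)."""
    return {c.transcript_id for c in calls if c.noncoding}


def orf_heuristic(seq: str, min_codons: int = 100) -> bool:
    """Crude coding-potential stand-in: ``True`` (coding) iff the longest
    forward-strand ORF (ATG through an in-frame stop) spans >= ``min_codons``
    codons, the ATG included and the stop excluded.
    """
    s = seq.upper()
    if re.search(r"[^ACGTN]", s):
        raise ValidationError("sequence contains non-ACGTN characters")
    longest = 0
    for frame in range(3):
        codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
        start: Optional[int] = None
        for i, codon in enumerate(codons):
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                longest = max(longest, i - start)
                start = None
    return longest >= min_codons


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def exonic_overlap_bp(t: TranscriptModel, g: GeneModel) -> int:
    """Total bp shared between the transcript's exons and the gene's merged exons."""
    if t.chrom != g.chrom:
        return 0
    return sum(_overlap(te, ge) for te in t.exons for ge in g.exons)


def span_gap(a: Interval, b: Interval) -> int:
    """Gap in bp between two disjoint intervals (0 if they touch or overlap)."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def _is_divergent(t: TranscriptModel, g: GeneModel) -> bool:
    # Divergent orientation: the two TSSs face away from each other.
    if t.strand == g.strand:
        return False
    if g.strand == "+":
        return t.tss <= g.tss
    return t.tss >= g.tss


def classify_lncrna(
    lnc: TranscriptModel,
    genes: Sequence[GeneModel],
    params: ClassifyParams = ClassifyParams(),
) -> LncRNARecord:
    """Assign one positional category to a lncRNA (see module docstring).

    The nearest gene on the same chromosome (by span gap, 0 when overlapping)
    is recorded alongside the category.
    """
    same_chrom = [g for g in genes if g.chrom == lnc.chrom]
    if not same_chrom:
        logger.warning("chromosome %s absent from annotation; %s classified against "
                       "an empty gene set", lnc.chrom, lnc.id)

    nearest: Optional[GeneModel] = None
    nearest_gap: Optional[int] = None
    for g in same_chrom:
        gap = span_gap(lnc.span, g.span)
        if nearest_gap is None or gap < nearest_gap:
            nearest, nearest_gap = g, gap

    category = "other"
    # antisense / sense_overlapping: exonic overlap, split by strand
    for g in same_chrom:
        if exonic_overlap_bp(lnc, g) >= 1:
            if g.strand != lnc.strand:
                category = "antisense"
                break
    else:
        for g in same_chrom:
            if exonic_overlap_bp(lnc, g) >= 1 and g.strand == lnc.strand:
                category = "sense_overlapping"
                break
        else:
            category = _classify_nonoverlapping(lnc, same_chrom, nearest_gap, params)

    return LncRNARecord(
        transcript=lnc,
        category=category,
        nearest_gene_id=nearest.id if nearest is not None else None,
        distance_bp=nearest_gap,
    )


def _classify_nonoverlapping(
    lnc: TranscriptModel,
    genes: Sequence[GeneModel],
    nearest_gap: Optional[int],
    params: ClassifyParams,
) -> str:
    for g in genes:
        if _overlap(lnc.span, g.span) > 0:  # inside the gene body, no exonic overlap
            for intron in g.introns:
                if intron[0] <= lnc.start and lnc.end <= intron[1]:
                    return "intronic"
    for g in genes:
        if (
            span_gap(lnc.span, g.span) >= 0
            and _overlap(lnc.span, g.span) == 0
            and abs(lnc.tss - g.tss) <= params.bidirectional_tss_window
            and _is_divergent(lnc, g)
        ):
            return "bidirectional"
    if nearest_gap is None or nearest_gap > params.intergenic_min_distance:
        return "intergenic"
    return "other"


def classify_all(
    lncs: Iterable[TranscriptModel],
    genes: Sequence[GeneModel],
    params: ClassifyParams = ClassifyParams(),
) -> List[LncRNARecord]:
    return [classify_lncrna(t, genes, params) for t in lncs]


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_categories(
    records: Iterable[LncRNARecord] | Dict[str, int],
) -> Tuple[Dict[str, int], Dict[str, float]]:
    """Per-category counts and percentages (half-up, one decimal).

    Accepts either classified records or a pre-tallied ``{category: count}``
    mapping.  Percentages are omitted (empty dict) for empty input.
    """
    if isinstance(records, dict):
        counts = {c: int(records.get(c, 0)) for c in LNCRNA_CATEGORIES}
        unknown = set(records) - set(LNCRNA_CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")
    else:
        counts = {c: 0 for c in LNCRNA_CATEGORIES}
        for r in records:
            counts[r.category] += 1
    total = sum(counts.values())
    if total == 0:
        return counts, {}
    pct = {c: _round_half_up(100.0 * n / total) for c, n in counts.items()}
    return counts, pct
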