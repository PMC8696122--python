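"""Core record types shared across the pipeline.

Coordinates are 0-based half-open internally; GTF input/output converts
to/from the 1-based inclusive convention at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple


class ValidationError(ValueError):
    """Raised when a record violates its structural invariants."""


Interval = Tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript.

    Parameters
    ----------
    id : str
        Transcript identifier (GTF ``transcript_id``).
    chrom : str
        Chromosome / scaffold name.
    strand : str
        ``'+'`` or ``'-'``.
    exons : tuple of (start, end)
        Sorted, non-overlapping, 0-based half-open exon intervals.
    gene_id : str, optional
        Parent gene identifier, if any.
    """

    id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.id}: transcript has no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise ValidationError(f"{self.id}: malformed exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        """Total exonic length in bp."""
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site (5' end, strand-aware)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GeneModel:
    """A reference gene: the union of its transcripts plus a biotype tag."""

    id: str
    chrom: str
    strand: str
    span: Interval
    transcripts: Tuple[TranscriptModel, ...] = ()
    biotype: str = "coding"

    def __post_init__(self) -> None:
        s, e = self.span
        if e <= s:
            raise ValidationError(f"{self.id}: malformed span {self.span}")
        for t in self.transcripts:
            if t.start < s or t.end > e:
                raise ValidationError(f"{self.id}: span does not cover transcript {t.id}")

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def exons(self) -> Tuple[Interval, ...]:
        """Merged exon intervals across all transcripts (whole span if none)."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        if not ivs:
            return (self.span,)
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return tuple((s, e) for s, e in merged)

    @property
    def introns(self) -> Tuple[Interval, ...]:
        """Gaps between merged exons."""
        ex = self.exons
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))


#: The positional lncRNA classes, in classification priority order.
LNCRNA_CATEGORIES = (
    "antisense",
    "sense_overlapping",
    "intronic",
    "bidirectional",
    "intergenic",
    "other",
)


@dataclass(frozen=True)
class LncRNARecord:
    """A classified lncRNA with its nearest reference gene."""

    transcript: TranscriptModel
    category: str
    nearest_gene_id: Optional[str] = None
    distance_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in LNCRNA_CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if (self.nearest_gene_id is None) != (self.distance_bp is None):
            raise ValidationError("nearest_gene_id and distance_bp must be set together")
        if self.distance_bp is not None and self.distance_bp < 0:
            raise ValidationError("distance_bp must be non-negative")


@dataclass(frozen=True)
class CodingPotentialCall:
    """Three boolean coding-evidence verdicts for one transcript.

    ``True`` means the predictor sees coding evidence.  The canonical keys are
    the two ab initio predictors and the protein-database hit.
    """

    transcript_id: str
    verdicts: Mapping[str, bool]

    def __post_init__(self) -> None:
        if len(self.verdicts) != 3:
            raise ValidationError(
                f"{self.transcript_id}: exactly three verdicts required, got {len(self.verdicts)}"
            )

    @property
    def noncoding(self) -> bool:
        """True iff all three predictors agree the transcript is noncoding."""
        return not any(self.verdicts.values())


@dataclass(frozen=True)
class TargetEdge:
    """A lncRNA -> gene regulatory edge with its mechanism and evidence.

    ``evidence`` is overlap bp (antisense), gap bp (cis) or the Pearson r
    (trans); ``sign`` is set for trans edges only.
    """

    lncrna_id: str
    gene_id: str
    mechanism: str
    evidence: float
    sign: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("antisense", "cis", "trans"):
            raise ValidationError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "trans" and self.sign not in ("positive", "negative"):
            raise ValidationError("trans edges require sign 'positive' or 'negative'")


@dataclass(frozen=True)
class CeRNATriplet:
    """An mRNA-miRNA(s)-lncRNA competing-endogenous-RNA triplet.

    ``scc_mrna_mirna`` / ``scc_lncrna_mirna`` are the most negative Spearman
    coefficients across the shared miRNAs (all retained pairs individually
    pass the SCC filter).
    """

    mrna_id: str
    lncrna_id: str
    mirna_ids: Tuple[str, ...]
    scc_mrna_mirna: float
    scc_lncrna_mirna: float
    pcc_mrna_lncrna: float
    k_shared: int
    p_sponge: float

    def __post_init__(self) -> None:
        if self.k_shared < 1 or len(self.mirna_ids) != self.k_shared:
            raise ValidationError("k_shared must equal the number of shared miRNAs (>=1)")
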