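"""Readers/writers for the pipeline's file formats.

GTF is 1-based inclusive on disk (parsed with :mod:`gffutils`) and converted
to 0-based half-open coordinates in memory.  Expression matrices are TSV with
features as rows and a header row of sample ids; gene sets are GMT; the
miRNA-target table and the synthetic-truth manifest are TSV.
"""
from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd

from .models import GeneModel, TranscriptModel, ValidationError


def _gtf_attrs(feature: gffutils.Feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def read_gtf(path: str) -> Tuple[List[GeneModel], List[TranscriptModel]]:
    """Parse a GTF into coding gene models and lncRNA transcript models.

    Transcripts whose ``gene_biotype`` (or ``biotype``) attribute is
    ``protein_coding`` are grouped into :class:`GeneModel` records; the rest
    are returned as candidate lncRNA transcripts.  ``gene_id`` and
    ``transcript_id`` attributes are required on exon features.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, Optional[str], str]] = {}
    for ex in db.features_of_type("exon"):
        tid = _gtf_attrs(ex, "transcript_id")
        gid = _gtf_attrs(ex, "gene_id")
        if tid is None or gid is None:
            raise ValidationError(
                f"exon at {ex.seqid}:{ex.start} lacks gene_id/transcript_id"
            )
        biotype = _gtf_attrs(ex, "gene_biotype") or _gtf_attrs(ex, "biotype") or "protein_coding"
        exons.setdefault(tid, []).append((ex.start - 1, ex.end))  # to 0-based half-open
        meta[tid] = (ex.seqid, ex.strand, gid, biotype)

    genes: Dict[str, List[TranscriptModel]] = {}
    lncs: List[TranscriptModel] = []
    for tid, ivs in exons.items():
        chrom, strand, gid, biotype = meta[tid]
        t = TranscriptModel(
            id=tid, chrom=chrom, strand=strand, exons=tuple(sorted(ivs)), gene_id=gid
        )
        if biotype == "protein_coding":
            genes.setdefault(gid, []).append(t)
        else:
            lncs.append(t)

    gene_models = []
    for gid, ts in genes.items():
        span = (min(t.start for t in ts), max(t.end for t in ts))
        gene_models.append(
            GeneModel(
                id=gid,
                chrom=ts[0].chrom,
                strand=ts[0].strand,
                span=span,
                transcripts=tuple(ts),
                biotype="coding",
            )
        )
    gene_models.sort(key=lambda g: (g.chrom, g.start, g.id))
    lncs.sort(key=lambda t: (t.chrom, t.start, t.id))
    return gene_models, lncs


def _gtf_line(
    chrom: str,
    feature: str,
    start0: int,
    end0: int,
    strand: str,
    gene_id: str,
    transcript_id: Optional[str],
    biotype: str,
) -> str:
    attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
    if transcript_id:
        attrs += f' transcript_id "{transcript_id}";'
    return "\t".join(
        [chrom, "lncnet", feature, str(start0 + 1), str(end0), ".", strand, ".", attrs]
    )


def write_gtf(
    path: str,
    genes: Sequence[GeneModel],
    lncrnas: Sequence[TranscriptModel] = (),
    lnc_biotype: str = "lncRNA",
) -> None:
    """Write gene/transcript/exon rows in 1-based inclusive GTF."""
    lines: List[str] = []
    for g in genes:
        lines.append(_gtf_line(g.chrom, "gene", g.start, g.end, g.strand, g.id, None,
                               "protein_coding"))
        for t in g.transcripts:
            lines.append(_gtf_line(g.chrom, "transcript", t.start, t.end, t.strand,
                                   g.id, t.id, "protein_coding"))
            for s, e in t.exons:
                lines.append(_gtf_line(g.chrom, "exon", s, e, t.strand, g.id, t.id,
                                       "protein_coding"))
    for t in lncrnas:
        gid = t.gene_id or t.id
        lines.append(_gtf_line(t.chrom, "transcript", t.start, t.end, t.strand,
                               gid, t.id, lnc_biotype))
        for s, e in t.exons:
            lines.append(_gtf_line(t.chrom, "exon", s, e, t.strand, gid, t.id,
                                   lnc_biotype))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_matrix(path: str) -> pd.DataFrame:
    """Feature x sample TSV with the feature id in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_lengths(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def write_lengths(lengths: pd.Series, path: str) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="feature_id")


def read_design(path: str) -> pd.DataFrame:
    """Sample design TSV: sample_id, tissue, stage, replicate."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"stage": str})
    required = {"tissue", "stage", "replicate"}
    if not required <= set(df.columns):
        raise ValidationError(f"design file needs columns {sorted(required)}")
    return df


def write_design(design: pd.DataFrame, path: str) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_mirna_targets(path: str) -> pd.DataFrame:
    """miRNA-target TSV with columns mirna_id, target_id, target_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "target_id"} <= set(df.columns):
        raise ValidationError("target table needs columns mirna_id, target_id")
    if "target_class" not in df.columns:
        df["target_class"] = ""
    return df


def write_mirna_targets(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
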