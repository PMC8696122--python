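"""Novel-transcript filter, coding-potential consensus and lncRNA classification."""
import pytest

from lncnet.annotation import (
    ClassifyParams,
    classify_all,
    classify_lncrna,
    consensus_noncoding,
    filter_novel_transcripts,
    orf_heuristic,
    summarize_categories,
)
from lncnet.models import (
    CodingPotentialCall,
    GeneModel,
    LncRNARecord,
    TranscriptModel,
    ValidationError,
)


def tr(tid, exons, strand="+", chrom="chr1"):
    return TranscriptModel(id=tid, chrom=chrom, strand=strand, exons=tuple(exons))


def gene(gid, exons, strand="+", chrom="chr1"):
    t = TranscriptModel(id=f"{gid}.t1", chrom=chrom, strand=strand, exons=tuple(exons))
    return GeneModel(
        id=gid, chrom=chrom, strand=strand, span=(t.start, t.end),
        transcripts=(t,), biotype="coding",
    )


HOST = gene("G1", [(10_000, 11_000), (12_000, 13_000), (14_000, 15_000)])


class TestNovelFilter:
    @pytest.mark.parametrize(
        "exons,kept,rule",
        [
            ([(0, 100), (200, 300)], True, None),          # 2 exons, exactly 200 bp
            ([(0, 100), (200, 299)], False, "length"),     # 199 bp
            ([(0, 5000)], False, "exon_count"),            # single exon
        ],
    )
    def test_boundaries(self, exons, kept, rule):
        result, log = filter_novel_transcripts([tr("t", exons)])
        assert bool(result) is kept
        if rule:
            assert log == [("t", rule)]

    def test_idempotent(self):
        ts = [tr("a", [(0, 100), (200, 300)]), tr("b", [(0, 50), (60, 100)]),
              tr("c", [(0, 900)])]
        once, _ = filter_novel_transcripts(ts)
        twice, log = filter_novel_transcripts(once)
        assert twice == once and log == []


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.tuples(st.integers(0, 2_000), st.integers(1, 400)),
                min_size=1,
                max_size=5,
            ),
            min_size=0,
            max_size=8,
        )
    )
    def test_filter_idempotent_property(raw_transcripts):
        ts = []
        for i, pieces in enumerate(raw_transcripts):
            pos, exons = 0, []
            for gap, length in pieces:
                start = pos + gap
                exons.append((start, start + length))
                pos = start + length + 1
            ts.append(tr(f"t{i}", exons))
        once, _ = filter_novel_transcripts(ts)
        twice, log = filter_novel_transcripts(once)
        assert twice == once and log == []

except ImportError:  # pragma: no cover
    pass


class TestConsensus:
    def test_intersection_semantics(self):
        calls = [
            CodingPotentialCall("t1", {"cpc": False, "cnci": False, "protein_db": False}),
            CodingPotentialCall("t2", {"cpc": False, "cnci": False, "protein_db": True}),
            CodingPotentialCall("t3", {"cpc": True, "cnci": True, "protein_db": True}),
        ]
        assert consensus_noncoding(calls) == {"t1"}

    def test_empty(self):
        assert consensus_noncoding([]) == set()

    def test_missing_verdict_rejected(self):
        with pytest.raises(ValidationError):
            CodingPotentialCall("t", {"cpc": False, "cnci": False})


class TestOrfHeuristic:
    def test_no_atg_is_noncoding(self):
        assert orf_heuristic("C" * 90) is False

    def test_long_orf_is_coding(self):
        seq = "ATG" + "GCT" * 299 + "TAA"
        assert orf_heuristic(seq) is True

    def test_99_codon_orf_below_threshold(self):
        # ORF of exactly 99 codons (ATG + 98 sense codons), then a stop
        seq = "ATG" + "GCT" * 98 + "TAA"
        assert orf_heuristic(seq) is False
        assert orf_heuristic(seq, min_codons=99) is True

    def test_invalid_characters(self):
        with pytest.raises(ValidationError):
            orf_heuristic("ACGTXACGT")


class TestClassification:
    def test_antisense(self):
        lnc = tr("l", [(10_500, 11_200), (11_400, 11_600)], strand="-")
        rec = classify_lncrna(lnc, [HOST])
        assert rec.category == "antisense"
        assert rec.nearest_gene_id == "G1" and rec.distance_bp == 0

    def test_sense_overlapping(self):
        lnc = tr("l", [(10_500, 11_200), (11_400, 11_600)], strand="+")
        assert classify_lncrna(lnc, [HOST]).category == "sense_overlapping"

    def test_strand_flip_antisymmetry(self):
        exons = [(10_500, 11_200), (11_400, 11_600)]
        plus = classify_lncrna(tr("l", exons, strand="+"), [HOST])
        minus = classify_lncrna(tr("l", exons, strand="-"), [HOST])
        assert {plus.category, minus.category} == {"sense_overlapping", "antisense"}

    def test_intronic_either_strand(self):
        for strand in "+-":
            lnc = tr("l", [(11_100, 11_300), (11_500, 11_800)], strand=strand)
            assert classify_lncrna(lnc, [HOST]).category == "intronic"

    def test_bidirectional_divergent(self):
        lnc = tr("l", [(9_200, 9_500), (9_600, 9_800)], strand="-")
        rec = classify_lncrna(lnc, [HOST])
        assert rec.category == "bidirectional"
        assert rec.distance_bp == 200

    def test_bidirectional_requires_divergence(self):
        # same orientation as the gene: a plain upstream neighbour, not
        # bidirectional; within 5 kb it lands in the residual class
        lnc = tr("l", [(9_200, 9_500), (9_600, 9_800)], strand="+")
        assert classify_lncrna(lnc, [HOST]).category == "other"

    def test_intergenic_beyond_min_distance(self):
        lnc = tr("l", [(20_001, 20_300), (20_400, 20_700)])
        rec = classify_lncrna(lnc, [HOST])
        assert rec.category == "intergenic"
        assert rec.distance_bp == 5_001

    def test_other_in_proximal_band(self):
        lnc = tr("l", [(17_000, 17_300), (17_400, 17_700)])
        rec = classify_lncrna(lnc, [HOST])
        assert rec.category == "other" and rec.distance_bp == 2_000

    def test_empty_chromosome_is_intergenic(self):
        lnc = tr("l", [(100, 400), (500, 800)], chrom="chrUn")
        rec = classify_lncrna(lnc, [HOST])
        assert rec.category == "intergenic" and rec.nearest_gene_id is None

    def test_partition_property(self, noiseless_dataset):
        recs = classify_all(noiseless_dataset.lncrnas, noiseless_dataset.genes)
        assert len(recs) == len(noiseless_dataset.lncrnas)
        counts, _ = summarize_categories(recs)
        assert sum(counts.values()) == len(recs)

    def test_synthetic_recovery_is_exact(self, noiseless_dataset):
        truth = noiseless_dataset.truth.lncrna_category
        recs = classify_all(noiseless_dataset.lncrnas, noiseless_dataset.genes)
        assert all(r.category == truth[r.transcript.id] for r in recs)


class TestSummarize:
    def test_published_category_percentages(self):
        counts = {
            "intergenic": 1941,
            "bidirectional": 355,
            "antisense": 763,
            "sense_overlapping": 384,
            "other": 455,
        }
        _, pct = summarize_categories(counts)
        assert pct["intergenic"] == 49.8
        assert pct["bidirectional"] == 9.1
        assert pct["antisense"] == 19.6
        assert pct["sense_overlapping"] == 9.9
        assert pct["other"] == 11.7

    def test_exact_fractions_and_single(self):
        _, pct = summarize_categories({"intergenic": 1, "antisense": 3})
        assert pct["intergenic"] == 25.0 and pct["antisense"] == 75.0
        _, pct1 = summarize_categories({"intronic": 1})
        assert pct1["intronic"] == 100.0

    def test_empty_input(self):
        counts, pct = summarize_categories([])
        assert sum(counts.values()) == 0 and pct == {}
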