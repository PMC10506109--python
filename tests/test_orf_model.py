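import pytest

from orfkit.errors import MappingError, ParseError, ValidationError
from orfkit.orf_model import (
    GenomicInterval,
    ORFRecord,
    ProvenanceTag,
    TranscriptModel,
    orf_nt_length,
    read_orf_calls,
    read_transcript_models,
    to_transcript_coords,
    write_orf_calls,
    write_transcript_models,
)

from conftest import CHROM, make_orf, single_exon_tx


class TestGenomicInterval:
    def test_invalid_strand(self):
        with pytest.raises(ParseError):
            GenomicInterval("chr1", 0, 10, "*")

    def test_empty_interval(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10, "+")

    def test_len(self):
        assert len(GenomicInterval("chr1", 5, 20, "+")) == 15


class TestTranscriptModel:
    def test_minus_strand_tx_zero_is_rightmost_base(self):
        tx = TranscriptModel(
            "T", "G", "protein_coding",
            exons=(GenomicInterval("c", 0, 100, "-"), GenomicInterval("c", 200, 300, "-")),
        )
        assert tx.tx_to_genomic(0) == 299
        assert tx.genomic_to_tx(299) == 0
        assert tx.tx_to_genomic(tx.length - 1) == 0

    def test_empty_exon_chain_forbidden(self):
        with pytest.raises(ValidationError):
            TranscriptModel("T", "G", "protein_coding", exons=())

    def test_cds_must_be_divisible_by_three(self):
        with pytest.raises(ValidationError, match="divisible by 3"):
            single_exon_tx(cds=(10, 21))

    def test_cds_on_noncoding_biotype_rejected(self):
        with pytest.raises(ValidationError, match="noncoding biotype"):
            single_exon_tx(cds=(9, 18), biotype="lncRNA")

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_coordinate_round_trip_and_monotonicity(self, strand):
        tx = TranscriptModel(
            "T", "G", "lncRNA",
            exons=(
                GenomicInterval("c", 10, 60, strand),
                GenomicInterval("c", 100, 130, strand),
                GenomicInterval("c", 200, 220, strand),
            ),
        )
        genomic = [tx.tx_to_genomic(t) for t in range(tx.length)]
        assert sorted(genomic) == [*range(10, 60), *range(100, 130), *range(200, 220)]
        # strictly monotone along the transcript (direction depends on strand)
        deltas = [b - a for a, b in zip(genomic, genomic[1:])]
        assert all(d > 0 for d in deltas) if strand == "+" else all(d < 0 for d in deltas)
        for t in range(tx.length):
            assert tx.genomic_to_tx(genomic[t]) == t


class TestORFRecord:
    def test_length_not_divisible_rejected(self):
        with pytest.raises(ValidationError, match="divisible by 3"):
            make_orf("x", [(0, 10)])

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValidationError, match="overlapping blocks"):
            make_orf("x", [(0, 30), (20, 50)])

    def test_stop_codon_pos_derived_plus(self):
        orf = make_orf("x", [(0, 30)])
        assert orf.stop_codon_pos == 27

    def test_stop_codon_pos_derived_minus(self):
        orf = make_orf("x", [(0, 30)], strand="-")
        assert orf.stop_codon_pos == 2

    def test_stop_codon_split_across_blocks(self):
        # last block holds only 2 nt: stop codon spans the junction
        orf = make_orf("x", [(0, 28), (50, 52)])
        assert orf.stop_codon_pos == 27

    def test_aa_seq_length_checked(self):
        with pytest.raises(ValidationError, match="aa_seq"):
            ORFRecord("x", "", (GenomicInterval(CHROM, 0, 30, "+"),), aa_seq="MK")


class TestOrfNtLength:
    def test_36_nt_blocks_give_33(self):
        assert orf_nt_length(make_orf("x", [(0, 18), (30, 48)])) == 33

    def test_minimal_met_stop_orf(self):
        assert orf_nt_length(make_orf("x", [(0, 6)])) == 3

    def test_sixteen_codon_boundary(self):
        assert orf_nt_length(make_orf("x", [(0, 51)])) == 48

    def test_always_positive_multiple_of_three(self):
        import numpy as np

        from conftest import random_orf_set

        rng = np.random.default_rng(5)
        for orf in random_orf_set(rng):
            n = orf_nt_length(orf)
            assert n >= 3 and n % 3 == 0


class TestToTranscriptCoords:
    def test_single_exon_identity(self):
        tx = single_exon_tx(length=300, cds=None)
        orf = make_orf("x", [(30, 63)], transcript_id="TX1")
        assert to_transcript_coords(orf, tx) == (30, 63)

    def test_two_exon_cumulative_offsets(self):
        tx = TranscriptModel(
            "TX1", "G", "lncRNA",
            exons=(GenomicInterval(CHROM, 0, 100, "+"), GenomicInterval(CHROM, 200, 300, "+")),
        )
        orf = make_orf("x", [(90, 100), (200, 223)], transcript_id="TX1")
        assert to_transcript_coords(orf, tx) == (90, 123)

    def test_intronic_block_raises(self):
        tx = TranscriptModel(
            "TX1", "G", "lncRNA",
            exons=(GenomicInterval(CHROM, 0, 100, "+"), GenomicInterval(CHROM, 200, 300, "+")),
        )
        orf = make_orf("x", [(150, 180)], transcript_id="TX1")
        with pytest.raises(MappingError):
            to_transcript_coords(orf, tx)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_length_preserving(self, strand):
        tx = TranscriptModel(
            "TX1", "G", "lncRNA",
            exons=(GenomicInterval(CHROM, 0, 90, strand), GenomicInterval(CHROM, 150, 240, strand)),
        )
        blocks = tx.tx_interval_to_blocks(30, 120)
        orf = ORFRecord("x", "TX1", blocks)
        ts, te = to_transcript_coords(orf, tx)
        assert (ts, te) == (30, 120)
        assert te - ts == sum(len(b) for b in orf.blocks)


GTF_TEXT = """\
chrT\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; transcript_biotype "protein_coding";
chrT\tsrc\tCDS\t130\t162\t.\t+\t0\tgene_id "G1"; transcript_id "T1"; transcript_biotype "protein_coding";
chrT\tsrc\tstop_codon\t163\t165\t.\t+\t0\tgene_id "G1"; transcript_id "T1"; transcript_biotype "protein_coding";
"""


class TestReadTranscriptModels:
    def test_single_exon_conversion_and_stop_append(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(GTF_TEXT)
        models = read_transcript_models(path)
        tx = models["T1"]
        assert tx.exons[0].start == 99 and tx.exons[0].end == 200
        # CDS (129,162) genomic -> tx (30,63); stop codon appended -> (30,66)
        assert tx.cds_tx == (30, 66)
        assert tx.biotype == "protein_coding"

    def test_stop_appended_when_not_annotated(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text("\n".join(GTF_TEXT.splitlines()[:2]) + "\n")
        models = read_transcript_models(path)
        assert models["T1"].cds_tx == (30, 66)

    def test_cds_without_exons_is_validation_error(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            'chrT\tsrc\tCDS\t10\t42\t.\t+\t0\tgene_id "G"; transcript_id "T9";\n'
        )
        with pytest.raises(ValidationError, match="T9"):
            read_transcript_models(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(GTF_TEXT + "garbage line without tabs\n")
        with pytest.raises(ParseError, match="line 4"):
            read_transcript_models(path)

    def test_cds_outside_exons_names_transcript(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            'chrT\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G"; transcript_id "T1";\n'
            'chrT\tsrc\tCDS\t250\t282\t.\t+\t0\tgene_id "G"; transcript_id "T1";\n'
        )
        with pytest.raises(ValidationError, match="T1"):
            read_transcript_models(path)

    def test_minus_strand_two_exon_roundtrip(self, tmp_path, small_transcriptome):
        path = tmp_path / "sim.gtf"
        write_transcript_models(small_transcriptome.values(), path)
        models = read_transcript_models(path)
        assert set(models) == set(small_transcriptome)
        for tid, tx in small_transcriptome.items():
            assert models[tid].exons == tx.exons
            assert models[tid].cds_tx == tx.cds_tx
            assert models[tid].biotype == tx.biotype


class TestReadWriteOrfCalls:
    def test_bed12_two_block_arithmetic(self, tmp_path):
        path = tmp_path / "a.bed"
        row = "\t".join(
            ["chrT", "100", "250", "o1|T1", "0", "+", "100", "250", "0", "2", "18,18", "0,132"]
        )
        path.write_text(row + "\n")
        records, report = read_orf_calls(path)
        assert not report.rejected
        assert orf_nt_length(records[0]) == 33
        assert records[0].orf_id == "o1" and records[0].transcript_id == "T1"

    def test_overlapping_blocks_rejected_with_reason(self, tmp_path):
        path = tmp_path / "a.bed"
        row = "\t".join(
            ["chrT", "100", "160", "bad", "0", "+", "100", "160", "0", "2", "30,30", "0,20"]
        )
        path.write_text(row + "\n")
        records, report = read_orf_calls(path)
        assert records == []
        assert report.rejected[0][0] == "bad"
        assert "overlapping blocks" in report.rejected[0][1]

    def test_tsv_provenance_verbatim(self, tmp_path):
        path = tmp_path / "a.tsv"
        orf = make_orf("o1", [(0, 30)], transcript_id="T1")
        write_orf_calls([orf], path)
        records, report = read_orf_calls(path)
        assert not report.rejected
        assert records[0].source == ProvenanceTag("ds", "callerA", "rep1", "s1")

    def test_unknown_strand_is_parse_error(self, tmp_path):
        path = tmp_path / "a.tsv"
        orf = make_orf("o1", [(0, 30)])
        write_orf_calls([orf], path)
        path.write_text(path.read_text().replace("\t+\t", "\t?\t"))
        with pytest.raises(ParseError):
            read_orf_calls(path)

    def test_round_trip_bit_exact(self, tmp_path):
        orfs = [
            make_orf("o1", [(0, 18), (40, 58)], category=None),
            make_orf("o2", [(100, 160)], strand="-", replicate="rep3"),
        ]
        path = tmp_path / "calls.tsv"
        write_orf_calls(orfs, path)
        back, report = read_orf_calls(path)
        assert not report.rejected
        assert [(o.blocks, o.source, o.orf_id) for o in back] == [
            (o.blocks, o.source, o.orf_id) for o in orfs
        ]

    def test_bed12_round_trip(self, tmp_path):
        orfs = [make_orf("o1", [(0, 18), (40, 58)], transcript_id="T1")]
        path = tmp_path / "calls.bed"
        write_orf_calls(orfs, path, fmt="bed12")
        back, _ = read_orf_calls(path)
        assert back[0].blocks == orfs[0].blocks
        assert back[0].transcript_id == "T1"
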