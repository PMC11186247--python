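"""GFF3/FASTA I/O and domain-type invariants."""

import pytest

from annobench import (
    AnnotationSet,
    ExonInterval,
    Gff3Error,
    TranscriptModel,
    GenomeSequence,
    normalize_stop_codons,
    read_fasta,
    read_gff3,
    unique_cds_intervals,
    write_fasta,
    write_gff3,
)
from annobench.genes import chain_key

from conftest import annotation_from_chains, iv

GFF_BASIC = """##gff-version 3
c1\tsrc\tgene\t100\t400\t.\t+\t.\tID=g1
c1\tsrc\tmRNA\t100\t400\t.\t+\t.\tID=t1;Parent=g1
c1\tsrc\tCDS\t100\t200\t.\t+\t0\tID=cds1;Parent=t1
c1\tsrc\tCDS\t300\t400\t.\t+\t0\tID=cds2;Parent=t1
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestExonInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ExonInterval("c1", 0, 10, "+")
        with pytest.raises(ValueError):
            ExonInterval("c1", 10, 5, "+")
        with pytest.raises(ValueError):
            ExonInterval("c1", 1, 10, ".")

    def test_overlap_is_strand_and_seqid_aware(self):
        a = iv("c1", 100, 200)
        assert a.overlaps(iv("c1", 200, 300))
        assert not a.overlaps(iv("c1", 201, 300))
        assert not a.overlaps(iv("c1", 100, 200, "-"))
        assert not a.overlaps(iv("c2", 100, 200))


class TestReadGff3:
    def test_basic_hierarchy(self, tmp_path):
        ann = read_gff3(_write(tmp_path, "a.gff3", GFF_BASIC))
        assert ann.n_genes == 1 and ann.n_transcripts == 1
        (tx,) = list(ann.transcripts())
        assert [(c.start, c.end) for c in tx.cds_chain] == [(100, 200), (300, 400)]

    def test_multi_line_cds_grouped_and_sorted(self, tmp_path):
        text = GFF_BASIC + "c1\tsrc\tCDS\t250\t260\t.\t+\t0\tID=cds3;Parent=t1\n"
        ann = read_gff3(_write(tmp_path, "a.gff3", text))
        (tx,) = list(ann.transcripts())
        assert [c.start for c in tx.cds_chain] == [100, 250, 300]

    def test_orphan_cds_under_gene_gets_auto_transcript(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "c1\tsrc\tgene\t10\t50\t.\t-\t.\tID=gX\n"
            "c1\tsrc\tCDS\t10\t50\t.\t-\t0\tID=cdsX;Parent=gX\n"
        )
        ann = read_gff3(_write(tmp_path, "a.gff3", text))
        assert ann.n_genes == 1
        (tx,) = list(ann.transcripts())
        assert tx.gene_id == "gX" and tx.strand == "-"

    def test_missing_parent_feature_named_in_error(self, tmp_path):
        text = GFF_BASIC + "c1\tsrc\tCDS\t500\t600\t.\t+\t0\tID=cds9;Parent=ghost\n"
        with pytest.raises(Gff3Error, match="cds9|ghost"):
            read_gff3(_write(tmp_path, "a.gff3", text))

    def test_cds_without_parent_attribute_rejected(self, tmp_path):
        text = "##gff-version 3\nc1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=lone\n"
        with pytest.raises(Gff3Error, match="lone"):
            read_gff3(_write(tmp_path, "a.gff3", text))

    def test_malformed_line_error_names_line_number(self, tmp_path):
        text = GFF_BASIC + "c1\tbroken row\n"
        with pytest.raises(Gff3Error, match="line 6"):
            read_gff3(_write(tmp_path, "a.gff3", text))

    def test_dotted_strand_on_cds_rejected(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "c1\tsrc\tgene\t10\t50\t.\t+\t.\tID=g1\n"
            "c1\tsrc\tmRNA\t10\t50\t.\t+\t.\tID=t1;Parent=g1\n"
            "c1\tsrc\tCDS\t10\t50\t.\t.\t0\tID=c1;Parent=t1\n"
        )
        with pytest.raises(Gff3Error, match="strand"):
            read_gff3(_write(tmp_path, "a.gff3", text))

    def test_custom_cds_feature_type(self, tmp_path):
        text = GFF_BASIC.replace("\tCDS\t", "\tcds\t")
        assert read_gff3(_write(tmp_path, "a.gff3", text)).n_genes == 0
        ann = read_gff3(tmp_path / "a.gff3", cds_feature_types={"cds"})
        assert ann.n_genes == 1


class TestWriteGff3:
    def test_round_trip_preserves_structure(self, tmp_path):
        ann = annotation_from_chains(
            [
                [("c1", 100, 200, "+"), ("c1", 300, 400, "+")],
                [("c2", 50, 80, "-")],
            ]
        )
        path = tmp_path / "out.gff3"
        write_gff3(ann, path)
        back = read_gff3(path)
        assert back.n_genes == ann.n_genes
        assert back.n_transcripts == ann.n_transcripts
        assert unique_cds_intervals(back) == unique_cds_intervals(ann)
        assert {chain_key(t) for t in back.transcripts()} == {
            chain_key(t) for t in ann.transcripts()
        }

    def test_empty_annotation_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.gff3"
        write_gff3(AnnotationSet(), path)
        assert path.read_text() == "##gff-version 3\n"

    def test_opposite_strands_preserved(self, tmp_path):
        ann = annotation_from_chains(
            [[("c1", 10, 20, "+")], [("c1", 100, 120, "-")]]
        )
        path = tmp_path / "s.gff3"
        write_gff3(ann, path)
        strands = {t.strand for t in read_gff3(path).transcripts()}
        assert strands == {"+", "-"}


class TestUniqueCdsIntervals:
    def test_shared_isoform_exon_counted_once(self):
        from annobench import GeneModel

        shared = iv("c1", 100, 200)
        t1 = TranscriptModel("t1", "g1", [shared, iv("c1", 300, 400)])
        t2 = TranscriptModel("t2", "g1", [shared])
        ann = AnnotationSet(genes=[GeneModel("g1", [t1, t2])])
        assert unique_cds_intervals(ann) == {shared, iv("c1", 300, 400)}

    def test_strand_is_part_of_the_key(self):
        ann = annotation_from_chains(
            [[("c1", 100, 200, "+")], [("c1", 100, 200, "-")]]
        )
        assert len(unique_cds_intervals(ann)) == 2

    def test_empty_annotation(self):
        assert unique_cds_intervals(AnnotationSet()) == set()


class TestStopCodonNormalization:
    def test_include_extends_three_prime_terminal_exon(self):
        ann = annotation_from_chains([[("c1", 100, 200, "+"), ("c1", 300, 400, "+")]])
        out = normalize_stop_codons(ann, "include")
        (tx,) = list(out.transcripts())
        assert (tx.cds_chain[0].end, tx.cds_chain[1].end) == (200, 403)

    def test_exclude_on_minus_strand_trims_first_interval(self):
        ann = annotation_from_chains([[("c1", 100, 200, "-"), ("c1", 300, 400, "-")]])
        out = normalize_stop_codons(ann, "exclude")
        (tx,) = list(out.transcripts())
        assert tx.cds_chain[0].start == 103

    def test_as_is_returns_input_unchanged(self):
        ann = annotation_from_chains([[("c1", 100, 200, "+")]])
        assert normalize_stop_codons(ann, "as-is") is ann


class TestFasta:
    def test_basic_read_uppercases(self, tmp_path):
        p = _write(tmp_path, "a.fa", ">c1\natgc\n")
        (seq,) = read_fasta(p)
        assert seq.seqid == "c1" and seq.sequence == "ATGC"

    def test_header_first_token_and_order(self, tmp_path):
        p = _write(tmp_path, "a.fa", ">c1 some description\nAAA\n>c2\nCCC\n")
        seqs = read_fasta(p)
        assert [s.seqid for s in seqs] == ["c1", "c2"]

    def test_duplicate_seqid_rejected(self, tmp_path):
        p = _write(tmp_path, "a.fa", ">c1\nAAA\n>c1\nCCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_empty_record_rejected(self, tmp_path):
        p = _write(tmp_path, "a.fa", ">c1\n>c2\nAAA\n")
        with pytest.raises(ValueError, match="empty"):
            read_fasta(p)

    def test_write_read_round_trip(self, tmp_path):
        seqs = [GenomeSequence("s1", "ACGT" * 40), GenomeSequence("s2", "TTTT")]
        p = tmp_path / "w.fa"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(s.seqid, s.sequence) for s in back] == [
            (s.seqid, s.sequence) for s in seqs
        ]
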