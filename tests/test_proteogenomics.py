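"""Six-frame translation, decoys, and peptide-set overlap."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq, reverse_complement
from hypothesis import given, strategies as st

from annobench import (
    GenomeSequence,
    PeptideSet,
    generate_decoys,
    peptide_overlap,
    read_peptide_list,
    six_frame_translate,
    translate_frame,
)
from annobench.proteogenomics import ProteinEntry

dna = st.text(alphabet="ACGT", min_size=3, max_size=400)


def oracle_segments(sequence: str, frame: int, min_len: int) -> list[str]:
    """Independent per-frame oracle via Biopython translation."""
    seq = sequence if frame > 0 else reverse_complement(sequence)
    offset = abs(frame) - 1
    sub = seq[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    protein = str(Seq(sub).translate())
    return [s for s in protein.split("*") if len(s) >= min_len]


class TestTranslateFrame:
    def test_forward_frame_one(self):
        assert translate_frame("ATGAAATGA", 1) == "MK*"

    def test_reverse_frame_one(self):
        # revcomp is TCATTTCAT -> TCA TTT CAT
        assert translate_frame("ATGAAATGA", -1) == "SFH"

    def test_ambiguous_codon_is_x(self):
        assert translate_frame("ATGNNNAAA", 1) == "MXK"

    def test_invalid_frame_rejected(self):
        with pytest.raises(ValueError):
            translate_frame("ATG", 4)


class TestSixFrame:
    def test_min_len_filters_all(self):
        out = six_frame_translate([GenomeSequence("c1", "ATGAAATGA")], min_len=50)
        assert out == []

    def test_min_len_must_be_positive(self):
        with pytest.raises(ValueError):
            six_frame_translate([GenomeSequence("c1", "ATG")], min_len=0)

    def test_ids_encode_seqid_frame_ordinal(self):
        out = six_frame_translate([GenomeSequence("c1", "ATGAAATGA")], min_len=1)
        assert all(e.id.startswith("c1|frame") for e in out)
        assert any("|frame+1|" in e.id for e in out)
        assert any("|frame-1|" in e.id for e in out)

    def test_drop_x_segments_flag(self):
        seqs = [GenomeSequence("c1", "ATGNNNAAA")]
        kept = six_frame_translate(seqs, min_len=1)
        dropped = six_frame_translate(seqs, min_len=1, drop_x_segments=True)
        assert any("X" in e.sequence for e in kept)
        assert not any("X" in e.sequence for e in dropped)

    @given(dna, st.integers(1, 10))
    def test_matches_naive_per_frame_oracle(self, sequence, min_len):
        got = six_frame_translate([GenomeSequence("c1", sequence)], min_len=min_len)
        by_frame = {}
        for e in got:
            frame = int(e.id.split("|")[1].removeprefix("frame"))
            by_frame.setdefault(frame, []).append(e.sequence)
        for frame in (1, 2, 3, -1, -2, -3):
            assert by_frame.get(frame, []) == oracle_segments(
                sequence, frame, min_len
            ), f"frame {frame} of {sequence!r}"

    @given(dna)
    def test_reverse_complement_swaps_frames(self, sequence):
        """Translating the reverse complement yields the same multiset of
        segments with forward/reverse frame labels exchanged."""
        fwd = six_frame_translate([GenomeSequence("c1", sequence)], min_len=1)
        rev = six_frame_translate(
            [GenomeSequence("c1", reverse_complement(sequence))], min_len=1
        )

        def multiset(entries, sign):
            return Counter(
                e.sequence
                for e in entries
                if int(e.id.split("|")[1].removeprefix("frame")) * sign > 0
            )

        assert multiset(fwd, +1) == multiset(rev, -1)
        assert multiset(fwd, -1) == multiset(rev, +1)

    @given(dna)
    def test_per_frame_codon_count_conservation(self, sequence):
        """Residues plus stops in frame offset f total floor((L-f)/3)."""
        length = len(sequence)
        for frame in (1, 2, 3, -1, -2, -3):
            protein = translate_frame(sequence, frame)
            assert len(protein) == (length - (abs(frame) - 1)) // 3


class TestDecoys:
    def test_reversal_and_tag(self):
        (decoy,) = generate_decoys([ProteinEntry("p1", "PEPTIDE")])
        assert decoy.sequence == "EDITPEP"
        assert decoy.id == "rev_p1"

    def test_palindrome_still_tagged(self):
        (decoy,) = generate_decoys([ProteinEntry("p1", "ABA")])
        assert decoy.sequence == "ABA" and decoy.id.startswith("rev_")

    def test_cardinality_and_composition_preserved(self, rng):
        targets = [
            ProteinEntry(f"p{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                                     size=int(rng.integers(5, 30)))))
            for i in range(20)
        ]
        decoys = generate_decoys(targets)
        assert len(decoys) == len(targets)
        for t, d in zip(targets, decoys):
            assert Counter(t.sequence) == Counter(d.sequence)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            generate_decoys([])


def _ps(label, *peps):
    return PeptideSet(label=label, peptides=frozenset(peps))


class TestPeptideOverlap:
    def test_half_overlap_fixture(self):
        report = peptide_overlap([_ps("ref", "A", "B"), _ps("s", "A")], "ref")
        assert report.overlap_percent["s"] == pytest.approx(50.0)
        assert report.regions[frozenset({"ref"})] == 1
        assert report.regions[frozenset({"ref", "s"})] == 1
        assert report.regions[frozenset({"s"})] == 0

    def test_identical_sets_full_overlap(self):
        report = peptide_overlap([_ps("ref", "A", "B"), _ps("s", "A", "B")], "ref")
        assert report.overlap_percent["s"] == pytest.approx(100.0)

    def test_disjoint_sets_zero_overlap(self):
        report = peptide_overlap([_ps("ref", "A"), _ps("s", "B")], "ref")
        assert report.overlap_percent["s"] == pytest.approx(0.0)
        assert report.regions[frozenset({"ref", "s"})] == 0

    def test_errors_on_bad_labels(self):
        with pytest.raises(ValueError, match="duplicate"):
            peptide_overlap([_ps("x", "A"), _ps("x", "B")], "x")
        with pytest.raises(ValueError, match="reference_label"):
            peptide_overlap([_ps("a", "A"), _ps("b", "B")], "zzz")
        with pytest.raises(ValueError, match="2-4"):
            peptide_overlap([_ps("a", "A")], "a")

    def test_il_equivalence_flag(self):
        report = peptide_overlap(
            [_ps("ref", "PILK"), _ps("s", "PLLK")], "ref", il_equivalent=True
        )
        assert report.overlap_percent["s"] == pytest.approx(100.0)
        strict = peptide_overlap([_ps("ref", "PILK"), _ps("s", "PLLK")], "ref")
        assert strict.overlap_percent["s"] == pytest.approx(0.0)

    @given(st.integers(0, 2**32 - 1), st.integers(2, 4))
    def test_venn_partition_sums_to_union(self, seed, n_sets):
        rng = np.random.default_rng(seed)
        universe = [f"PEP{i}" for i in range(30)]
        sets = [
            _ps(f"s{k}", *(p for p in universe if rng.random() < 0.4))
            or _ps(f"s{k}")
            for k in range(n_sets)
        ]
        report = peptide_overlap(sets, "s0")
        union = set().union(*(s.peptides for s in sets))
        assert report.union_size == len(union)
        assert sum(report.regions.values()) == len(union)
        assert all(0 <= v <= 100 or np.isnan(v)
                   for v in report.overlap_percent.values())


def test_read_peptide_list_formats(tmp_path):
    p = tmp_path / "peps.tsv"
    p.write_text("peptide\tscore\nAAK\t0.9\nLLR\t0.8\nAAK\t0.7\n# comment\n")
    ps = read_peptide_list(p, label="run1")
    assert ps.label == "run1"
    assert ps.peptides == frozenset({"AAK", "LLR"})
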