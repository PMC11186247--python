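"""Proteogenomic search-space construction and peptide-set overlap.

Six-frame translation enumerates every possible protein reading of a
genome: frames +1..+3 translate the forward strand at codon offsets 0..2,
frames -1..-3 translate the reverse complement at offsets 0..2 (so -k means
offset k-1 on the reverse complement). Translation uses the standard
genetic code; any codon containing an ambiguity code is rendered as X, and
segments are split at stop codons. This yields the open-reading-frame-free
search space used to benchmark predicted proteomes: peptides identified
against a predicted database are compared with those identified against
the reference database, and a high overlap means the prediction is a
reliable search space.

Decoy generation here is per-entry sequence reversal — the usual
target-decoy construction preserving length and amino-acid composition.
PSM scoring and FDR filtering happen upstream; this module consumes
already-filtered peptide lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

__all__ = [
    "ProteinEntry",
    "PeptideSet",
    "OverlapReport",
    "six_frame_translate",
    "translate_frame",
    "generate_decoys",
    "peptide_overlap",
    "read_peptide_list",
    "write_protein_fasta",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class ProteinEntry:
    """One translated segment; id encodes seqid, frame and ordinal."""

    id: str
    sequence: str


@dataclass(frozen=True)
class PeptideSet:
    label: str
    peptides: frozenset[str]

    def __post_init__(self) -> None:
        if any(not p for p in self.peptides):
            raise ValueError(f"peptide set {self.label!r} contains empty strings")


@dataclass
class OverlapReport:
    """Venn partition over 2-4 peptide sets plus reference-relative overlap %."""

    labels: tuple[str, ...]
    reference_label: str
    regions: dict[frozenset, int] = field(default_factory=dict)
    overlap_percent: dict[str, float] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def translate_frame(sequence: str, frame: int) -> str:
    """Translate one frame; stops as '*', ambiguous codons as 'X'."""
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    seq = sequence.upper()
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    residues = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOP_CODONS:
            residues.append("*")
        else:
            residues.append(_CODON_TABLE.get(codon, "X"))
    return "".join(residues)


def six_frame_translate(
    seqs: Iterable,
    min_len: int = 7,
    drop_x_segments: bool = False,
) -> list[ProteinEntry]:
    """Translate all six frames, splitting at stops, keeping segments >= min_len.

    ``min_len`` defaults to 7 residues — below the shortest peptides a
    search engine typically reports. Segments containing X are kept by
    default (a single ambiguous base should not erase a whole segment);
    ``drop_x_segments`` discards them.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    entries: list[ProteinEntry] = []
    for seq in seqs:
        for frame in FRAMES:
            protein = translate_frame(seq.sequence, frame)
            frame_tag = f"+{frame}" if frame > 0 else str(frame)
            ordinal = 0
            for segment in protein.split("*"):
                if len(segment) < min_len:
                    continue
                if drop_x_segments and "X" in segment:
                    continue
                ordinal += 1
                entries.append(
                    ProteinEntry(
                        id=f"{seq.seqid}|frame{frame_tag}|seg{ordinal}",
                        sequence=segment,
                    )
                )
    return entries


def generate_decoys(
    entries: Sequence[ProteinEntry],
    decoy_tag: str = "rev_",
) -> list[ProteinEntry]:
    """One reversed-sequence decoy per target, id prefixed with the tag."""
    if not entries:
        raise ValueError("no target entries to generate decoys from")
    return [
        ProteinEntry(id=f"{decoy_tag}{e.id}", sequence=e.sequence[::-1])
        for e in entries
    ]


def _normalize_il(peptides: frozenset[str]) -> frozenset[str]:
    return frozenset(p.replace("I", "L") for p in peptides)


def peptide_overlap(
    sets: Sequence[PeptideSet],
    reference_label: str,
    il_equivalent: bool = False,
) -> OverlapReport:
    """Exact Venn partition of 2-4 peptide sets and overlap % vs a reference.

    ``il_equivalent`` folds isoleucine onto leucine before comparison
    (indistinguishable by mass spectrometry); off by default.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"need 2-4 peptide sets, got {len(sets)}")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels: {labels}")
    if reference_label not in labels:
        raise ValueError(
            f"reference_label {reference_label!r} not among {labels}"
        )
    members = {
        s.label: (_normalize_il(s.peptides) if il_equivalent else s.peptides)
        for s in sets
    }
    union = frozenset().union(*members.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            in_labels = frozenset(combo)
            out_labels = set(labels) - in_labels
            count = sum(
                1
                for pep in union
                if all(pep in members[l] for l in in_labels)
                and not any(pep in members[l] for l in out_labels)
            )
            regions[in_labels] = count
    reference = members[reference_label]
    overlap_percent = {}
    for label in labels:
        if label == reference_label:
            continue
        overlap_percent[label] = (
            100.0 * len(members[label] & reference) / len(reference)
            if reference
            else float("nan")
        )
    return OverlapReport(
        labels=tuple(labels),
        reference_label=reference_label,
        regions=regions,
        overlap_percent=overlap_percent,
    )


def read_peptide_list(path: str | Path, label: str | None = None) -> PeptideSet:
    """Read peptides from text: one per line, or first column of a TSV.

    Lines starting with '#' and a leading 'peptide' header are skipped.
    """
    path = Path(path)
    peptides = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if not token or token.startswith("#"):
                continue
            if token.lower() in {"peptide", "sequence"}:
                continue
            peptides.add(token)
    return PeptideSet(label=label or path.stem, peptides=frozenset(peptides))


def write_protein_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.id}\n{e.sequence}\n")
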