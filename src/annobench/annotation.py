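"""Domain model for genome annotations and sequences, plus GFF3/FASTA I/O.

Coordinates are GFF3-native throughout: 1-based, inclusive on both ends.
No half-open conversion happens anywhere in the package, which removes the
usual source of off-by-one errors in exact-boundary comparison.

The hierarchy mirrors GFF3: genes contain transcripts (mRNA features),
transcripts carry an ordered chain of CDS segments. Only CDS features are
read by default; exact-boundary evaluation operates on CDS coordinates and
strand, never on phase/frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from Bio import SeqIO

__all__ = [
    "ExonInterval",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "GenomeSequence",
    "Gff3Error",
    "read_gff3",
    "write_gff3",
    "unique_cds_intervals",
    "read_fasta",
    "write_fasta",
    "normalize_stop_codons",
]

VALID_STRANDS = frozenset({"+", "-"})


class Gff3Error(ValueError):
    """Raised for malformed or unresolvable GFF3 content."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """One CDS segment: seqid, 1-based inclusive start/end, strand."""

    seqid: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "ExonInterval") -> bool:
        """Shared >=1 bp on the same seqid and strand."""
        return (
            self.seqid == other.seqid
            and self.strand == other.strand
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class TranscriptModel:
    """A transcript's CDS chain: ordered, non-overlapping, one seqid/strand."""

    transcript_id: str
    gene_id: str
    cds_chain: list[ExonInterval]

    def __post_init__(self) -> None:
        chain = sorted(self.cds_chain, key=lambda iv: iv.start)
        if chain:
            seqids = {iv.seqid for iv in chain}
            strands = {iv.strand for iv in chain}
            if len(seqids) > 1 or len(strands) > 1:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS chain spans multiple "
                    f"seqids/strands ({seqids}, {strands})"
                )
            for a, b in zip(chain, chain[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"transcript {self.transcript_id}: overlapping CDS "
                        f"({a.start},{a.end}) and ({b.start},{b.end})"
                    )
        self.cds_chain = chain

    @property
    def seqid(self) -> str:
        return self.cds_chain[0].seqid

    @property
    def strand(self) -> str:
        return self.cds_chain[0].strand


@dataclass
class GeneModel:
    """A gene with one or more transcript isoforms."""

    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")


@dataclass
class AnnotationSet:
    """A full annotation: genes -> transcripts -> CDS chains."""

    genes: list[GeneModel] = field(default_factory=list)
    source_label: str = "annotation"

    def __post_init__(self) -> None:
        gene_ids = [g.gene_id for g in self.genes]
        if len(gene_ids) != len(set(gene_ids)):
            raise ValueError("duplicate gene_id in AnnotationSet")
        tx_ids = [t.transcript_id for g in self.genes for t in g.transcripts]
        if len(tx_ids) != len(set(tx_ids)):
            raise ValueError("duplicate transcript_id in AnnotationSet")

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self.genes:
            yield from gene.transcripts

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes)


@dataclass
class GenomeSequence:
    """One assembly sequence (contig/scaffold/chromosome), uppercased."""

    seqid: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.seqid!r} is empty")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# GFF3 reading
# ---------------------------------------------------------------------------

_GENE_TYPES = {"gene", "pseudogene"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def _validate_gff3_lines(path: str | Path) -> None:
    """Pre-pass giving line-numbered errors for structurally broken rows."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.startswith(">"):  # trailing FASTA section
                return
            fields = stripped.split("\t")
            if len(fields) != 9:
                raise Gff3Error(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise Gff3Error(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from exc
            if start < 1 or end < start:
                raise Gff3Error(
                    f"{path}: line {lineno}: invalid interval [{start},{end}]"
                )


def read_gff3(
    path: str | Path,
    cds_feature_types: Iterable[str] = ("CDS",),
    source_label: str | None = None,
) -> AnnotationSet:
    """Read a GFF3 file into an :class:`AnnotationSet`.

    CDS features are attached to their transcript through the Parent
    attribute and transcripts to their gene likewise. CDS rows whose Parent
    is a gene directly (no mRNA level) get one auto-generated transcript per
    gene. Coordinates are kept 1-based inclusive, exactly as in the file.

    Raises
    ------
    Gff3Error
        On malformed rows (with line number), a CDS without a resolvable
        Parent, or a CDS with strand ``.`` (strand is required for
        exact-boundary evaluation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gff3_lines(path)
    cds_types = set(cds_feature_types)

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    # transcript_id -> (gene_id, [intervals]); preserve encounter order
    tx_chains: dict[str, list[ExonInterval]] = {}
    tx_gene: dict[str, str] = {}
    gene_order: list[str] = []
    auto_tx_count = 0

    def _feature_id(feat: gffutils.Feature) -> str:
        return feat.id

    for feat in db.all_features():
        if feat.featuretype not in cds_types:
            continue
        if feat.strand not in VALID_STRANDS:
            raise Gff3Error(
                f"{path}: CDS {feat.id!r} at {feat.seqid}:{feat.start}-{feat.end} "
                f"has strand {feat.strand!r}; '+' or '-' required for evaluation"
            )
        parents = feat.attributes.get("Parent", [])
        if not parents:
            raise Gff3Error(
                f"{path}: CDS feature {feat.id!r} has no Parent attribute"
            )
        interval = ExonInterval(feat.seqid, feat.start, feat.end, feat.strand)
        for parent_id in parents:
            try:
                parent = db[parent_id]
            except gffutils.FeatureNotFoundError as exc:
                raise Gff3Error(
                    f"{path}: CDS feature {feat.id!r} references missing "
                    f"Parent {parent_id!r}"
                ) from exc
            if parent.featuretype in _GENE_TYPES:
                # orphan CDS directly under a gene: one synthetic transcript
                gene_id = _feature_id(parent)
                tx_id = f"{gene_id}.auto_t1"
                auto_tx_count += 1
            else:
                tx_id = _feature_id(parent)
                grandparents = parent.attributes.get("Parent", [])
                gene_id = grandparents[0] if grandparents else tx_id
            if tx_id not in tx_chains:
                tx_chains[tx_id] = []
                tx_gene[tx_id] = gene_id
                if gene_id not in gene_order:
                    gene_order.append(gene_id)
            tx_chains[tx_id].append(interval)

    genes_map: dict[str, list[TranscriptModel]] = {g: [] for g in gene_order}
    for tx_id, chain in tx_chains.items():
        gene_id = tx_gene[tx_id]
        genes_map[gene_id].append(
            TranscriptModel(transcript_id=tx_id, gene_id=gene_id, cds_chain=chain)
        )

    genes = [
        GeneModel(gene_id=gid, transcripts=genes_map[gid])
        for gid in gene_order
        if genes_map[gid]
    ]
    return AnnotationSet(genes=genes, source_label=source_label or path.stem)


def write_gff3(ann: AnnotationSet, path: str | Path) -> None:
    """Write gene/mRNA/CDS rows with Parent links; round-trip safe."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in ann.genes:
            g_start = min(iv.start for t in gene.transcripts for iv in t.cds_chain)
            g_end = max(iv.end for t in gene.transcripts for iv in t.cds_chain)
            strand = gene.transcripts[0].strand
            seqid = gene.transcripts[0].seqid
            src = ann.source_label
            fh.write(
                f"{seqid}\t{src}\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for tx in gene.transcripts:
                t_start = tx.cds_chain[0].start
                t_end = tx.cds_chain[-1].end
                fh.write(
                    f"{tx.seqid}\t{src}\tmRNA\t{t_start}\t{t_end}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gene.gene_id}\n"
                )
                for i, iv in enumerate(tx.cds_chain, start=1):
                    fh.write(
                        f"{iv.seqid}\t{src}\tCDS\t{iv.start}\t{iv.end}\t.\t"
                        f"{iv.strand}\t.\tID=cds.{tx.transcript_id}.{i};"
                        f"Parent={tx.transcript_id}\n"
                    )


def unique_cds_intervals(ann: AnnotationSet) -> set[ExonInterval]:
    """Deduplicated CDS intervals keyed by (seqid, start, end, strand).

    Shared exons across isoforms are counted once, so CDS-level metrics
    reflect prediction quality, not isoform multiplicity.
    """
    return {iv for tx in ann.transcripts() for iv in tx.cds_chain}


def normalize_stop_codons(ann: AnnotationSet, mode: str = "as-is") -> AnnotationSet:
    """Harmonize the stop-codon convention of terminal CDS segments.

    GFF3 dialects differ on whether the stop codon lies inside the terminal
    CDS. ``include`` extends each chain's 3'-terminal segment by 3 bp;
    ``exclude`` trims it by 3 bp; ``as-is`` (default) leaves coordinates
    untouched. Apply the same mode to both annotations before comparison,
    or terminal exons will systematically fail exact matching.
    """
    if mode == "as-is":
        return ann
    if mode not in {"include", "exclude"}:
        raise ValueError(f"mode must be include|exclude|as-is, got {mode!r}")
    delta = 3 if mode == "include" else -3
    genes = []
    for gene in ann.genes:
        txs = []
        for tx in gene.transcripts:
            chain = list(tx.cds_chain)
            if tx.strand == "+":
                last = chain[-1]
                chain[-1] = ExonInterval(
                    last.seqid, last.start, last.end + delta, last.strand
                )
            else:
                first = chain[0]
                chain[0] = ExonInterval(
                    first.seqid, max(1, first.start - delta), first.end, first.strand
                )
            txs.append(TranscriptModel(tx.transcript_id, tx.gene_id, chain))
        genes.append(GeneModel(gene.gene_id, txs))
    return AnnotationSet(genes=genes, source_label=ann.source_label)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file; seqid is the first whitespace token of the header."""
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"{path}: duplicate seqid {record.id!r}")
        if len(record.seq) == 0:
            raise ValueError(f"{path}: empty record {record.id!r}")
        seen.add(record.id)
        seqs.append(GenomeSequence(seqid=record.id, sequence=str(record.seq)))
    return seqs


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.seqid}\n")
            s = seq.sequence
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
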