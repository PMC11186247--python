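"""Assembly contiguity and composition statistics.

N50 is the length of the shortest contig in the smallest set of longest
contigs whose cumulative length reaches at least half the assembly size;
L50 is the size of that set. A contig reaching exactly half counts (>=,
not >), the conventional definition. GC% by default is computed over
unambiguous bases only — 100*(G+C)/(A+C+G+T) — because Ns inflate the
denominator on draft assemblies; a flag switches to total length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import GenomeSequence

__all__ = ["AssemblyStats", "compute_stats", "n50_l50"]


@dataclass(frozen=True)
class AssemblyStats:
    total_size: int
    n_contigs: int
    n50: int
    l50: int
    gc_percent: float

    def as_dict(self) -> dict[str, float | int]:
        return {
            "total_size": self.total_size,
            "n_contigs": self.n_contigs,
            "n50": self.n50,
            "l50": self.l50,
            "gc_percent": self.gc_percent,
        }


def n50_l50(lengths: Sequence[int]) -> tuple[int, int]:
    """(N50, L50) of a multiset of contig lengths."""
    if not lengths:
        raise ValueError("at least one contig required")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    cumulative = 0
    for i, length in enumerate(ordered, start=1):
        cumulative += length
        if cumulative >= half:
            return length, i
    raise AssertionError("unreachable")


def compute_stats(
    seqs: Iterable[GenomeSequence],
    gc_over_total_length: bool = False,
) -> AssemblyStats:
    """Compute size, contig count, N50/L50 and GC% for an assembly."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("at least one sequence required")
    lengths = [len(s) for s in seqs]
    total = sum(lengths)
    n50, l50 = n50_l50(lengths)
    gc = at = 0
    for s in seqs:
        seq = s.sequence
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    denominator = total if gc_over_total_length else gc + at
    gc_percent = 100.0 * gc / denominator if denominator else 0.0
    return AssemblyStats(
        total_size=total,
        n_contigs=len(seqs),
        n50=n50,
        l50=l50,
        gc_percent=gc_percent,
    )
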