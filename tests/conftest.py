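"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from annobench import (
    AnnotationSet,
    ExonInterval,
    GeneModel,
    TranscriptModel,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def iv(seqid: str, start: int, end: int, strand: str = "+") -> ExonInterval:
    return ExonInterval(seqid, start, end, strand)


def annotation_from_chains(
    chains: list[list[tuple]],
    label: str = "test",
    prefix: str = "g",
) -> AnnotationSet:
    """One gene with one transcript per chain; chain items are
    (seqid, start, end, strand) tuples."""
    genes = []
    for i, chain in enumerate(chains, start=1):
        gene_id = f"{prefix}{i}"
        tx = TranscriptModel(
            transcript_id=f"{gene_id}.t1",
            gene_id=gene_id,
            cds_chain=[ExonInterval(*c) for c in chain],
        )
        genes.append(GeneModel(gene_id=gene_id, transcripts=[tx]))
    return AnnotationSet(genes=genes, source_label=label)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_cds_counts(
    ref: set[ExonInterval], pred: set[ExonInterval]
) -> dict[str, int]:
    """All-pairs comparison oracle for the CDS classification counts."""

    def overlaps(a: ExonInterval, b: ExonInterval) -> bool:
        return (
            a.seqid == b.seqid
            and a.strand == b.strand
            and a.start <= b.end
            and b.start <= a.end
        )

    tp = sum(1 for p in pred if p in ref)
    ope = sum(
        1 for p in pred if p not in ref and any(overlaps(p, r) for r in ref)
    )
    we = len(pred) - tp - ope
    fn = sum(1 for r in ref if r not in pred)
    me = sum(
        1
        for r in ref
        if r not in pred and not any(overlaps(r, p) for p in pred)
    )
    return {"tp": tp, "fp": ope + we, "fn": fn, "ope": ope, "we": we, "me": me}


def brute_force_n50_l50(lengths: list[int]) -> tuple[int, int]:
    """Sort-descending cumulative-sum oracle."""
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    running = 0
    for i, length in enumerate(ordered):
        running += length
        if 2 * running >= total:
            return length, i + 1
    raise AssertionError


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    seqids: tuple[str, ...] = ("c1", "c2"),
    coord_max: int = 2000,
    max_len: int = 120,
) -> set[ExonInterval]:
    out = set()
    for _ in range(n):
        seqid = seqids[rng.integers(len(seqids))]
        start = int(rng.integers(1, coord_max))
        length = int(rng.integers(1, max_len))
        strand = "+" if rng.random() < 0.5 else "-"
        out.add(ExonInterval(seqid, start, start + length, strand))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240619)
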