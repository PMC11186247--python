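"""Synthetic genomes, reference annotations and perturbed predictions with
exact machine-readable ground truth.

The generator emulates multi-exon plant-like gene models: non-overlapping
genes on both strands of a random nucleotide sequence with a configurable
GC target (default 37%, typical of crop genomes), uniformly sampled exon
counts, exon lengths and intron lengths, and a minimum intergenic gap.
CDS regions are *not* given valid start/stop framing — evaluation here is
coordinate-based, not translation-based.

The perturber then constructs a "prediction" whose evaluation is known in
closed form. Each unique reference CDS interval is independently kept
(copied exactly), boundary-shifted (one boundary moved by 1..max_shift,
still overlapping the original, never colliding with any other reference
interval), or dropped; additionally a chosen number of wrong exons is
placed in intergenic space at >= guard_distance from every reference exon.
By construction:

    evaluate_cds(ref, pred) == TP=kept, OPE=shifted, WE=wrong,
                               FN=shifted+dropped, ME=dropped

so the evaluator can be checked for *exact* (integer-count) recovery of
the planned truth, and gene-level TP equals the number of genes whose
exons were all kept (single-isoform case).

Everything is driven by one numpy Generator per call: identical seeds give
byte-identical FASTA/GFF3 output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import (
    AnnotationSet,
    ExonInterval,
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    unique_cds_intervals,
)
from .evaluation import CdsEvalResult

__all__ = [
    "GeneratorConfig",
    "PerturbationConfig",
    "TruthCounts",
    "generate_reference",
    "perturb_annotation",
    "expected_metrics",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic genome + reference annotation.

    Length ranges are inclusive (min, max) tuples sampled uniformly.
    Defaults sketch a compact plant-like gene space: ~5 exons per gene,
    exons of 60-300 bp, introns of 100-400 bp, GC 37%.
    """

    seed: int = 0
    n_seqids: int = 1
    seq_length: int = 500_000
    gc_target: float = 0.37
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (1, 9)
    exon_length: tuple[int, int] = (60, 300)
    intron_length: tuple[int, int] = (100, 400)
    intergenic_gap: int = 500
    strand_prob: float = 0.5
    isoform_prob: float = 0.0  # chance of adding a shared-exon second isoform

    def __post_init__(self) -> None:
        if self.n_seqids < 1 or self.seq_length < 1:
            raise ValueError("n_seqids and seq_length must be positive")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError(f"gc_target must be in (0,1), got {self.gc_target}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("exons_per_gene", "exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name}: need 1 <= min <= max, got ({lo},{hi})")
        if self.intergenic_gap < 1:
            raise ValueError("intergenic_gap must be >= 1")
        if not 0.0 <= self.strand_prob <= 1.0:
            raise ValueError("strand_prob must be in [0,1]")
        if not 0.0 <= self.isoform_prob <= 1.0:
            raise ValueError("isoform_prob must be in [0,1]")


@dataclass(frozen=True)
class PerturbationConfig:
    """Per-exon perturbation plan: keep/shift/drop probabilities plus
    spurious (wrong) exons placed clear of every reference exon."""

    seed: int = 0
    p_keep: float = 0.8
    p_shift: float = 0.1
    p_drop: float = 0.1
    max_shift: int = 10
    n_wrong_exons: int = 0
    guard_distance: int = 25
    wrong_exon_length: tuple[int, int] = (60, 300)

    def __post_init__(self) -> None:
        probs = (self.p_keep, self.p_shift, self.p_drop)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("p_keep/p_shift/p_drop must be in [0,1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(
                f"p_keep+p_shift+p_drop must sum to 1, got {sum(probs)}"
            )
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")
        if self.guard_distance <= self.max_shift:
            raise ValueError("guard_distance must exceed max_shift")
        if self.n_wrong_exons < 0:
            raise ValueError("n_wrong_exons must be >= 0")
        lo, hi = self.wrong_exon_length
        if lo < 1 or hi < lo:
            raise ValueError("wrong_exon_length: need 1 <= min <= max")


@dataclass(frozen=True)
class TruthCounts:
    """The generator's planned per-category exon counts."""

    kept: int
    shifted: int
    dropped: int
    wrong: int
    genes_intact: int

    def as_dict(self) -> dict[str, int]:
        return {
            "kept": self.kept,
            "shifted": self.shifted,
            "dropped": self.dropped,
            "wrong": self.wrong,
            "genes_intact": self.genes_intact,
        }


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def generate_reference(
    cfg: GeneratorConfig,
) -> tuple[list[GenomeSequence], AnnotationSet]:
    """Generate a synthetic genome and its reference annotation.

    Deterministic given ``cfg.seed``. Genes never overlap and are separated
    by at least ``cfg.intergenic_gap``; raises if the requested genes cannot
    fit, stating the minimum sequence length required.
    """
    rng = np.random.default_rng(cfg.seed)
    # split genes as evenly as possible across seqids
    base, extra = divmod(cfg.n_genes, cfg.n_seqids)
    genes_per_seqid = [base + (1 if i < extra else 0) for i in range(cfg.n_seqids)]

    genes: list[GeneModel] = []
    seqs: list[GenomeSequence] = []
    gene_no = 0
    for s, n_here in enumerate(genes_per_seqid, start=1):
        seqid = f"chr{s}"
        # sample all gene structures first so the fit check is exact
        structures = []
        for _ in range(n_here):
            k = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            exon_lens = rng.integers(
                cfg.exon_length[0], cfg.exon_length[1] + 1, size=k
            )
            intron_lens = rng.integers(
                cfg.intron_length[0], cfg.intron_length[1] + 1, size=max(k - 1, 0)
            )
            structures.append((exon_lens, intron_lens))
        spans = [int(e.sum() + i.sum()) for e, i in structures]
        required = sum(spans) + (n_here + 1) * cfg.intergenic_gap
        if required > cfg.seq_length:
            raise ValueError(
                f"{seqid}: {n_here} genes need at least {required} bp "
                f"(seq_length={cfg.seq_length}); increase seq_length or "
                f"reduce n_genes"
            )
        # distribute the leftover space randomly over the n_here+1 gaps
        leftover = cfg.seq_length - required
        if n_here > 0:
            extra_gaps = rng.multinomial(leftover, np.full(n_here + 1, 1 / (n_here + 1)))
        else:
            extra_gaps = np.array([leftover])
        pos = 1
        for g, (exon_lens, intron_lens) in enumerate(structures):
            pos += cfg.intergenic_gap + int(extra_gaps[g])
            strand = "+" if rng.random() < cfg.strand_prob else "-"
            gene_no += 1
            gene_id = f"g{gene_no:05d}"
            chain = []
            cursor = pos
            for e_idx, elen in enumerate(exon_lens):
                chain.append(
                    ExonInterval(seqid, cursor, cursor + int(elen) - 1, strand)
                )
                cursor += int(elen)
                if e_idx < len(intron_lens):
                    cursor += int(intron_lens[e_idx])
            pos = cursor
            transcripts = [
                TranscriptModel(f"{gene_id}.t1", gene_id, chain)
            ]
            if len(chain) >= 2 and rng.random() < cfg.isoform_prob:
                # exon-skipping isoform sharing all but one internal/terminal exon
                skip = int(rng.integers(0, len(chain)))
                alt = [iv for i, iv in enumerate(chain) if i != skip]
                transcripts.append(TranscriptModel(f"{gene_id}.t2", gene_id, alt))
            genes.append(GeneModel(gene_id, transcripts))
        seqs.append(
            GenomeSequence(seqid, _random_genome(rng, cfg.seq_length, cfg.gc_target))
        )
    return seqs, AnnotationSet(genes=genes, source_label="reference")


def _candidate_shifts(
    iv: ExonInterval, rng: np.random.Generator, max_shift: int
) -> list[ExonInterval]:
    """All single-boundary shifts by 1..max_shift that keep overlap with the
    source, in a seed-determined random preference order."""
    candidates = []
    for delta in range(1, max_shift + 1):
        for new_start in (iv.start - delta, iv.start + delta):
            if new_start >= 1 and new_start <= iv.end:
                candidates.append(ExonInterval(iv.seqid, new_start, iv.end, iv.strand))
        for new_end in (iv.end - delta, iv.end + delta):
            if new_end >= iv.start:
                candidates.append(ExonInterval(iv.seqid, iv.start, new_end, iv.strand))
    rng.shuffle(candidates)
    return candidates


def perturb_annotation(
    ref: AnnotationSet,
    cfg: PerturbationConfig,
    seq_lengths: dict[str, int] | None = None,
) -> tuple[AnnotationSet, TruthCounts]:
    """Perturb a reference annotation into a prediction with known truth.

    Each unique reference CDS interval is kept, shifted or dropped with the
    configured probabilities. Shifted intervals always still overlap their
    source, never coincide with or overlap any other reference interval,
    and never collide with another prediction; if no such shift exists for
    an interval (it can happen only in pathologically dense references) the
    interval is kept instead, so the returned :class:`TruthCounts` remain
    exact. Wrong exons are placed at >= ``guard_distance`` from every
    reference interval (any strand) and never overlap each other.

    ``seq_lengths`` bounds wrong-exon placement per seqid; if omitted, the
    maximum reference coordinate per seqid is used.
    """
    rng = np.random.default_rng(cfg.seed)
    uniq = sorted(unique_cds_intervals(ref))

    actions: dict[ExonInterval, str] = {}
    replacements: dict[ExonInterval, ExonInterval] = {}

    by_seqid: dict[str, list[ExonInterval]] = {}
    for iv in uniq:
        by_seqid.setdefault(iv.seqid, []).append(iv)

    def _overlap(a: ExonInterval, b: ExonInterval) -> bool:
        return a.start <= b.end and b.start <= a.end

    choices = rng.choice(3, size=len(uniq), p=[cfg.p_keep, cfg.p_shift, cfg.p_drop])
    choice_of = dict(zip(uniq, choices))
    kept = shifted = dropped = 0
    # Reference intervals within a seqid are disjoint (generator guarantee)
    # and shifts are local (<= max_shift), so the only possible clashes of a
    # shift candidate are with the sorted prev/next reference interval and
    # with the prediction already emitted for prev — an O(1) check.
    for intervals in by_seqid.values():
        prev_pred: ExonInterval | None = None
        for i, iv in enumerate(intervals):
            choice = choice_of[iv]
            if choice == 0:
                actions[iv] = "keep"
                prev_pred = iv
                kept += 1
                continue
            if choice == 2:
                actions[iv] = "drop"
                dropped += 1
                continue
            prev_ref = intervals[i - 1] if i > 0 else None
            next_ref = intervals[i + 1] if i + 1 < len(intervals) else None
            new_iv = None
            for cand in _candidate_shifts(iv, rng, cfg.max_shift):
                if prev_ref is not None and (
                    cand == prev_ref or _overlap(cand, prev_ref)
                ):
                    continue
                if next_ref is not None and (
                    cand == next_ref or _overlap(cand, next_ref)
                ):
                    continue
                if prev_pred is not None and (
                    cand == prev_pred or _overlap(cand, prev_pred)
                ):
                    continue
                new_iv = cand
                break
            if new_iv is None:  # no safe shift exists: keep instead
                actions[iv] = "keep"
                prev_pred = iv
                kept += 1
            else:
                actions[iv] = "shift"
                replacements[iv] = new_iv
                prev_pred = new_iv
                shifted += 1

    # rebuild gene/transcript structure from surviving intervals
    genes: list[GeneModel] = []
    genes_intact = 0
    for gene in ref.genes:
        gene_uniq = {iv for t in gene.transcripts for iv in t.cds_chain}
        if all(actions[iv] == "keep" for iv in gene_uniq):
            genes_intact += 1
        new_txs = []
        for tx in gene.transcripts:
            chain = []
            for iv in tx.cds_chain:
                act = actions[iv]
                if act == "keep":
                    chain.append(iv)
                elif act == "shift":
                    chain.append(replacements[iv])
            if chain:
                new_txs.append(
                    TranscriptModel(f"{tx.transcript_id}.pred", tx.gene_id, chain)
                )
        if new_txs:
            genes.append(GeneModel(f"{gene.gene_id}.pred", new_txs))

    # wrong exons: intergenic placement, >= guard_distance from every ref exon
    wrong_intervals = _place_wrong_exons(rng, cfg, uniq, seq_lengths)
    for w, iv in enumerate(wrong_intervals, start=1):
        gid = f"wrong_g{w:05d}"
        genes.append(
            GeneModel(gid, [TranscriptModel(f"{gid}.t1", gid, [iv])])
        )

    pred = AnnotationSet(genes=genes, source_label="predicted")
    truth = TruthCounts(
        kept=kept,
        shifted=shifted,
        dropped=dropped,
        wrong=len(wrong_intervals),
        genes_intact=genes_intact,
    )
    return pred, truth


def _place_wrong_exons(
    rng: np.random.Generator,
    cfg: PerturbationConfig,
    ref_intervals: list[ExonInterval],
    seq_lengths: dict[str, int] | None,
) -> list[ExonInterval]:
    if cfg.n_wrong_exons == 0:
        return []
    if not ref_intervals and not seq_lengths:
        raise ValueError(
            "cannot place wrong exons: no reference intervals and no seq_lengths"
        )
    # free gaps per seqid: complement of ref intervals padded by guard_distance
    seqids = sorted(
        set(iv.seqid for iv in ref_intervals)
        | (set(seq_lengths) if seq_lengths else set())
    )
    gaps: list[tuple[str, int, int]] = []  # (seqid, lo, hi) placeable start..end
    for seqid in seqids:
        blocked = sorted(
            (
                max(1, iv.start - cfg.guard_distance),
                iv.end + cfg.guard_distance,
            )
            for iv in ref_intervals
            if iv.seqid == seqid
        )
        limit = (
            seq_lengths[seqid]
            if seq_lengths and seqid in seq_lengths
            else (max((iv.end for iv in ref_intervals if iv.seqid == seqid), default=0)
                  + cfg.guard_distance + cfg.wrong_exon_length[1] + 1)
        )
        pos = 1
        for lo, hi in blocked:
            if lo - 1 >= pos:
                gaps.append((seqid, pos, min(lo - 1, limit)))
            pos = max(pos, hi + 1)
        if pos <= limit:
            gaps.append((seqid, pos, limit))

    placed: list[ExonInterval] = []
    open_gaps = [g for g in gaps if g[2] >= g[1]]
    for _ in range(cfg.n_wrong_exons):
        length = int(
            rng.integers(cfg.wrong_exon_length[0], cfg.wrong_exon_length[1] + 1)
        )
        fitting = [i for i, (_, lo, hi) in enumerate(open_gaps) if hi - lo + 1 >= length]
        if not fitting:
            raise ValueError(
                f"insufficient intergenic space for {cfg.n_wrong_exons} wrong "
                f"exons (placed {len(placed)})"
            )
        # weight gaps by available room so placement stays well spread
        rooms = np.array([open_gaps[i][2] - open_gaps[i][1] + 2 - length for i in fitting], float)
        gi = fitting[int(rng.choice(len(fitting), p=rooms / rooms.sum()))]
        seqid, lo, hi = open_gaps.pop(gi)
        start = int(rng.integers(lo, hi - length + 2))
        strand = "+" if rng.random() < 0.5 else "-"
        placed.append(ExonInterval(seqid, start, start + length - 1, strand))
        # split the gap around the new exon (1 bp spacing avoids duplicates)
        if start - 2 >= lo:
            open_gaps.append((seqid, lo, start - 2))
        if start + length + 1 <= hi:
            open_gaps.append((seqid, start + length + 1, hi))
        open_gaps.sort()
    return placed


def expected_metrics(t: TruthCounts) -> CdsEvalResult:
    """Closed-form evaluation result implied by the planned truth counts:
    TP=kept, OPE=shifted, WE=wrong, FN=shifted+dropped, ME=dropped."""
    return CdsEvalResult(
        tp=t.kept,
        fp=t.shifted + t.wrong,
        fn=t.shifted + t.dropped,
        ope=t.shifted,
        we=t.wrong,
        me=t.dropped,
    )
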