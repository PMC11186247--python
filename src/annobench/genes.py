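"""Gene-level exact-structure evaluation.

A predicted gene counts as a true positive only when the boundaries of all
its coding regions correspond exactly to a reference gene's — operationally,
when at least one of its transcript chain signatures equals at least one
reference transcript chain signature (the any-isoform rule, analogous to
"complete exact intron-chain match" practice). One shifted boundary in a
single CDS makes the whole gene a false positive. Genes are matched by
chain signature only, never by identifier or locus overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import AnnotationSet, TranscriptModel

__all__ = ["GeneEvalResult", "chain_key", "evaluate_genes"]

ChainKey = tuple[str, str, tuple[tuple[int, int], ...]]


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


@dataclass(frozen=True)
class GeneEvalResult:
    """Gene-level counts and Sn/Sp/F1."""

    tp: int
    fp: int
    fn: int
    n_ref_genes: int
    n_pred_genes: int
    matched_ref_genes: int

    @property
    def sn(self) -> float | None:
        return _safe_div(self.matched_ref_genes, self.n_ref_genes)

    @property
    def sp(self) -> float | None:
        return _safe_div(self.tp, self.n_pred_genes)

    @property
    def f1(self) -> float | None:
        sn, sp = self.sn, self.sp
        if sn is None or sp is None or sn + sp == 0:
            return None
        return 2 * sn * sp / (sn + sp)

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "sn": self.sn,
            "sp": self.sp,
            "f1": self.f1,
        }


def chain_key(t: TranscriptModel) -> ChainKey:
    """Canonical chain signature: (seqid, strand, ((start, end), ...)).

    Two transcripts have equal signatures iff every CDS boundary and the
    strand are identical.
    """
    if not t.cds_chain:
        raise ValueError(f"transcript {t.transcript_id} has an empty CDS chain")
    return (t.seqid, t.strand, tuple((iv.start, iv.end) for iv in t.cds_chain))


def evaluate_genes(
    ref: AnnotationSet,
    pred: AnnotationSet,
    require_all_isoforms: bool = False,
) -> GeneEvalResult:
    """Evaluate gene structures by exact chain-signature matching.

    With ``require_all_isoforms=False`` (default) a gene is credited when
    any of its isoform chains matches any reference isoform chain; with
    ``True`` every isoform chain of the gene must exist in the reference
    (and vice versa for reference recovery).
    """
    ref_keys = {chain_key(t) for t in ref.transcripts()}
    pred_keys = {chain_key(t) for t in pred.transcripts()}

    def _gene_matches(gene, other_keys) -> bool:
        keys = [chain_key(t) for t in gene.transcripts]
        if require_all_isoforms:
            return all(k in other_keys for k in keys)
        return any(k in other_keys for k in keys)

    tp = sum(1 for g in pred.genes if _gene_matches(g, ref_keys))
    fp = pred.n_genes - tp
    matched_ref = sum(1 for g in ref.genes if _gene_matches(g, pred_keys))
    fn = ref.n_genes - matched_ref
    return GeneEvalResult(
        tp=tp,
        fp=fp,
        fn=fn,
        n_ref_genes=ref.n_genes,
        n_pred_genes=pred.n_genes,
        matched_ref_genes=matched_ref,
    )
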