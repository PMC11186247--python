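"""Combine two predicted annotations into merged (union) or common
(intersection) sets.

"Merged" keeps every distinct transcript chain from either predictor
(identical chains deduplicated); it can only add true positives, so its
CDS-level sensitivity is at least that of either input. "Common" keeps only
chains predicted identically by both tools, trading sensitivity for
specificity. Identity is exact chain-signature equality — the same
exact-boundary criterion used by the evaluators — not mere locus overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import AnnotationSet, GeneModel, TranscriptModel
from .genes import ChainKey, chain_key

__all__ = ["CombinationResult", "merge_annotations", "intersect_annotations"]


@dataclass
class CombinationResult:
    combined: AnnotationSet
    mode: str  # "union" | "intersection"
    provenance: dict[str, str] = field(default_factory=dict)  # gene_id -> source(s)


def _chain_map(ann: AnnotationSet) -> dict[ChainKey, TranscriptModel]:
    """First transcript per distinct signature, in encounter order."""
    out: dict[ChainKey, TranscriptModel] = {}
    for tx in ann.transcripts():
        key = chain_key(tx)
        if key not in out:
            out[key] = tx
    return out


def _build(
    chains: list[tuple[ChainKey, TranscriptModel, str]],
    mode: str,
    label: str,
) -> CombinationResult:
    # one gene per distinct chain; ids regenerated (source-prefixed ordinal)
    genes: list[GeneModel] = []
    provenance: dict[str, str] = {}
    for i, (key, tx, source) in enumerate(chains, start=1):
        gene_id = f"{mode}_g{i:06d}"
        new_tx = TranscriptModel(
            transcript_id=f"{gene_id}.t1",
            gene_id=gene_id,
            cds_chain=list(tx.cds_chain),
        )
        genes.append(GeneModel(gene_id=gene_id, transcripts=[new_tx]))
        provenance[gene_id] = source
    combined = AnnotationSet(genes=genes, source_label=label)
    return CombinationResult(combined=combined, mode=mode, provenance=provenance)


def merge_annotations(a: AnnotationSet, b: AnnotationSet) -> CombinationResult:
    """Union of transcript chain signatures from both predictors."""
    a_map, b_map = _chain_map(a), _chain_map(b)
    chains: list[tuple[ChainKey, TranscriptModel, str]] = []
    for key, tx in a_map.items():
        source = "both" if key in b_map else a.source_label
        chains.append((key, tx, source))
    for key, tx in b_map.items():
        if key not in a_map:
            chains.append((key, tx, b.source_label))
    label = f"union({a.source_label},{b.source_label})"
    return _build(chains, "union", label)


def intersect_annotations(a: AnnotationSet, b: AnnotationSet) -> CombinationResult:
    """Chains predicted identically (same CDS coordinates) by both tools."""
    a_map, b_map = _chain_map(a), _chain_map(b)
    chains = [(key, tx, "both") for key, tx in a_map.items() if key in b_map]
    label = f"intersection({a.source_label},{b.source_label})"
    return _build(chains, "intersection", label)
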