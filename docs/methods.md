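# Methods

## Exact-boundary evaluation

All coordinates are GFF3-native (1-based, inclusive) end to end; no
half-open conversion exists anywhere in the package. Exact matching is a
set-membership test on `(seqid, start, end, strand)`, so the usual
off-by-one failure mode of annotation comparison cannot occur between
modules — only between input dialects (see stop codons below).

**CDS level.** Evaluation operates on the *deduplicated* set of CDS
intervals of each annotation: an exon shared by several isoforms counts
once. The alternative — counting per isoform — would scale TP and FP with
isoform multiplicity and make specificity a function of how many isoforms a
tool emits rather than of boundary quality. Predicted intervals partition
into TP (exact match), OPE (no exact match but ≥1 bp overlap with a
same-seqid, same-strand reference interval) and WE (no overlap); reference
intervals into TP, FN, with the subset of FN overlapped by no prediction
flagged ME. This yields the identities `FP = OPE + WE` and, whenever
FP > 0, `OScore + WScore = 1`, which the test suite asserts on randomized
inputs. Overlap detection uses an interval tree per (seqid, strand); the
tests verify equivalence with an all-pairs brute-force oracle.

Two policies are explicit choices rather than inherited conventions:

- *Strand:* overlap requires the same strand. An antisense prediction over
  a coding region does not capture that coding region, so it is WE, not
  OPE.
- *Overlap threshold:* ≥1 shared bp by default; `min_overlap` is exposed
  for sensitivity analyses but is not part of the headline metrics.

**Ratios with zero denominators** (e.g. specificity with zero predictions,
OScore with zero false positives) are reported as `None`/`NA`, never 0, and
are dropped pairwise from downstream statistics. Imputing 0 would silently
turn "no evidence" into "worst possible score".

**Gene level.** A transcript's chain signature is
`(seqid, strand, ((start₁,end₁), …))`. A predicted gene is TP when any of
its isoform signatures equals any reference isoform signature (any-isoform
rule, the analogue of exact intron-chain matching); a flag switches to
requiring every isoform. Genes are matched by signature only — identifiers
and locus overlap play no role — so renamed or re-numbered annotations
compare cleanly.

**Stop codons.** GFF3 dialects disagree on whether the stop codon lies
inside the terminal CDS. `normalize_stop_codons` shifts the 3'-terminal
boundary of every chain by ±3 bp (`include`/`exclude`; default `as-is`).
Comparing annotations of mismatched dialects without harmonizing makes
every terminal exon fail exact matching and depresses Sn/Sp by roughly the
fraction of terminal exons; the CLI applies one mode to all inputs.

## Annotation combination

*Merged* is the union of distinct chain signatures of two predictions;
*common* is their intersection. "Same prediction" means identical CDS
coordinates — the same exactness criterion as the evaluator — not locus
overlap; a looser locus-overlap mode is deliberately out of scope, since a
union of inexact variants would blur the metric being studied. Union can
only add true positives, hence `Sn(union) ≥ max(Sn_a, Sn_b)` and
`Sn(common) ≤ min(Sn_a, Sn_b)`; both inequalities are asserted over random
synthetic pairs. Gene identifiers in combined output are regenerated to
avoid collisions; provenance (which source contributed each chain) is kept
alongside.

## Assembly statistics

N50 is the length of the shortest contig in the smallest set of longest
contigs whose cumulative length is ≥ half the assembly; L50 is that set's
size; ties at exactly half count (≥, not >). GC% defaults to
`100·(G+C)/(A+C+G+T)` — Ns and ambiguity codes excluded from numerator and
denominator — because draft plant assemblies can carry long N gaps that
would otherwise dilute GC; `gc_over_total_length=True` reproduces the
total-length convention some tools use.

## Statistics

Feature–accuracy association uses Spearman rank correlation by default
(monotone, outlier-robust; assembly sizes span orders of magnitude), with
Pearson available. Combinations with fewer than 3 complete pairs are
reported as not-computable rather than raised, since sparse per-order
tables are the norm. Tool comparison runs Shapiro-Wilk per group (a
normality screen; annotation metrics are generally non-normal), a
Kruskal-Wallis omnibus per metric, then all pairwise two-sided Mann-Whitney
U tests: exact enumeration when both groups have ≤8 observations, normal
approximation with tie correction above that. Raw p-values are always
reported; Benjamini-Hochberg adjustment is opt-in and flagged in the
report, so the reader always knows which is shown. Groups with fewer than
3 usable observations are excluded with a warning and listed — small
taxonomic orders are summarized descriptively, not tested.

## Proteogenomics

Six-frame translation: frames +1..+3 are codon offsets 0..2 on the forward
strand, −1..−3 offsets 0..2 on the reverse complement; standard genetic
code; segments split at stop codons; default minimum segment length 7
residues (below typical search-engine peptide minima). Codons containing
any ambiguity code translate to X uniformly — deliberately stricter than
resolving reducible ambiguities (e.g. GCN→A) so that segment content never
depends on which ambiguity code appears. Segments containing X are kept by
default (one ambiguous base should not erase a segment); a flag drops them.
Decoys are per-entry sequence reversal (length and composition preserved),
tagged with a configurable prefix. Peptide comparison is exact string
equality by default; an I/L-equivalence flag folds isoleucine onto leucine,
since mass spectrometry cannot distinguish them. PSM scoring and FDR
filtering are upstream of this package: overlap reports consume
already-filtered peptide lists.

## Synthetic data: what it emulates and what it does not

The generator produces plant-like gene structure *geometry*: 1–9 exons per
gene (uniform), exons 60–300 bp, introns 100–400 bp, intergenic gaps ≥500
bp, GC target 37% (typical of the crop genomes this kind of benchmark is
run on), genes on both strands, never overlapping. Nucleotides are sampled
i.i.d. per base; CDS regions carry no start/stop codons, no splice-site
dinucleotides, and no codon structure, and the genome has no repeats. This
is sufficient — and exactly sufficient — for testing coordinate-based
evaluation, combination, assembly statistics and translation bookkeeping.
Passing tests therefore demonstrate correctness of the *measurement*
machinery, not anything about how real predictors behave on real genomes;
the synthetic "predictors" are error processes, not gene finders.

The perturber plans truth by construction. Per unique reference interval:
keep, shift one boundary by δ ∈ [1, max_shift] (default 10 bp), or drop;
plus `n_wrong_exons` spurious exons placed ≥ guard_distance (default 25 bp,
required > max_shift) from every reference exon. Shift candidates are
rejected if they coincide with any reference interval, overlap any
reference interval other than their source, or collide with the prediction
already emitted for the neighbouring interval; because generated reference
intervals are disjoint and shifts are local, checking the sorted
neighbours suffices (O(1) per candidate). In the measure-zero case where no
legal shift exists, the interval is kept and counted as kept, so the truth
counts remain exact rather than approximate. These guarantees give the
closed-form expectation `TP=kept, OPE=shifted, WE=wrong, FN=shifted+dropped,
ME=dropped`, which the acceptance suite verifies exactly over 50 seeded
configurations of ~1000 genes (~5000 unique exons) each — sized to keep the
full check under a couple of minutes on one core while still being two
orders of magnitude above the hand-checkable examples.

Single-isoform genes are the default; `isoform_prob` adds exon-skipping
second isoforms to exercise interval deduplication and the any-isoform gene
rule (with isoforms present, gene-level TP may legitimately exceed the
intact-gene count: dropping a skipped exon can turn one isoform's chain
into the other's).

## Degenerate inputs and numerical notes

- Empty annotations are valid everywhere; every ratio involving them is
  `None`, not 0 (self-comparison of an empty set yields all-`None`).
- Seqids present in only one annotation are still evaluated (predictions
  there are WE, references there are ME) — silently intersecting seqid
  universes would hide scaffold-naming mismatches.
- Metric equality in tests is exact on counts and `pytest.approx` on
  ratios; the union/intersection monotonicity assertions allow 1e-12 for
  float division.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical FASTA and
  GFF3 output.

## Known limitations

- GTF and attribute-rich GFF3 are out of scope; only ID/Parent structure is
  read, and only CDS features (configurable feature-type set) are
  evaluated. UTRs and non-coding exon parts are ignored.
- The "common" combination has no locus-overlap mode.
- The synthetic generator does not model repeat content, pseudogenes,
  overlapping genes, trans-splicing, or assembly errors; correlations
  measured on panels of synthetic genomes reflect the error process built
  into the panel, not genome biology.
- Six-frame translation emits unframed segments, not ORFs; it is a search
  space, not a gene caller.
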