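# annobench

Exact-boundary benchmarking of structural genome annotations, built for the
situation plant genomics keeps running into: a genome assembly exists, one
or more automated gene predictors (e.g. BRAKER2, Helixer) have been run on
it, and the question is how good their gene models are — against a trusted
reference annotation, against each other, and as a protein search space for
mass-spectrometry proteomics.

The package is aimed at genome-annotation and proteogenomics practitioners.
It takes GFF3 annotations and FASTA assemblies, and provides:

- **CDS-level evaluation** by exact coordinate matching. A predicted coding
  segment is a true positive (TP) only if its `(seqid, start, end, strand)`
  is identical to a reference CDS; anything else is a false positive (FP).
  Besides the standard

  ```
  Sn = TP / (TP + FN)      Sp = TP / (TP + FP)      F1 = 2·Sn·Sp / (Sn + Sp)
  ```

  the false calls are decomposed: an FP that still overlaps a reference
  exon (same seqid and strand, ≥1 bp) is an *overlapping predicted exon*
  (OPE), one that overlaps nothing is a *wrong exon* (WE), and a reference
  exon overlapped by no prediction at all is a *missed exon* (ME):

  ```
  OScore = OPE / FP        WScore = WE / FP         MScore = ME / (TP + FN)
  ```

  OScore/WScore separate "found the region, missed the boundary" from
  "hallucinated an exon"; MScore counts coding regions a tool never saw.
- **Gene-level evaluation**: a predicted gene is correct only when the
  boundaries of *all* its coding regions match a reference isoform exactly
  (exact chain match; one shifted boundary fails the whole gene).
- **Annotation combination**: the *merged* (union of exact transcript
  chains; sensitivity can only rise) and *common* (intersection;
  specificity rises at the cost of unique correct calls) strategies for two
  predictors.
- **Assembly statistics**: size, contig count, N50/L50, GC%.
- **Feature–accuracy statistics**: Spearman/Pearson correlation of genome
  features with accuracy, and Shapiro-Wilk → Kruskal-Wallis → pairwise
  Mann-Whitney comparison of tools.
- **Proteogenomics**: six-frame translation search spaces, reversed-sequence
  decoys, and Venn/overlap reports between peptide lists identified against
  different protein databases.
- **Synthetic ground truth**: a generator of plant-like multi-exon gene
  models on a random genome plus a perturber that plans exactly which exons
  are kept, boundary-shifted, dropped, or spurious — so every evaluator
  output can be checked against closed-form expected counts.

## Worked example

Simulate a 200 kb genome with 30 genes, perturb the reference into a
"prediction" (80% of exons kept, 10% boundary-shifted, 10% dropped, 8
spurious exons), then evaluate:

```bash
annobench simulate --seed 11 --n-genes 30 --seq-length 200000 --n-wrong 8 --outdir sim
annobench evaluate sim/reference.gff3 sim/predicted.gff3 --out eval.tsv
column -t eval.tsv
```

```
source     cds_tp  cds_fp  cds_fn  cds_ope  cds_we  cds_me  cds_sn    cds_sp    cds_f1    cds_oscore  cds_wscore  cds_mscore  gene_tp  gene_fp  gene_fn  gene_sn   gene_sp   gene_f1
predicted  114     22      31      14       8       17      0.786207  0.838235  0.811388  0.636364    0.363636    0.117241    11       27       19       0.366667  0.289474  0.323529
```

Reading the row: of 145 unique reference exons, 114 were reproduced with
exact boundaries (Sn = 0.786). Of the 136 predicted exons, 22 were wrong
(Sp = 0.838), and those errors are mostly near-misses — 64% overlap a real
exon (OScore) versus 36% hallucinated (WScore). About 12% of reference
exons were never touched by any prediction (MScore). At the gene level only
11 of 30 genes had *every* exon boundary correct, so gene sensitivity drops
to 0.37 — exact gene structures are much harder than individual exons. The
numbers agree exactly with the planned perturbation in `sim/truth.json`
(`kept=114, shifted=14, dropped=17, wrong=8, genes_intact=11`).

The same works on real data: pass your reference GFF3, one or more
predictor GFF3s, and optionally `--stop-codon include|exclude` to harmonize
annotations whose dialects disagree about whether the stop codon is inside
the terminal CDS (if you skip this for mismatched dialects, every terminal
exon fails exact matching).

Other subcommands: `annobench combine` (merged/common annotation),
`annobench stats` (N50/L50/GC), `annobench sixframe` (translation database,
optionally with decoys), `annobench peptide-overlap`, `annobench correlate`
and `annobench compare`. All are deterministic given their inputs and seed,
and every report embeds the version, parameters and input checksums.

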