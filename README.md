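# bcrnet

Isotype-resolved B-cell receptor (BCR) repertoire analysis: from barcoded
paired-end amplicon reads to error-corrected unique BCRs, clonal networks,
and class-switch statistics — together with a ground-truthed repertoire
simulator that makes every stage of the pipeline testable.

## Who this is for

Immunogenomics analysts working with isotype-resolved IGH amplicon
sequencing — libraries in which each RNA molecule is tagged with a
15-nt molecular barcode (pattern `NNNNTNNNNTNNNNT`) before amplification
and the constant-region primer preserves the isotype identity (IgM, IgD,
IgG1–4, IgA1–2, IgE) of every read. Typical questions: how are somatic
hypermutation (SHM), class-switch recombination (CSR) and clonal
expansion coupled; how does a malignant (e.g. CLL) clone differ from the
healthy repertoire; which V genes favour which isotype fates.

## What it computes

* **Barcode consensus error correction** — read pairs are quality
  filtered (median Phred > 34), merged on an identical > 50 bp overlap,
  oriented V→constant, isotype-called by 10-mer matching against the
  first 50 bp of each constant gene, and collapsed per barcode by
  majority vote; groups are kept only above 80% mean per-position
  consensus support. The pre-correction error rate is estimated from
  mismatches within barcode groups.
* **Clonal networks** — vertices are unique V(D)J sequences (vertex
  size = read support), edges join sequences differing by exactly one
  nucleotide (no indels), clones are connected components.
* **Unique-BCR statistics** — isotype frequencies, CDR3 lengths and
  silent / non-silent SHM medians are computed over *unique* sequences,
  cancelling per-cell RNA differences (plasmablasts carry ~1000× the
  BCR RNA of naive cells).
* **CLL partitioning** — the leukemic repertoire is the largest cluster
  plus all BCRs sharing its CDR3s; BCRs sharing only the V–J
  combination are quarantined from both repertoires.
* **Class-switch statistics** — pairwise isotype overlap coefficients
  from 20 subsamples of 8,000 reads; conditional probabilities
  `P(Switched | V gene)`, `P(Switched | V gene, mutated/unmutated)` and
  `P(Isotype Y | V gene, switched)` over unique BCRs with a > 100-read
  gene filter; isotype-specific IGHV usage profiles with Spearman
  correlations, chi-squared non-randomness tests against unmutated
  IgD/M, Wilcoxon cohort comparisons and one-/two-way ANOVA of switch
  probability on gene × mutational status.
* **Simulation** — multi-clone repertoires with geometric/Zipf clone
  sizes, per-generation SHM, a downstream-only (deletional) CSR
  transition matrix over the locus order IGHM/IGHD → IGHG3 → IGHG1 →
  IGHA1 → IGHG2 → IGHG4 → IGHE → IGHA2, cell-type RNA abundance skew,
  barcode tagging, PCR duplication, per-base error and paired reads —
  with complete ground truth for every read.

## Worked example

Run the full pipeline (simulate → preprocess → annotate → network →
stats) on a simulated repertoire:

```bash
cat > demo.yaml <<'YAML'
seed: 7
germline: {n_v: 6, n_d: 3, n_j: 2}
simulate: {n_clones: 120, clone_size_p: 0.3, shm_rate: 0.003,
           founder_switch_probs: 0.3, plasmablast_prob: 0.02}
reads: {error_rate: 0.004, pcr_duplicates: 3.0}
stats: {overlap_depth: 2000, overlap_subsamples: 20, min_reads: 50}
YAML
bcrnet all -c demo.yaml -o demo/
```

which prints the per-stage manifest counts:

```json
{
  "cells": 431,
  "clones": 120,
  "molecules": 3347,
  "read_pairs": 13374,
  "preprocess": {
    "raw_pairs": 13374,
    "no_barcode": 174,
    "barcode_groups": 3947,
    "precorrection_error_rate": 0.003965472629382909,
    "consensus_bcrs": 3862
  },
  "annotated": 3862,
  "unique_sequences": 1291,
  "clusters": 699
}
```

Reading this: 431 simulated cells yielded 3,347 barcoded RNA molecules
and 13,374 read pairs. The mismatch rate within barcode groups, 0.397%,
recovers the injected 0.4% per-base error before correction. Barcode
groups exceed molecules because a sequencing error inside a barcode
spawns a spurious singleton group; majority-vote consensus then removes
essentially all per-read errors. The 3,862 consensus BCRs collapse to
1,291 unique V(D)J sequences in 699 single-nucleotide clusters (clones).
`demo/isotype_frequencies.tsv` contrasts the unique-BCR percentages with
the read-weighted ones — the latter inflated for the plasmablast-derived
isotypes — and `demo/overlap_matrix.tsv`, `demo/switch_probabilities.tsv`
hold the class-switch statistics.

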