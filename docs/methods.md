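# Methods

## The measurement problem

Isotype-resolved BCR sequencing reads the heavy-chain V(D)J region of
each transcript together with enough of the constant gene to identify
its class. Two systematic distortions stand between raw reads and
repertoire biology: amplification/sequencing errors inflate apparent
SHM and fragment clones, and per-cell RNA abundance (plasmablasts
express on the order of 1000× more BCR RNA than naive B cells) inflates
read-weighted frequencies. The pipeline addresses the first with
molecular-barcode consensus correction and the second by counting
unique V(D)J nucleotide sequences rather than reads.

## Preprocessing model and choices

Read pairs pass a median-Phred filter (strictly > 34 on both mates; the
median of an even-length read is the mean of the two central values)
and are merged only when an *identical* overlap strictly longer than
50 bp exists; the merged quality string takes the overlap from the
forward mate. Orientation and barcode: the amplicon layout is fixed as
`[15-nt barcode][V(D)J][first 50 nt of the constant gene]`, barcode at
the V-primer end; a merged read is accepted on whichever strand shows
the conserved T's (1-based positions 5, 10, 15) at its 5' end, forward
strand checked first. Trimming is coordinate-based (the amplicon design
is known), not fuzzy primer search.

Isotype calling scores each constant gene by the number of shared
10-mers between the read's 50-nt constant-side segment and the gene's
first 50 bp (at most 41); the call is the unique argmax, with ties and
all-zero scores ambiguous. A single central mismatch destroys 10
k-mers, so even one error leaves a decisive margin when constant-gene
prefixes differ at ≥ 5 positions — which the synthetic germline
generator guarantees.

"Sequence certainty" of a barcode group is defined here as mean
per-position consensus support: the fraction of member reads matching
the majority base, averaged over positions (for two reads this equals
pairwise identity). Groups are retained strictly above 0.8. Only reads
of the group's modal length enter the consensus (length ties resolve to
the shorter; dropped reads are counted); base ties resolve
lexicographically (A < C < G < T) for determinism. A singleton group has
certainty 1.0. The pre-correction error rate is the summed mismatch
count of member reads against their group consensus divided by the
total member bases compared, over groups with ≥ 2 reads (so two
100-nt reads with two mismatches contribute 2/200).

The frame/immunoglobulin filter retains a consensus only when its best
V and J identities reach 70% (anchored ungapped comparison over the
full germline segment) and the V-to-J reading frame is open.

## Annotation

V and J calls are anchored ungapped best matches against the packaged
germline set; ties break by fewest mismatches, then name order. This
replaces external annotation services and is adequate because the
amplicon layout has no indels; records failing the identity thresholds
are dropped and counted. Mutation counts cover the aligned V region
only (not the CDR3/junction): per codon, the observed codon — with all
its observed mutations — is translated against the germline codon, and
every mutated nucleotide in the codon is non-silent iff the amino acids
differ, else silent. Multi-hit codons therefore count all their bases
on one side; silent + non-silent = total always. CDR3 is the
translation of the region strictly between the conserved V-cysteine
codon and the conserved J-tryptophan/phenylalanine codon; a record
whose anchor has been mutated away keeps a null CDR3 but is retained.

## Clonal networks

Vertices are unique sequences (read support summed, isotypes unioned);
an edge requires equal length and Hamming distance exactly one —
"non-indel" is read as implying equal length. The implementation
(vectorized pairwise comparison for small length buckets, masked-key
join for large ones) is contractually equivalent to the brute-force
all-pairs definition, and is tested against an independent
union-find oracle. Cluster ids order components by read support, ties
by smallest vertex index. Networks are per sample.

## Statistics over unique BCRs

*Isotype frequencies.* Denominator = total isotype-presence events of
unique sequences, so a sequence seen in k isotypes contributes k events
and percentages sum to 100. (The alternative single-assignment reading
is supported by the same machinery but not the default.)

*Overlap coefficients.* Reads are subsampled without replacement
(multivariate hypergeometric over (sequence, class) read counts) to
8,000 reads, 20 times; IgD and IgM are merged into one class first
(IgM reads arise from IgD transcripts by alternative splicing).
Within a subsample, a unique sequence whose observed class set has size
exactly two increments that pair; pair counts are normalized to sum to
one per subsample and averaged. Sequences observed in three or more
classes are deliberately not counted. Samples below the depth are
computed once without subsampling, flagged. The per-pair SE across
subsamples is reported.

*CLL partition.* Malignant = largest cluster by reads ∪ identical CDR3
(amino acid) matches to it; non-malignant excludes additionally all
V–J-combination matches; sequences matching only the V–J rule are
quarantined in neither set. The three sets always partition the
repertoire exactly.

*Switch probabilities.* All counts are over unique BCRs; "switched"
means any isotype outside {IgM, IgD}, "mutated" means ≥ 1 V-region
nucleotide mutation. Genes need more than 100 supporting reads (and,
at cohort level, presence in more than 5 samples) to be retained.
`P(IsotypeY | X, switched)` is computed over switched-class presence
events so that the sum over Y equals one exactly even when a sequence
occupies two switched classes.

*Gene profiles.* Per isotype class (IgM and IgD separate; IgG1/2 and
IgA1/2 merged), the percentage of unique-BCR presence events carried by
each retained V gene (≥ 100 reads of support); pairwise class
correlation defaults to Spearman (Pearson available). The
non-randomness test against unmutated IgD/M usage is an R×2 chi-squared
contingency test over retained genes, one p-value per class.

*Cohort tests.* Wilcoxon rank-sum (normal approximation) for metric
comparisons; one-way ANOVA of P(Switched | gene) on gene identity and
two-way ANOVA with a gene × mutational-status interaction via OLS.
Benjamini–Hochberg adjustment is available for families of pairwise
comparisons.

## Simulator

Each clone is an independent recombination: uniform V, D, J; 0–12
untemplated N nucleotides on each side of D, resampled until the total
junction keeps the J anchor in frame; founders are IgM (or IgD with
probability 0.3). Non-founder cells pick a uniform parent within the
clone, draw their isotype from the parent's row of a row-stochastic CSR
matrix restricted to downstream constant genes (deletional
recombination; IgM↔IgD transitions carry no mass), and add
Binomial(L, shm_rate) fresh uniform substitutions — no WRC/GYW hotspot
bias. Substitutions creating an in-frame stop codon are resampled by
default (expressed BCRs are productive); the unconditioned junction law
is available by switching `avoid_stop_codons` off. Cells that are
unswitched and unmutated are naive; others are plasmablasts with
probability `plasmablast_prob`, else memory. RNA copies default to
naive 1, memory 4, plasmablast 1000.

Two config extensions exist because the validation studies need planted
effects: `founder_switch_probs` gives each clone founder a per-V-gene
marginal probability of being class-switched (the quantity
`P(Switched | V gene)` estimates), and `planted_clone` creates a
dominant CLL-like clone whose per-cell SHM step is at most one
nucleotide, so the clone remains a single network component.

**Read emission and error model.** Every RNA molecule receives a unique
barcode; each molecule yields `1 + Poisson(pcr_duplicates)` read pairs.
The injected `error_rate` acts per amplified template copy — polymerase
errors shared by the two mates of a pair — which is the error class
barcode consensus is designed to remove; an independent per-mate
sequencing error rate is available separately (default 0). This is why
pairs merge despite errors (the mates agree with each other, not with
the true molecule) and why the within-barcode mismatch rate is an
unbiased estimate of the injected rate. Base qualities are nominal
(Q40): a polymerase error is a confidently read wrong base.

What the simulator does **not** model: indel sequencing errors,
chimeric PCR artifacts, SHM hotspot motifs, light chains, allele-level
germline variation, V/J exonuclease chewback. Passing tests therefore
demonstrate correctness of the estimators under substitution-type noise
and known clone structure, not robustness to indel-rich or
allele-ambiguous real data.

## Validation studies and problem sizes

The studies in `bcrnet.validation` (run by the test suite and
`scripts/acceptance.py`) use: 20 clustering fixtures of ≤ 500 unique
sequences; ~5,000 molecules for the noiseless round trip; ~47,000 read
pairs at 0.4% injected error with mean 5 reads per barcode for error
correction (post-consensus error measured over groups with ≥ 3 reads);
2 × 1,000 unique BCRs × 10 seeds for switch-probability recovery
(95% Clopper–Pearson intervals, joint coverage of both genes per
seed); ~1,500 clones at ~12,000 reads for overlap-ranking recovery
(depth 8,000, 20 subsamples); 400 single-cell clones with 25%
plasmablasts for the RNA-skew study; and a planted clone of 2,200 cells
over ~150 background clones (~85% of reads) for the CLL partition.
These sizes give each estimate enough support that the stated
tolerances are comfortably non-trivial while the whole battery runs in
well under a minute.

## Known limitations

* The annotator assumes the fixed amplicon layout (V anchored at the
  sequence start, J at the end); externally produced AIRR tables can be
  fed into the network/statistics layers instead.
* Barcode collisions and within-barcode strand chimeras are not
  modelled; barcodes are treated as exact keys (no fuzzy clustering).
* At per-base error ≥ ~1%, barcode-field errors create enough spurious
  singleton groups that consensus counts visibly exceed molecule
  counts; downstream unique-BCR statistics absorb most of this, but
  vertex read counts retain a small upward bias.
* The chi-squared non-randomness test needs several retained genes per
  class; sparse classes return NaN rather than a forced p-value.
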