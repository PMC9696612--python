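# Methods

This note documents the models and numerical choices behind `nlrkit`, what
the synthetic cohorts emulate, and what passing the validation suite does
and does not demonstrate.

## Profile scanning with exact p-values

Domains and motifs are modelled as ungapped position-specific scoring
matrices (PSSMs) over the 20 standard amino acids. Scores are log-odds in
bits against a background distribution (Robinson–Robinson frequencies for
proteome scans, a 0th-order model estimated from the input for motif work).
From an alignment block the matrix is
`log2((count(a,j) + pc·bg[a]) / (n + pc) / bg[a])` with total pseudocount
`pc` spread by background frequency.

Scores are discretized to 1/100-bit bins. The null distribution of a
window score is computed exactly by convolving the per-column score
distributions over the integer support; the survival function of that
distribution gives the p-value of a window, and `evalue = p × windows
scanned`. Because windows are scored with the same discretized integers the
DP uses, reported p-values are *identical* to exhaustive enumeration over
all length-w words — the suite verifies this on a 4-letter background,
where all probabilities are dyadic and float addition is exact. The
discretization error (≤ 0.005 bits/column) is negligible against every
threshold used.

Thresholds: `scan_proteome` defaults to E ≤ 1e-2, configurable. The
validation workflows scan at E ≤ 1e-6: planted-domain hits carry e-values
below 1e-30, while an E ≤ 1e-2 policy admits ~1 chance domain per 100
scans, enough to perturb exact-recovery measurements over thousands of
scans. Motif rescanning (`scan_motifs`) defaults to position p ≤ 1e-4
(a MAST-like confirmation threshold); the planted-registry pipeline uses
p ≤ 1e-9 because indicator-sharp PWMs place true occurrences near
p = 20^-w ≈ 3e-20, whereas p ≈ 1e-4 is reachable by ~6 chance residue
matches in 15.

## Architecture classification

A gene needs an NB hit to be an NB-LRR candidate. With NB + LRR, the
N-terminal kind decides TNL / CNL / RNL; NB + LRR without a recognized
N-terminus is NL; NB without LRR (including TIR–NB truncations) is the
partial label N; everything else is `other`. Architecture is
coordinate-ordered: the N-terminal hit must start before the NB hit and the
LRR hit after it. When several N-terminal kinds hit one gene the
best-scoring one wins, with ties broken RPW8 > TIR > CC (the rarest, most
specific signature first) and flagged for review; an absolute
kind-precedence was rejected because it would let a marginal RPW8 hit
override a full-strength TIR domain.

## Physical clusters

Two NB-LRR genes are linked when they share a seqid and at most
`max_intervening` (default 8) other annotated genes — of any kind,
including other NB-LRRs — lie strictly between their start coordinates;
clusters are the transitive closure. Within one seqid the count between two
candidates equals their index distance in start order minus one, so linking
consecutive candidates and chaining runs is exactly equivalent to the
all-pairs rule (any linked pair implies all its consecutive pairs are
linked); the suite nevertheless checks equivalence against a brute-force
all-pairs + union-find oracle on 1,000 random layouts. Overlapping genes
order by start, ties by id, and never cross seqids.

## Orthology

Pairwise similarity is Smith–Waterman with affine gaps (BLOSUM62, gap open
11, extend 1; a gap of length L costs 11 + L, the BLAST convention).
E-values follow Karlin–Altschul, `E = K·m·n·exp(−λS)` with the documented
gapped-BLOSUM62 constants K = 0.041, λ = 0.267; they are approximate and
used only for thresholding and ranking. Aligned intervals come from the
standard two-pass trick (argmax cell, then a reverse pass), avoiding a
traceback matrix. The kernel is numba-compiled; an independent
implementation (biotite's `align_optimal`, called with `gap_penalty=(-12,-1)`
to equalize the gap convention) serves as the oracle.

The orthology graph keeps cross-species reciprocal best hits (ties: higher
score, then lower e-value, then lexicographic id) and within-species edges
that pass E ≤ 1e-5 *and* are at least as strong as both members' best
cross-species hits — the recent-paralog criterion. A plain threshold is
available (`inparalog_mode="threshold"`) but is not the default: all
NB-LRR proteins share domain blocks, so at E ≤ 1e-5 nearly every
same-class pair qualifies and Markov clustering would fuse unrelated
families. Edge weights are −log10 E capped at 200.

Markov clustering runs per connected component on the column-stochastic
adjacency with self-loops at each node's maximum incident weight:
expansion (squaring), inflation (elementwise power 1.5, column
renormalization), pruning below 1e-5, until the iterant moves < 1e-6 or
100 iterations (then the current hard clustering is returned with a
warning). Clusters are the connected components of the converged matrix's
nonzero pattern; the result is always a partition, group ids are assigned
by decreasing size. A gene is a *paralog* when its orthogroup contains
another gene of its species. Reference proteins attach to the group of
their single best qualifying hit.

## Motif discovery

Discovery is expectation-maximization of one PWM at a time. For a width w,
all sequence windows form the sample; the site model is either
any-number-of-occurrences (ANR, default — repeated motifs such as M6a/M6b
are real in NB domains) or zero-or-one-per-sequence (ZOOPS). Erasure of
previously discovered motifs enters as a fixed per-window likelihood
discount (the minimum remaining position weight under the window), which
keeps the EM objective `Σ log((1−q) + q·f·L)` non-decreasing — a property
the suite asserts for every start.

Starting points are sampled windows (weighted by erasure) ranked by how
strongly their exact residues recur across sequences; the best `n_starts`
seed EM with a sharp initialization (0.85 on the seed residue per column).
The sharp start matters: from a soft start, EM reliably drifts into a
merged solution whose bimodal columns capture two unrelated motifs that
share a handful of residues, and that merged optimum has the higher
likelihood, so it would also win start selection. Significance of a fitted
motif is the total site information `Σ Z·log-likelihood-ratio` (bits); a
motif is accepted while this exceeds twice the best significance obtainable
from residue-shuffled sequences (computed once per width). The floor is
skipped when there are fewer than five windows per sequence, where a
shuffle largely reproduces the signal. Accepted occurrences (Z > 0.5) are
probabilistically erased and the search repeats; discovery stops early with
a warning when the floor is reached.

Rescanning, lettering (per-gene `a, b, …` suffixes in coordinate order,
restarting at each gene), presence matrices (lettered labels are distinct
columns), and strict/relaxed conserved- and class-specific-set calls follow
the definitions in the module docstrings.

## Family profiles

Presence matrices are clustered with Jaccard distance and average linkage
by default (standard for binary trait matrices; Hamming and complete
linkage are flags), rows sorted by label for deterministic ties, cut at
k = 8 groups by default to mirror the conventional eight-pattern report.
`pearson` is the closed-form product-moment coefficient with explicit
zero-variance and short-input errors. Family summaries report the
arithmetic mean with the min–max range, formatted `mean (min–max)`.
Reports are timestamp-free JSON/TSV/newick with content checksums, so
reruns are byte-identical.

## The synthetic cohort

`synthdata.generate_cohort` emulates the statistical structure the pipeline
assumes, not real sequences:

* **Building blocks.** A registry of domain segments (TIR 40, CC 30,
  RPW8 32, NB anchor 40, LRR unit 24 residues) and NB motifs (13 core plus
  per-class specific sets; width 15 by default) is drawn from background
  frequencies with rejection sampling so no two planted blocks share ≥ 40%
  positional identity at any offset — without this, chance near-matches
  make the planted truth itself ambiguous.
* **Founders and orthogroups.** Each founder concatenates N-terminal
  domain, linker, NB anchor, core+specific motifs in class order with
  founder-specific 2–6-residue spacers, 3–5 identical LRR units and a tail
  (partial-class founders are NB-only). Orthogroups follow a star
  phylogeny: per species a founder survives with probability 1 − loss_rate
  and its copy mutates at `substitution_rate` per residue (substitution
  redraws uniformly over the alphabet, so rate 1 leaves 5% identity);
  per-motif dropout replaces a motif block with random residues of equal
  length, keeping coordinates stable. Tandem duplicates are copies of the
  *species* gene at one-fifth the substitution rate — recent duplicates, as
  the recent-paralog graph rule expects.
* **Layout.** Tandem arrays always form physical clusters; single-copy
  founders co-cluster per a size distribution heavily skewed to singletons.
  Within clusters, 0–8 background genes intervene (drawn from a configured
  distribution); between clusters at least 9 background genes separate, so
  the planted clusters are exactly the components under the default rule.
  Species draw heterogeneous duplication propensities
  (uniform(0.05, 2.5) × duplication_rate), producing the family-size spread
  real repertoires show and structurally coupling per-species paralog and
  cluster counts. `genes_per_species` is a target: background genes are
  topped up if a species draws many copies, so layout guarantees always
  hold.
* **Determinism.** All randomness flows through named streams derived from
  the config seed (registry stream; one stream per species index), so a
  fixed config reproduces byte-identical FASTA/GFF3/truth outputs and the
  cohort is stable under adding species.

What the cohort does *not* emulate: real amino-acid composition beyond
0th-order frequencies, indels and domain-length variation, gene-structure
features (introns, UTRs, nucleotide sequence), non-star phylogenies,
segmental duplications and synteny. Passing the recovery tests therefore
shows the pipeline's decision structure is correct under its own model
assumptions — exact thresholds and recovery rates on real proteomes will
differ, and profile-HMM scanners remain preferable for real data (the
domain scanner accepts InterProScan/HMMER tabular output for that reason).

## Validation problem sizes

The suite and `scripts/acceptance.py` use: 1,000 random layouts for the
cluster-rule oracle; a 5-species cohort with ~200 NB-LRR genes at 5%
substitution for orthogroup recovery (ARI vs planted families); 100 random
pairs for the alignment oracle; 30 planted 15-mers in 70 sequences for
motif recovery at 0% and 5% noise; a two-class cohort planted with
13 core + 8 TNL- + 10 CNL-specific motifs for the conserved-set calls;
width-4 motifs on a 4-letter background for p-value enumeration; and a
ten-species cohort for the cluster–paralog correlation. These sizes keep a
full validation run to a few minutes while leaving every measured property
non-trivial.

## Known limitations

* Karlin–Altschul parameters are fixed for BLOSUM62 11/1; other matrices
  require user-supplied constants for meaningful e-values.
* Motif width selection searches a coarse grid and compares significance
  margins across widths without MEME's full E-value machinery; widths far
  from the planted range are not tested.
* MCL uses dense per-component matrices — fine for thousands of genes,
  not for whole-proteome graphs.
* The InterProScan reader trusts the 13-column layout and maps unknown
  signatures to `other` rather than failing.
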