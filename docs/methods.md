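# Methods

This document records the exact conventions each stage implements, the
assumptions behind the simulator, and the numerical choices a reader
needs to interpret (or reproduce) the outputs.

## Sequence model and shared conventions

- Genomes are sets of contigs over `ACGTN`; genes are 1-based inclusive
  coordinate spans with strand `+`/`-`; minus-strand CDS are the reverse
  complement of the slice.
- Translation uses the standard bacterial/nuclear code (NCBI table 1);
  a trailing stop codon is stripped, an internal stop is an error that
  names the codon position, codons containing `N` translate to `X`.
- Functional annotation uses one-letter COG-style categories `A`–`Z`
  (X = mobilome, M = cell envelope, …). Proportions are always computed
  over **annotated** members only; the annotated fraction is reported
  separately so the denominator is never hidden.

## ANI (fragment method)

Each genome is cut into non-overlapping 1,000 bp windows per contig
(trailing remainder discarded; window length must be ≥ 100 bp). A window
is searched against the other genome by exact 15-mer seeds on both
strands, extended ungapped over the full window at each candidate
diagonal, and **accepted** when ≥ 70% of the window aligns within the
target and identity ≥ 30%. One-way ANI is the mean identity of accepted
windows; reported ANI is the mean of the two directions (or the one that
produced an estimate; `None` if neither did). Close relatives are
background genomes with ANI **strictly** > 95% to at least one focal
genome.

Assumption: the acceptance thresholds make ANI exactly interpretable on
substitution-only genome pairs (which is how the simulator's recovery
tests are built); genomes with large indel/content differences lower the
aligned fraction rather than the identity.

## Ortholog clustering (RBH)

Proteins are compared by global alignment (BLOSUM62, affine gaps, open
−11 / extend −1); identity is identities divided by alignment length
*including gap columns*, ×100. For each gene, candidate partners in each
other genome are ranked by shared amino-acid 4-mers (descending, ties by
id) and capped at 50 — a seeding heuristic bounding the number of full
alignments; a pair is an edge when it is the mutual best-scoring match,
identity ≥ 30% and the shorter/longer length ratio of aligned coverage is
≥ 0.5. Within-genome paralog edges require > 70% identity (with a
score-based screen at 0.4× the smaller self-score to skip hopeless
alignments). Clusters are connected components of this graph; unmatched
genes form singletons. Cluster category is the majority vote of annotated
members, ties broken lexicographically. A cluster is **unique** when its
member genomes are a subset of the focal set.

Marker density (genes per Mb of genome) between focal and background
groups is compared with a two-sided Mann-Whitney U test (scipy); both
groups must have ≥ 2 genomes.

## Rank-decile variation

Each focal protein's **top-hit identity** is the identity of its
best-scoring global alignment against the background protein set (same
aligner/identity conventions as above; candidate prefilter as above). A
raw-score threshold (default 50) stands in for a database E-value cutoff;
`calibrate_score_threshold` derives one empirically as the (1 − fpr)
quantile of scores between shuffled protein pairs. Proteins with hits are
sorted by dissimilarity (100 − identity) ascending, ties by gene id, and
split into 10 bins whose sizes differ by at most one (larger bins first).
For each category, its within-bin share (over annotated members) is
correlated with the bins' mean dissimilarity: Pearson r from the
covariance formula, two-sided p from the t transform on n − 2 degrees of
freedom, significance at p < 0.01. Categories with zero variance in
either vector are reported as undetermined rather than r = 0.

## Codon usage (Wright's ENC)

Per amino-acid family homozygosity is F̂ = (nΣp̂² − 1)/(n − 1), undefined
for n < 2 or F̂ ≤ 0. ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with F̄ the
mean over defined families in each degeneracy class (2-fold ×9, 3-fold =
Ile, 4-fold ×5, 6-fold = Leu/Ser/Arg as single classes); a missing 3-fold
class is imputed as (F̄₂ + F̄₄)/2; values above 61 are truncated to 61.
Met, Trp and stops are excluded. GC3 is the G+C fraction at third
positions of countable (unambiguous, non-stop) codons. The expected curve
is ENC\*(s) = 2 + s + 29/(s² + (1 − s)²) with s = GC3; a gene is "below
the curve" when its ENC is smaller than ENC\*(its GC3).

Endpoints (verified analytically and in the acceptance suite): one codon
per degenerate family gives exactly 20; exactly equal synonymous counts
give 64.73 before truncation, reported as 61.

## Recruitment and RPKG

BLAST tabular (outfmt 6, 12 columns) hits are parsed with query coverage
= absolute query span / read length (so minus-strand query coordinates
work); filters are inclusive: evalue ≤ 1e−5 (hits without an evalue
pass), identity ≥ 95, coverage ≥ 80. The built-in mapper seeds reads by
exact 21-mers on both strands, extends ungapped, scores identity over the
read length and reports coverage 100 with one best hit per (read,
genome). Competitive assignment gives each read to the genome of its
highest-identity hit; ties break by higher score, then lexicographically
smallest genome id. RPKG = (Rx / MG) / Gx with the metagenome size MG in
gigabases and genome size Gx in kilobases. Depth profiles are Z-normalised
per genome row with the sample (ddof = 1) standard deviation, constant
rows mapping to zeros, and clustered by complete linkage on Euclidean
distances (rows sorted by id first so input order cannot change the
tree); the tree is serialised as Newick with branch lengths from merge
heights.

## Simulator: scope and limits

`simulate_clade` draws an ancestor (genes with Zipf-like codon weights
`(rank+1)^(−4·bias)`, fixed intergenic spacers) and derives each genome
by substitution only: a nucleotide budget `round(d·L)` per genome, split
into amino-acid-changing single-nucleotide codon swaps (never creating
stops) and synonymous swaps, spacers mutated at rate d. Per-category
divergence multipliers scale the nonsynonymous share. Focal genomes
additionally receive planted unique genes drawn from a category
distribution over-weighting X and M. Ground truth records the family of
every gene, the unique gene ids and all planted divergences.

Limits, by design: no indels, rearrangements, gene loss, HGT between
simulated genomes, or amplification bias — so planted divergence is
exactly recoverable and ANI/clustering errors are attributable to the
method, not the generator. Pairwise divergence between two genomes is
approximately the sum of their divergences from the ancestor.

`simulate_divergent_proteome` (used for the fast-category power study)
draws per-gene base amino-acid divergence as 0.02 + Exponential(mean
0.06), capped at 0.45, times the category multiplier. The heavy tail
mirrors real ortholog divergence (most genes conserved, a minority fast)
and is what makes the decile analysis well-powered at desk scale; with a
uniform divergence distribution the category-share response is too convex
for a 10-point Pearson screen. This distribution was fixed before the
acceptance replicates were scored.

Read simulation picks a genome per read proportional to abundance ×
genome length, a uniform start on a uniformly chosen contig and strand,
and independent substitution errors.

## Problem sizes

The shipped configurations are desk-scale choices, not claims about real
data: genomes of tens of kilobases (50–100 genes of 120–300 codons),
4–5 genomes per clade, thousands to 50,000 reads of 150 bp, 10 bins ×
60 genes per category for the power study. At these sizes the full test
suite runs in well under the 25-minute budget on one CPU and every
recovery criterion (ANI ± 0.5 points at 1/5/10% divergence, exact family
recovery at ~10% pairwise divergence, unique precision/recall ≥ 0.9,
fast-category detection in ≥ 90/100 replicates, RPKG r ≥ 0.99) is met
with margin.
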