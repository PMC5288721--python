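# Methods

## The problem

An ancient whole-genome duplication (WGD, paleotetraploidy) leaves two
signatures in a modern diploidized genome: long runs of genes whose paralogs
appear in conserved order elsewhere in the genome (homeologous synteny
blocks), and an excess of paralog pairs at a common sequence divergence (a
peak in the distribution of a divergence clock). `wgdkit` implements the
desk-scale computational chain that turns a gene annotation plus protein
similarity into that evidence — block detection, per-pair divergence
statistics, peak calling, homeolog-retention counting — together with
genetic-map scaffold anchoring and a simulator that generates genomes with a
known duplication history so every stage can be validated against ground
truth.

## Synteny blocks

Homologous gene pairs (anchors) are projected into rank space: gene order
along each sequence, 0-based, assigned by start coordinate (ties by end,
then gene id). Blocks are chains of anchors with strictly monotone ranks on
both sides (increasing for parallel, decreasing on side b for antiparallel
blocks) in which consecutive anchors are separated by at most
`max_intervening` genes (default 6, i.e. a rank gap of at most 7) and which
contain at least `min_genes` anchors (default 10). These defaults are the
acceptance criterion commonly used for defining homeologous regions in
plant paleopolyploidy studies.

Chaining is exact dynamic programming over anchors sorted by rank, scored by
summed hit bit scores with hard gap constraints (no gap penalty). Blocks are
extracted greedily: the best remaining chain is accepted, its anchors are
retired, and the search repeats until the best chain drops below
`min_genes`. All ties break deterministically: higher score, longer chain,
smaller (rank_a, rank_b) start, parallel before antiparallel. Tandem arrays
(anchors sharing a partner whose genes on one side lie within
`tandem_window` = 5 ranks of each other) collapse to their best-scoring
member before chaining so a local array cannot fake a block.

Two consequences of the greedy extraction rule are worth knowing. First,
raising `min_genes` can only reduce the number of blocks (it only moves the
stopping threshold). Second, raising `max_intervening` does *not*
necessarily increase the total number of anchored pairs: a larger gap
allowance can merge two acceptable chains into one and strand the leftover
anchors in fragments below `min_genes`. This is inherent to greedy
extraction with anchor exclusivity, not a bug; the test suite checks the
first property and documents the second with a counterexample.

Homeology patterns are classified on a graph over linkage groups weighted by
summed anchor counts: a two-group component whose mutual weight is at least
80% of each group's total is reported as a 1:1 homeologous pair; larger
components are "complex" (the signature of post-WGD rearrangement).

## Protein similarity

The all-vs-all search is exact affine-gap Smith–Waterman (BLOSUM62, gap
open 11, extend 1, unknown residues scored 0), affordable at desk scale and
free of seeding heuristics. Hits carry an E-value-like statistic
`E = K·m·n·exp(−λ·S)` with the fixed gapped-BLOSUM62 constants λ = 0.267,
K = 0.041, query length m and total database length n. Absolute E-values are
not calibrated against any external engine; what the pipeline relies on is
thresholding at the conventional cutoffs — 1e-10 within a genome, 1e-5
across genomes. A shared-k-mer prefilter (default word length 5) skips
sequence pairs with no common word; its soundness (no reported hit lost) is
a tested property, not an assumption.

## Divergence statistics

Each block pair is globally aligned at the protein level (end gaps free),
back-translated to a codon alignment, and summarised by:

- **4DTv** — the fraction of fourfold-degenerate third-codon sites that
  differ by a transversion. A site qualifies only when both codons share an
  identical two-base prefix that determines the amino acid regardless of the
  third base (the conservative convention: the third position is then
  synonymous in both sequences). Transition-only differences stay in the
  denominator. The multiple-hit correction is the Kimura transversion
  component, `−1/2·ln(1 − 2v)`, saturating at v ≥ 1/2; under a two-parameter
  substitution model this recovers exactly the transversion part of the
  divergence, and it is monotone in v, so peak locations are robust to the
  choice of any other monotone correction. The raw proportion is always
  reported alongside.
- **Ka/Ks (NG86)** — Nei–Gojobori counting: per-codon synonymous site
  fractions averaged over the two sequences (single-base changes to stop
  codons count as nonsynonymous); observed differences partitioned by
  equal-weight averaging over the minimal substitution pathways, excluding
  pathways through stop codons (if every pathway is blocked — possible for a
  handful of codon pairs — all pathways are averaged as a documented
  fallback); proportions corrected by the one-parameter formula
  `d = −3/4·ln(1 − 4p/3)`, saturating at p ≥ 3/4. Ka/Ks is undefined when
  Ks = 0 and flagged rather than raised.

Family-level selection contrasts use Welch's unequal-variance two-tailed
t-test of each labeled family's Ka/Ks values against a reference set (a
named family, or the pool of all defined values).

## Peak detection and event ordering

Corrected 4DTv values are binned (width 0.01 on [0,1]) and smoothed with a
Gaussian KDE using Silverman's bandwidth (recorded in the output). The
density is reflected at both support boundaries — without reflection the
KDE's edge falloff manufactures a spurious interior mode even on flat data —
and renormalised to integrate to one on the evaluation grid. Peaks are local
maxima with prominence at least 10% of the maximum density, reported at the
KDE argmax to three decimals. With fewer than 50 pairs a warning is issued
and peak calls should not be trusted.

Event ordering compares the youngest self-comparison peak (the candidate
WGD) with each cross-comparison peak (speciation): differences within a
tolerance (default 0.01) are reported as "indistinguishable" rather than
forced into an order, since peak-location noise at realistic pair counts
exceeds that difference.

Retention analysis counts, for every outgroup gene, the number of focal
queries listing it among their top-k best hits (k = 2 by default, bit-score
ranking with E-value then id tie-breaks); outgroup genes with 1..k homologs
are tallied and the share with exactly k is the two-copy retention
percentage.

## Scaffold anchoring

Marker flanks are located by exact substring search (forward and reverse
complement) against all scaffolds: exactly one occurrence is a unique
placement, more is ambiguous, none is unplaced. Scaffolds take the linkage
group of the majority of their unique markers (conflicts flagged, ties to
the smaller group number), are ordered by median marker cM (median rather
than mean: robust to one misplaced marker), and are oriented by the sign of
the Spearman correlation between marker offset and cM — at least two
distinct genetic positions are required, otherwise the scaffold stays
unoriented, written as "?" in the emitted AGP v2.1 file. Mismatch-tolerant
flank matching is out of scope.

## The simulator

The generator produces an ancestral gene order (random strands,
non-overlapping coordinates, random in-frame CDS without internal stops,
embedded in random intergenic sequence), splits off a single-copy outgroup,
duplicates every focal chromosome, deletes each duplicate copy independently
with the fractionation probability, optionally applies segmental inversions
and translocations (uniform 5–20-gene segments), and diverges every CDS
under a two-parameter (Kimura-type) codon-site model: transitions at rate
κβ, each transversion at rate β, mutations creating internal stops rejected,
amino-acid-changing mutations accepted with probability ω (default 0.2, the
simulated purifying pressure that makes Ka/Ks recovery testable).

Branch lengths are expected substitutions per fourfold-degenerate site per
lineage. Because every proposal at a 4D site is accepted, scaling the
proposal clock by `β·T = L/(κ+2)` makes the realized 4D substitution rate
exactly L; the expected corrected 4DTv of a pair is then `2d/(κ+2)` for
total divergence d — equal to the per-lineage branch length at the default
κ = 2.

Defaults are calibrated to the rubber-tree-like study system the package is
built around: κ = 2; WGD branch 0.073 and speciation branch 0.14 per
lineage, so the self- and ortholog-comparison 4DTv distributions are centred
on 0.073 and 0.14; per-copy loss probability 0.285, for which the expected
two-copy retention among outgroup genes with a surviving homolog,
`(1−p)/(1+p)`, is 55.6%; two chromosomes of 400 genes; CDS lengths 250–350
codons (≈ 900 bp, the average coding length of the emulated annotation).
The focal lineage receives a pre-WGD branch of `speciation − wgd` before
duplication, so ortholog pairs total `2·speciation` and paralog pairs total
`2·wgd` substitutions per 4D site. The truth table records every surviving
paralog/ortholog pair with expected and realized divergence (realized
counts accepted substitutions at 4D third positions over the branch-start
4D codon count — the 4D site set drifts slightly during descent, which the
consistency tests absorb within sampling error), per-ancestral-gene loss
flags, and, for the synthetic map, each scaffold's linkage group, order and
orientation.

What the simulator does not emulate: repeats and transposons, introns,
tandem-array birth/death, codon-usage bias, rate variation across sites or
genes, and more than one WGD (no older eudicot-scale peak). Passing tests
therefore demonstrate correctness of the inference chain under a clean
neutral-ish model, not robustness to every artefact of real annotations.

## Numerical behaviour worth knowing

- The mean of per-pair corrected 4DTv carries a small upward Jensen bias
  (the correction is convex), of order `var(v̂)/(1−2v)²`; with a few hundred
  4D sites per pair it is well under 1% and the recovery tests bound it
  explicitly.
- The KDE peak of the per-pair distribution sits a few percent *below* the
  mean divergence: Poisson branch-length variation plus binomial site
  sampling skew the per-pair distribution right, so its mode is left of its
  mean. At 400–800 pairs the self-comparison peak of a 0.073-expectation
  simulation typically reads 0.063–0.073. Peak locations should be read with
  the reported bandwidth in mind.
- All randomness flows from a single integer seed; identical configuration
  and seed reproduce byte-identical outputs. Replicate seeds in the
  simulation study derive deterministically from the master seed.

## Problem sizes used in the shipped validations

The test suite runs the full chain on simulated genomes of 2 chromosomes ×
400 genes (≈ 1,100–1,300 post-fractionation genes); the acceptance script
uses 2 × 600 genes, at which ~600 surviving paralog pairs make the KDE peak
location stable to about ±0.004 while the exact all-vs-all search stays a
few minutes on one CPU. Oracle comparisons (exhaustive chain enumeration,
brute-force NG86 pathway counting, ≤ 16-anchor random instances, 61×61
codon pairs) run at the scale where exhaustive computation is exact.
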