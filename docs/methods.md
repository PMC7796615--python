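# Methods

This note records the models, conventions and numerical choices behind
`plastidflow`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and strands

Internally every interval is 0-based half-open on the plus strand of a
circular reference; GFF3's 1-based inclusive coordinates exist only at the
file boundary, where the conversion is an involution.  Origin-spanning
features use the unrolled dialect (`end > genome length`) and are flagged;
positions inside them are resolved modulo the genome length.

Strand-specific libraries are resolved at SAM reading time.  Under the
dUTP `fr-firststrand` convention the first read of a pair is antisense to
the transcript: R1 mapped to the reference minus strand means a `+`
transcript, R2 mapped to minus means `-`; mates of a proper pair always
agree.  Downstream code only ever sees a per-record `transcript_strand`.
Supported CIGAR operations are M/I/D/S — plastid CDSs need no spliced
alignments at this scale; N/H/P are rejected explicitly.

## Coverage and transcribed fraction

Coverage is the mapped read count per base, kept per transcript strand
(deletions span but do not cover).  Window profiles use non-overlapping
windows (default 100 bp, final partial window retained) with the **mean**
per-base count as the window statistic — mean is the scale-consistent
choice for "read counts per base"; sum or max would only rescale or
roughen it.  The compression `log10(raw + 1) / log10(max_raw + 1)` is
anchored per strand and per species at its own maximum window value, which
maps zero coverage to 0 and the maximum to exactly 1; an all-zero strand
maps to all zeros.  A position counts as transcribed when its read count
reaches `min_cov` (default 1); the combined fraction is computed on the
union of strands and therefore never falls below either single-strand
fraction.

## Expression

A read is assigned to a CDS when at least 50 % of its aligned length
overlaps it; the larger overlap wins when two CDSs qualify, and exact ties
count for both (flagged `ambiguous`).  Sense/antisense is the comparison
of read transcript strand with CDS strand.  TPM is computed from sense
counts only: `rate_g = count_g / length_g`, scaled so rates sum to 10⁶;
an all-zero table stays zero.  Inter-species correlations default to
`log10(TPM + 1)`: plastid expression spans orders of magnitude and the few
dominant photosynthesis genes would otherwise determine the coefficient
alone.  Raw-TPM correlation is available via `transform=None`.

## Rearrangement distances

Annotated gene orders (restricted to genes present exactly once in every
species) are decomposed into synteny blocks: maximal runs whose adjacency,
with consistent relative orientation, holds in every species.  Each
species then becomes a circular signed permutation of blocks.  Distances
are computed from extremity adjacency sets, which makes them invariant to
rotation and to flipping the whole molecule — the two symmetries of a
circular genome.

- Breakpoint distance: oriented adjacencies of one genome absent from the
  other.
- DCJ distance: `N − C`, blocks minus cycles of the adjacency graph; for
  unichromosomal circular genomes this equals the minimal number of
  double-cut-and-join events, and one inversion is one event.  The test
  suite proves the formula against an exhaustive breadth-first search over
  genome states for every signed circular order of up to five blocks, and
  checks the metric axioms and the bracket `bp/2 ≤ dcj ≤ bp` on random
  instances.

DCJ is the default "pairwise rearrangement" (PR) statistic, with the
breakpoint distance reported alongside; how published rearrangement counts
were tallied is generally not stated, and DCJ is the standard minimal
inversion-event count for this geometry.

## C-to-U editing

Pileups are per position and per transcript strand, with read bases
projected to the plus strand (soft clips and insertions never touch the
reference; overlapping mates count independently, matching the coverage
semantics).  A `+`-strand candidate is a plus-strand C whose reads show T;
a `-`-strand candidate is a plus-strand G whose reads show A.  With
`n = edited + unedited` (other bases excluded as sequencing noise), a site
is called when `n ≥ 50`, `edited/n ≥ 0.1`, and the exact one-sided
binomial tail `P(X ≥ edited | n, ε) ≤ 10⁻⁶` with base error rate
`ε = 0.001` (≈ Q30).  The binomial test replaces a proprietary variant
p-value model with a transparent equivalent playing the same thresholding
role.  Efficiency is the fraction `edited/(edited+unedited)`; the literal
edited:unedited ratio is exposed as an auxiliary property.

Classification translates the affected codon before and after C→U with
the bacterial/plastid code (table 11): same amino acid → silent, changed →
non-silent; a site inside a CDS on the opposite transcript strand is
antisense (sense takes priority when CDSs overlap); sites outside all CDSs
are reported as noncoding but sit outside the three main categories.

Cross-species sharing maps each site to a column of a codon-aware
alignment of its ortholog group: sequences are translated (terminal stop
kept as a residue so its codon aligns too), globally aligned with BLOSUM62
and affine gaps (open −10, extend −0.5), star-wise around the longest
sequence, and back-mapped to nucleotides.  A site is shared when two or
more species carry a called site in the same column of the same group with
the same strand class.  Positions inside insertions relative to the centre
sequence have no common column and default to specific — a limitation that
only matters when several species share an insertion.

## Association statistics

The per-pair table holds, for each of the S(S−1)/2 unordered species
pairs, the ortholog expression correlation r_expr, the rearrangement count
PR, and the patristic distance (sum of branch lengths on the supplied
tree).  The two headline tests are plain two-sided Pearson tests across
those rows — PR vs distance (phylogeny control) and PR vs r_expr — with
`t = r·√(n−2)/√(1−r²)` on n−2 degrees of freedom and no multiple-testing
correction (a Benjamini–Hochberg helper exists upstream of nothing by
default).

Pairwise rows sharing a species are not independent, so this test is
mildly anticonservative: under the generator's no-association null it
rejects at about 9 % instead of the nominal 5 % (400 simulated families).
That is an intrinsic property of correlating pairwise matrices and the
reason the package also exposes a Mantel permutation test (Pearson r on
off-diagonal entries; add-one estimator `(1 + hits)/(n_perm + 1)` over
label permutations, exhaustive for ≤ 4 species), clearly labelled as the
calibrated companion rather than the primary statistic.

## The synthetic-data generator

The generator emulates, at desk scale, the structure that matters to each
pipeline stage:

- **Genome**: ~40 CDSs (default) in ~12 contiguous same-strand operons on
  a circular molecule of ~25–30 kb, genes 300–900 bp built codon-wise with
  no internal stops, short intra-operon spacers (20–60 bp) and longer
  inter-operon spacers (120–300 bp).  Real plastomes are 120–160 kb with
  ~80 single-copy CDSs; sizes here are scaled down ~4× so simulations run
  in seconds, which changes no algorithmic behaviour.
- **Inversions**: endpoints only in intergenic spacers, each endpoint cut
  at the midpoint of a previously uncut spacer.  Fresh endpoints mean each
  inversion breaks two original gene adjacencies and creates two new ones,
  so k inversions land at breakpoint distance 2k and DCJ distance exactly
  k — the ground truth behind the parameter-recovery tests.  The origin-
  flanking spacers are excluded so no feature ever wraps.
- **Transcription**: each operon emits its primary transcript at a
  lognormal rate (σ = 1, spanning the orders of magnitude real plastid
  genes span); with probability 0.2 (a free parameter — no quantitative
  read-through rate is published) transcription continues past the
  terminator into the next downstream unit, geometrically, two levels
  retained; a genome-wide background on both strands at 0.02× the mean
  operon rate models pervasive antisense/intergenic transcription and
  pushes the combined-strand transcribed fraction toward 100 %.
- **Edits**: sites are chosen at sense-strand C positions with adequate
  expected coverage and carried per fragment with probability equal to the
  target efficiency, so both mates of a pair agree.
- **Reads**: constant fragment length (240 bp; no insert-size
  distribution), fixed read length (80 bp), uniform fragment starts,
  substitution errors at ε per base, no indels and no quality strings.
  Records are emitted directly as alignments with the FR flag layout that
  makes `fr-firststrand` parsing recover the true transcript strand —
  alignment itself is out of scope.
- **Manifest**: exact expected per-base coverage (by direct convolution of
  the fragment-start window with the two read kernels) and per-gene
  abundance accompany every species, so coverage, TPM ranking and editing
  calls are all checked against closed-form truth, not against another
  simulation.

The family generator derives six species from one ancestor with
k = (0,1,2,3,4,5) inversions.  In the **coupled** scenario transcription
units are re-derived from each rearranged genome — relocated genes acquire
new operon contexts and read-through neighbours, the hypothesised
mechanism — and per-gene log-rates are additionally perturbed with
sd 0.35·√k, chosen so pairwise expression correlations span roughly
0.6–1.0, the range reported for real conifer orthologs.  In the
**uncoupled** (null) scenario transcription is position-insensitive (every
gene its own unit, no read-through) and every species receives a
perturbation of identical norm, so expression divergence carries no
rearrangement signal at all.  Genetic distances come from a star tree with
lognormal branch lengths drawn independently of k, mirroring the
observation that sequence divergence and rearrangement count need not
track each other.

What passing tests on these simulations do **not** show: behaviour under
real base-quality profiles, indels, spliced or multi-mapped reads, IR-type
large repeats (duplicated genes are excluded from block anchoring), RNA
degradation biases, or biological replicate structure.  The generator is a
model of the data-generating process the methods assume, not of a
sequencer.

## Numerical and degenerate-input choices

- TPM of an all-zero count table is all zeros (no 0/0).
- `window_scores` of an all-zero strand returns all zeros rather than 0/0.
- `pearson` raises on zero variance; `pearson_pvalue` returns 0 for
  |r| = 1 and flags it (`exact_r`) rather than dividing by zero.
- Binomial tails use `scipy.stats.binom.sf(e−1, n, ε)` — exact, not a
  normal approximation, because calls sit in the extreme tail.
- Ties in read-to-CDS assignment go to both CDSs, flagged, rather than an
  arbitrary winner.
- Every randomised operation takes an explicit seed; derived seeds are
  drawn below 2³¹ from a master `numpy` Generator, and reruns with the
  same configuration are byte-identical.

## Problem sizes

Defaults are sized so the full test suite runs in about a minute and the
acceptance script in well under a minute on one CPU: exhaustive DCJ
verification to five blocks (443 circular orders against a 945-state BFS),
1,000 random breakpoint instances at 6–10 blocks, 60 inversion-recovery
runs, 10 editing-recovery species at ~150× coverage, one 10⁵-read-pair
species for TPM/coverage statistics, and 20 coupled + 100 null families
for the association analysis.
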