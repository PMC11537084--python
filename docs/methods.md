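# Methods and design notes

This note records the models behind `markerbench`, the defaults and why
they were chosen, and the places where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic reference collections

Genomes are generated on a star phylogeny per genus: a random ancestor
operon is mutated independently into species consensus sequences, each
species into genomes, and each genome into operon copies. Mutations are
i.i.d. per site; each hit is a substitution to one of the three other
bases, or (with probability `indel_fraction`, default 0.1) a 1 bp
insertion or deletion. Because leaves of a star are two branches apart,
branch rates are half the configured *pairwise* divergences
(`d_between_species` 0.02, `d_within_species` 0.002, `d_between_copies`
0.001 substitutions/site by default). With indels disabled the recorded
per-site mutation process is an exact oracle for pairwise Hamming
identity, which is how the generator is tested.

The operon template mirrors typical bacterial averages: 16S 1,536 bp,
ITS1 400 bp, 23S 2,914 bp, ITS2 169 bp, 5S 108 bp — 5,127 bp total,
inside the 4,000–6,000 bp retention window. Concrete expansions of the
341F/805R degenerate primers are planted at fixed offsets in the 16S
(forward at 340, amplicon span 465 bp, inside the 430–550 bp filter) and
exempted from mutation, so in-silico PCR is guaranteed a target while
everything between the primers diverges. Copies are laid head-to-tail
with 200–500 bp random spacers; all coordinates are 0-based half-open.

What this emulates: controlled species separability per marker length,
multi-copy structure, conserved primer sites. What it does not: real
phylogenetic correlation between species, horizontal transfer of operon
segments, intragenomic copy heterogeneity beyond a uniform rate, GC or
codon structure, and real-world V3–V4 degeneracy (some real species are
identical over V3–V4; here divergence is uniform, so the short amplicon
is *relatively* more informative than in nature). Passing tests
therefore demonstrate correctness of the machinery and the direction of
marker-length effects, not field-calibrated accuracy magnitudes.

## Error model

Scanning original positions left to right, three independent uniform
draws per position decide deletion, insertion (uniform random base
before the position), then mismatch — a deleted base is never also
substituted. Mismatches substitute one of the three *other* bases so the
realized per-surviving-base mismatch frequency equals the nominal rate;
a `mismatch_includes_self` flag restores the 4-way draw. Built-in rates:
nanopore-class 0.0116/0.0081/0.0144 (mismatch/insertion/deletion) for
operon, 23S and 5S (they ride on the same long read), Illumina-class
0.0089/0.00045/0.00045 for 16S and V3–V4. Calibration is asserted at
three binomial standard errors over 2,000,000 positions, with mismatch
frequency measured per surviving base and indel frequencies per original
position.

## Classifiers

*k-mer matching* scores each species by the number of query windows
(counted with multiplicity over query positions) whose 31-mer occurs in
that species' reference set, forward strand only — queries and
references share orientation by construction. *Alignment* scores each
reference by the Smith–Waterman local score with match +2, mismatch −3,
gap open −5 and gap extend −2 (a length-g gap costs 5 + 2(g−1)); the
constants are a fixed, configurable stand-in for default nucleotide
BLAST scoring — only the score *ranking* enters the decision rule, and
raw score is monotone in bitscore at fixed parameters. The kernel is a
numba-jitted score-only DP, verified in tests against an independently
written full-matrix DP and against Biopython's `PairwiseAligner`.

Decision rules: ties broken uniformly at random with a seeded draw; a
genome with several copies is called by its best-scoring copy (ties
again random); a query with zero k-mer matches is left unclassified and
scored incorrect. References deliberately *include* the query's own
error-free source sequence — the benchmark measures error tolerance plus
species separability, not leave-one-out generalization.

## Metrics and confusion

Per-genus accuracy is correct calls over genomes. Precision and
sensitivity are one-vs-rest per species, macro-averaged over species
present in truth; a species never predicted is skipped from the
precision average (micro-averaging, where both collapse to accuracy, is
available). The confusion matrix is the row-normalized count table
P(predicted | true); unclassified calls are excluded from their row with
a warning (they cannot be attributed to any predicted species — rare at
the default settings, 5S only). The paired marker comparison is a
two-sided Wilcoxon *signed-rank* test on per-genus accuracies — the
paired member of the rank-test family — with zero differences dropped
and an exact null for n ≤ 25 without ties.

## Community simulation

True profiles draw per-species Dirichlet concentrations i.i.d. from
Geometric(p = 0.01) on {1, 2, …} (mean 100), then one Dirichlet draw.
Reads are apportioned by deterministic largest-remainder rounding
("distributed to match the true proportions" read as exact matching;
fractional-part ties go to the lower index), then reassigned per species
by one multinomial draw over its confusion row — mathematically
identical to per-read categorical sampling, and tested against a naive
per-read oracle in distribution. Library sizes default to 5,000–1,000,000
in six steps with six replicates; by default each replicate draws a
fresh true profile (a fixed-profile mode exists since it is unclear
whether replicates should share one truth).

## Compositional evaluation

CLR uses multiplicative zero replacement with δ = half the smallest
nonzero proportion followed by renormalization — the standard
conservative default, flagged prominently because it materially affects
Aitchison distances; δ and the policy are configurable. Aitchison
distance is the Euclidean norm of CLR differences; PCoA is classical
scaling delegated to scikit-bio; ANOSIM is implemented here (mid-ranks
for ties, R = (r̄_between − r̄_within)/(M/2), add-one permutation
p-value, 999 permutations by default, seeded) and cross-checked against
scikit-bio's R statistic and an exhaustive n = 6 enumeration. In the
pipeline, ANOSIM groups "actual" versus one prediction method, with the
six sweep replicates as samples — the omnibus layout is left to
configuration since the grouping behind the original analysis is not
fully specified.

## Differential abundance

The minimal faithful core of the common Maaslin2 configuration: TSS to
proportions, arcsin√ transform, per-species OLS on intercept + case
indicator, two-sided t-test on the slope, significance at raw p < 0.05
with *no* multiplicity correction (a q-value option exists but is off to
match the stated protocol). No prevalence or abundance filtering is
applied; real Maaslin2 defaults include filters the protocol statement
does not mention, so results can diverge on sparse data. Constant
responses report p = 1. Agreement between significant sets uses Venn
semantics: FNR = missed reference species / reference count, FDR =
non-reference predictions / predicted count, zero denominators reported
as 0 with a warning.

## Two-group study generator

The study table (default 39 control / 47 case samples, 188 species, 20
planted species, log-effect 1) draws each sample from its group's
Dirichlet. Case concentrations of the planted species are multiplied by
exp(±effect); two deliberate design choices stabilize this:

1. **Closure correction.** Compositions are closed, so inflating some
   species necessarily deflates all others; naively planting effects
   leaks a systematic shift into every null species, which 86 samples
   readily detect. The planted multipliers are therefore rescaled
   (within the planted set only) so the summed concentration is
   unchanged — null species keep identical marginals in both groups, and
   planted effects read as changes relative to the community background.
2. **Balanced signs.** Up/down assignments greedily balance the summed
   concentration of the two halves (then the whole assignment flips with
   probability ½), keeping the closure rescale factor well below the
   effect size so every planted sign survives in the realized group
   means. The effective log-effects are asymmetric (up-regulated species
   get |effect| + ln c with ln c ≈ −0.4): a known, documented
   consequence.

Study concentrations default to Geometric(p = 0.1) (mean 10, per-species
CV ≈ 0.3) — heavier per-sample noise than the community-simulation
profiles, chosen as a realistic stand-in for profiled gut metagenomes.

In the pipeline's study stage, per-marker confusion matrices over the
188 study species cannot come from the (much smaller) classification
benchmark taxonomy; instead a synthetic confusion is built whose
diagonal equals the marker's mean per-species correct rate from the
benchmark, with the residual mass on one random other species per row.

## Problem sizes and numerics

Default pipeline taxonomy is 3 genera × 3 species × 2 genomes with 1–2
operon copies — sized so the quadratic-time alignment classifier over
all five regions finishes in about a minute on one CPU; k-mer-only
configurations scale to much larger collections, and the marker-ordering
check averages k-mer accuracy over 5 seeds at 3 × 4 × 3. Determinism is
end-to-end: every stage derives its RNG from the master seed via
`SeedSequence(master, spawn_key=(stage, substage))`, and identical
configurations produce byte-identical output directories. Floating-point
tie comparisons for classifier scores are exact equality on integral
score values (k-mer counts, ×2/−3/−5/−2 alignment scores), so
tie-breaking is well defined.

## Known limitations

- Uniform i.i.d. divergence makes short markers more informative than in
  real taxa; accuracy magnitudes are not transferable, orderings are.
- Strand handling assumes generator orientation; reverse-strand primer
  search and fragmented operons are out of scope.
- Gapped primer matching is not supported (Hamming only), matching
  integer-percent primer-search semantics.
- The alignment classifier is exact Smith–Waterman, not a seeded
  heuristic; at large reference counts it is the runtime bottleneck.
- Unclassified queries are scored incorrect but excluded from confusion
  rows; with markers shorter than k = 31 this can bias confusion
  diagonals upward.
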