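# Methods

## Sequence model and genetic code

A coding sequence is an ordered tuple of codons for one
(sample, gene, isoform, allele); the frame is enforced at construction
(nucleotide length a multiple of three) and the standard nuclear genetic
code (61 sense codons, 3 stops, 20 synonym families) is taken from
Biopython's table 1. Codons containing ambiguity characters are kept in
the sequence but excluded from every count, with a logged warning; there
is no defensible way to attribute an `N`-containing codon to a synonym
family, and discarding the whole record would waste the clean positions.

## Per-gene metrics

**Frequency and aversion.** Codon frequency is a plain 64-entry tally.
The averted set is the complement of the tally's support — over all 64
codons by default (stop-codon aversion is informative), or over the 61
sense codons on request.

**Pairing.** The ribosome footprint is modelled as `window` consecutive
codons, default 9; two codons can interact iff their position difference
is ≤ `window − 1`. Position *j* counts as an identical-pairing event when
the same codon occurs among the previous `window − 1` positions, and as a
co-tRNA event when a synonymous but different codon does. Counting
*positions with at least one upstream partner* (rather than all pairs or
all windows) keeps each codon's count bounded by its occurrences — a run
of *k* identical codons yields exactly *k − 1* events — and is the
semantics pinned by the brute-force pair-enumeration oracle in the test
suite. Stop codons never pair but still occupy positions (the footprint
is physical). Enlarging the window can only add events, which the
property tests assert.

**RSCU.** `RSCU_c = k·X_c / Σ X_{c'}` within a family of size *k*; every
observed family sums to *k* (mean 1). Families with zero observations are
reported as missing (`nan`), not zero — an unused family carries no usage
information.

**Composition.** Per-base counts over the coding sequence and
GC = (G + C)/(A + C + G + T).

## Ramp detection

Per-codon translational speed is proxied by the codon's RSCU in a
reference table pooled over a user-supplied reference CDS set (for real
data, the longest isoform per gene; the synthetic generator provides one
in tests). The harmonic mean — the natural average of ratios, dominated
by slow codons — is taken over every sliding window (default 9 codons).
A ramp is called when a window mean falls below
`mean − outlier_z · sd` of all window means (default `outlier_z = 2`,
the simplest defensible outlier rule; configurable) *and* that window
starts within `leading_fraction` of the gene (default 0.01, i.e. the
first percentile; for genes where that covers less than one window, at
least the first window is considered). The reported ramp spans the gene
start through the last window of the contiguous outlier run, in
nucleotides (3 × codons). Genes shorter than the window are skipped with
a warning. Detection is invariant to uniform rescaling of speeds, as it
must be for a ratio-based proxy. Stop codons and codons absent from the
reference (undefined or zero RSCU) carry no speed and are dropped from
the profile.

## Population statistics

One-way ANOVA (scipy) per (gene, codon/metric) cell across populations;
Bonferroni thresholds are always `alpha / n_tests` with `n_tests` the
number of tests actually run in that metric family. Pairwise *t*-tests
are Student's pooled-variance by default — consistent with the pooled-sd
Cohen's *d* attached to significant pairs — with Welch behind a flag.
Cohen's *d* with zero pooled variance is reported missing rather than
infinite. Tukey's HSD (studentized range, scipy) serves small test
families such as per-variant minor-allele-frequency comparisons. The
minor allele is defined on the pooled cohort, so a single group's
frequency may exceed 0.5. Note that ANOVA on fully constant data is 0/0
and returns `nan`; groups with identical but non-constant values give
F = 0.

## Population identification

Gene motifs are sorted, duplicate-free codon tuples: codons with at least
one identical-pairing event (pairing mode; sense codons only) or the
averted codons (aversion mode; all 64). A genome's motif set discards
gene names; identical motifs from different genes collapse. Distance is
Jaccard, `1 − |A∩B|/|A∪B|` — the natural set-union-normalised
dissimilarity, exposed as a pluggable function. Only identical pairing
feeds pairing-mode motifs by default; co-tRNA pairing is not included.
Trees come from scikit-bio's Saitou–Nei neighbor-joining (deterministic;
negative branch lengths clamped to zero with a log note). For clade
counting the unrooted tree is midpoint-rooted (configurable), and a
cluster is a maximal clade whose leaves all belong to one population,
counted in a single post-order sweep. Percent predictive accuracy is
`100·(1 − (n_clusters − 1)/n_individuals)`, strictly decreasing in the
cluster count and equal to 100 only for a single clade.

## Synthetic cohorts

The generator emulates populations that differ only in synonymous codon
choice:

- one amino-acid sequence per gene, shared cohort-wide (drawn uniformly
  over the 20 amino acids), so all inter-individual variation is
  synonymous by construction; a shared terminal stop codon per gene;
- per-population synonymous-usage profiles: each family's probability
  vector is Dirichlet-distributed around the uniform base profile with
  concentration `divergence × family_size × base`. The default
  `divergence = 1` is a flat Dirichlet on every family — strongly
  divergent populations; `divergence → ∞` collapses all populations onto
  the base;
- a per-population *consensus* per gene, drawn from the profile through
  common random numbers: one shared uniform per codon position is mapped
  through each profile's inverse family CDF. Populations with identical
  profiles therefore have byte-identical consensus sequences (shared
  ancestry), and consensus sequences diverge exactly where profiles do.
  Marginally each consensus position is still a draw from the profile, so
  observed codon frequencies converge to the generating profile;
- sparse individual variation: each codon is independently resampled from
  the population profile with probability `mutation_rate`, default 0.005
  per codon — the order of per-site polymorphism in real human cohorts.

This hierarchy — population-wide systematic differences, sparse private
ones — is the regime in which motif-set clustering operates on real
genomes. An earlier design that drew every codon independently per
individual was rejected: exact motif tuples then almost never coincide
between any two genomes and all Jaccard distances saturate at 1,
destroying the clustering signal regardless of how divergent the
profiles are, and misrepresenting cohorts whose members differ by
isolated variants.

What the generator does **not** emulate: recombination, linkage,
demography, within-population substructure, isoform variation,
non-uniform amino-acid composition, and selection on codon use beyond
the family profiles. Passing the end-to-end tests therefore shows the
pipeline separates populations whose codon preferences differ
systematically against sparse individual noise — not that real cohorts
at real divergence levels reach any particular accuracy.

`plant_ramp` rewrites the first `slow_prefix` codons (default 9) toward
slow synonyms: each is replaced by the synonym with reference RSCU
closest to `rscu/speed_factor`, restricted to synonyms observed in the
reference (zero-RSCU codons have no defined speed). `speed_factor = 1`
leaves the gene unchanged; large factors select the rarest synonym.
Genotypes for the minor-allele-frequency workflow are Binomial(2, p)
draws with group-specific allele frequencies.

All generators take a mandatory seed and are byte-deterministic.

## Problem sizes in the validation suite

The stochastic validation checks run at fixed scales chosen to give
stable rates: 1,000 null replicates (5 groups × 20) for ANOVA type-I
calibration; exhaustive pairing sequences to length 5 plus 1,000 random
sequences to 30 codons over a 4-codon alphabet against the enumeration
oracle; one 3-population × 40-genome cohort of 50 genes × 300 codons for
end-to-end recovery; 200 replicate genes for ramp detection rates. All
seeds are fixed in the tests.

## Known limitations

- The per-gene CSV column layouts are this package's own convention
  (identifier columns, then fixed lexicographic codon order).
- Haplotype materialization accepts phased biallelic SNVs in CDS
  coordinates only; projecting genomic VCFs onto transcripts is out of
  scope.
- The outlier rule and leading-fraction convention for ramps are
  parameterized choices; other detectors draw the outlier boundary
  differently.
- Cluster counts depend on the rooting of the unrooted NJ tree; midpoint
  rooting is the deterministic default, and counts near the root can
  shift by one under other rootings.
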