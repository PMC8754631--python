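# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, and what the synthetic-data generators
do and do not emulate.

## Sequence composition and competence

A+T fraction is the exact count of A and T residues over the sequence
length; windowed profiles use tiled, non-overlapping windows by default
(step = window), dropping any trailing partial window. Whether published
per-kb profiles use tiled or sliding windows is generally unstated; tiled
is the default here and the step is a free parameter.

Homopolymer runs are maximal stretches of a *single* base (`AAA…` or
`TTT…`); an A-run abutting a T-run counts as two runs. A `mixed=True`
mode reports maximal mixed-A/T tracts instead, for sensitivity analysis.
"Runs longer than 2 bp" translates to a minimum length of 3, the default
everywhere.

The competence classifier encodes the empirical thresholds from
replacement experiments: sequences at or above A+T 0.747 behave like
native centromeric DNA (`active`); between 0.71 and 0.747 centromeres
form but are lost on propagation (`unstable`); below 0.71 there is no
detectable function (`inactive`). A minimum length gate (default
4000 bp) sits between the shortest stable (4.17 kb) and the longest
unstable (3.59 kb) constructs tested experimentally; sequences below it
are `too_short` regardless of composition. The thresholds are a
configuration object validated for monotonicity, and the classifier is
monotone in A+T at fixed adequate length.

Coordinates are 0-based half-open throughout the library; 1-based
conventions appear only at I/O boundaries that require them (none of the
supported formats do — bedGraph and BED are 0-based half-open).

## Candidate design

**Concatemers** are exact tandem arrays with no linker bases: five or
seven copies of an 889 bp unit give 4445 and 6223 bp (the "4.4 kb" and
"6.2 kb" arrays), which is consistent with no inserted linkers.

**Interleaved designs** alternate fixed-length segments from two pools
(A+T-rich CDEII-like 20-mers vs gene-backbone 20-mers at ~0.55), truncated
at the last whole segment so per-segment composition stays exact. With
equal 20 bp segments at 0.94 and 0.55 to 5.9 kb the overall A+T centres
slightly above (0.94+0.55)/2 = 0.745 because the alternation starts and
ends with an A-segment (148 vs 147 segments).

**Deletion markers**: one 4 bp deletion per full 1 kb block, placed
uniformly within ± jitter (default spacing/4) of the block centre, kept
clear of the sequence ends, never overlapping. The `MarkerSet` stores the
removed bases in unmodified coordinates, so applying and reverting is an
exact round trip — the invariant the read-discrimination index relies on.

**Run-targeted mutagenesis** implements two complementary schemes as
general algorithms (the exact historical mutant sequences are not
bundled; seeds make specific instances reproducible):

- `disrupt_runs` breaks every A/T homopolymer longer than `max_run`
  (default 2) by substituting every (max_run+1)-th position within the
  run with G or C — greedy left-to-right, which is the minimal
  substitution count for that guarantee (⌊run/3⌋ substitutions per run at
  the default). Randomness enters only in the G-vs-C choice.
- `reduce_at_preserving_runs` leaves every run longer than `max_run`
  byte-identical and substitutes randomly chosen A/T residues *outside*
  those runs until the composition is within 1/length of the target. An
  unachievable target (below the composition contributed by the preserved
  runs) raises an error that reports the achievable minimum.

## ChIP quantitation

Coverage is plain interval stabbing (depth[i] = number of placements
covering i), so the depth integral equals the total placed read length —
an invariant the tests assert. Alignment is out of scope: the package
consumes placements, either from a minimal TSV dialect
(`reference, start, end[, sequence]`, the canonical test format) or from
text SAM via pysam (primary mapped records only).

Normalisation divides depth by the mean of the read counts over two
reference centromeres, supplied explicitly. Read *counts* (not coverage
means) are used as the normaliser; the factor is retained on the track so
normalisation is invertible.

Read discrimination between an engineered candidate and its near-identical
native counterpart uses junction words: for each deletion marker, the
experimental word spans the deletion junction in the marked sequence
(default 10 bp flank each side, 20 bp total) and the native word is the
corresponding undeleted stretch (24 bp). Index construction verifies the
words are actually discriminating — a junction word occurring in the
*other* variant (possible in repetitive sequence) is rejected at build
time. A read is assigned experimental or native only on consistent
evidence; reads touching no marker, carrying conflicting words, or
shorter than a junction word are ambiguous with a reason code. The
ambiguous class is structurally large at realistic marker densities
(most short reads fall between markers); this mirrors the real
experiment, where only junction-spanning reads are informative. Words are
matched in the given orientation only, which is correct for SAM input
(SEQ is reference-strand) and for the simulator's reads.

The composition–binding regression tiles the candidate into 180 bp
non-overlapping segments (trailing partial dropped, offset 0), takes each
segment's A+T fraction as predictor and its mean normalised depth as
response (per-segment sum available via a flag), and fits OLS with a
two-sided slope test. Whether published versions of such regressions used
normalised or raw coverage, and which tiling offset, is typically
unstated; both are parameters recorded in the result object. With fewer
than three segments the regression is refused. A constant response
returns slope 0, R² 0, p 1 rather than NaN.

## Assay statistics

Recovery efficiency is
`(viable × frac_ura⁻ × frac_swapped)_test / viable_control`. Values above
1 are expected and meaningful: cells still carrying the enlarged
pre-deletion centromere grow more slowly than deletion clones, so
recovered swaps can outnumber the control.

The zero-event bound inverts the binomial zero-success probability
exactly: p* = 1 − (1 − c)^(1/n). It is strictly decreasing in n,
increasing in c, and approaches the Poisson form −ln(1−c)/n for large n.
Trials may be non-integer (continuous extension) because the
mutation-accumulation accounting produces fractional effective counts:
each of `lines` lineages contributes `log2(colony_size)` informative
divisions per streak round — the divisions along the founding lineage of
the colony picked at each round, the only divisions whose outcome is
ascertained by the next round's pick. This accounting (not total colony
divisions) is the one consistent with the ~0.1%-per-division headline
bound at colony size 5×10⁶, 10 rounds, 20 lines: 4450.7 effective
divisions give 0.1034% at 99% confidence.

## Evolutionary scaling

The fit is ordinary least squares of relative centromeric A+T
(centromere minus genome, in percentage points) on log10(genome size in
bp), with slope SE, two-sided t test, R², adjusted R² and F on (1, n−2)
df reported. Percentage points (not fractions) are the natural unit: a
slope near −8 over a ~2.4-decade size range corresponds to ~20 points of
enrichment lost from small fungal to large mammalian genomes, which
matches observed cross-species contrasts; the same relationship in
fractions would have a slope 100× smaller. Log base is configurable
(changing base 10 → e multiplies the slope by ln 10 and leaves R², F and
p unchanged — asserted numerically in the tests). No phylogenetic
correction is applied; the model is deliberately a plain cross-species
OLS, and adding phylogenetically independent contrasts is out of scope.
Clade-restricted fits return an explicit "insufficient species" outcome
below n = 3 instead of raising, since small clades are expected inputs.

## Synthetic data: what it emulates, and what it does not

`gen_sequence` emits DNA at an exact-to-rounding target composition with
controllable run structure: A/T content is laid down in single-base
homopolymer blocks with geometric lengths (mean = `run_intensity`,
default 2.0), separated by G/C gaps distributed multinomially. This lets
tests vary run length and bulk composition independently — the axis the
two mutagenesis schemes separate. It does not emulate dinucleotide
biases, mixed A/T tract statistics of real genomes, or repeat structure;
passing tests show the algorithms behave correctly under controlled run
statistics, not that real centromeres have those statistics.

`gen_chip_experiment` draws read starts with density proportional to a
piecewise-constant fold layout, picks the experimental (marked) or native
variant per read by a mixture weight, and applies i.i.d. substitution
errors. Defaults: 30× depth, 50 bp reads, error rate 0. It does not model
GC bias in library preparation, mapping ambiguity, duplicates or
fragment-length distributions. Because the two variants differ in length,
placements carry a `|experimental` / `|native` reference suffix and
coverage is computed per variant frame.

`gen_species_table` draws log10 genome sizes uniformly over
10⁷–2.5×10⁹ bp (~2.4 decades) and applies a linear law with Gaussian
noise; the defaults (n = 43, slope −7.8, σ = 8.2, genome A+T baseline
50%) put the expected R² near 0.3, i.e. a weak-but-real relationship of
the magnitude seen across real species tables. Centromere A+T is clipped
into [0, 100]; at the defaults clipping is vanishingly rare. Since the
published per-species table is not bundled, the regression is validated
by parameter recovery — 500 synthetic tables at these conditions, checking
slope unbiasedness and 95% CI coverage — rather than by reproducing a
specific printed slope.

`gen_assay_outcome` uses Poisson viable counts with the test-arm mean
chosen so the expected recovery equals the requested truth, and binomial
estimation of the scored fractions (defaults: control 10⁶ cells,
auxotroph/swap fractions 0.9, 1000 scored cells). The estimator ratio has
O(1/λ) bias from the Poisson denominator, negligible at the default
scale.

All generators are pure functions of their parameters; a single seed fans
out via `numpy.random.SeedSequence` into per-component streams, and a
`SimulationTruth` record accompanies every output so regeneration is
bit-identical.

## Numerical and testing choices

- Problem sizes in the test suite (kilobase-scale sequences, tens of
  regression segments, 500-table recovery studies, 10⁴-sequence fuzzing)
  were chosen so the full suite runs in well under a minute while keeping
  Monte-Carlo standard errors small enough for 3-SE assertions; they are
  statements about the algorithms, not about any particular dataset.
- Monte-Carlo assertions use 3 standard errors (or a ±0.03 band for
  95% CI coverage over 500 replicates), giving per-test false-alarm rates
  well below 1% under fixed seeds.
- The statsmodels OLS used by the scaling module is cross-checked in the
  tests against textbook closed-form simple-regression formulas computed
  independently; the zero-event closed form is cross-checked against
  numerical inversion of the binomial zero-success probability to 1e-9.
- Ties in `select_at_windows` rankings break by window start; all seeded
  operations are bit-reproducible for a fixed seed.

## Known limitations

- Marker discrimination searches the forward orientation only and exact
  words only; sequencing errors inside a junction word demote the read to
  ambiguous rather than being error-corrected.
- The recovery-efficiency model multiplies independently estimated
  fractions; it does not propagate their sampling covariance.
- The competence classifier is a threshold rule fitted to a handful of
  experimental compositions; the band edges (0.71, 0.747, 4000 bp) carry
  the granularity of those experiments and are configurable for that
  reason.
- No phylogenetic correction in the scaling fit (see above); clade
  heterogeneity beyond subset refits is not modelled.
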