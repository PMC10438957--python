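# Methods

## Model

Collocation analysis treats two genomic interval sets A and B as subsets
of a genome of G bases and asks how strongly they share bases — a
continuous quantity — rather than how many regions pass an overlap
cutoff. All six statistics are functions of one base-count quadruple
(|A|, |B|, |A∩B|, G), where |·| counts *distinct* bases after merging
overlapping or abutting intervals within a set. The implicit null model
behind PMI/NPMI is uniform placement: if a base belongs to A with
probability p(A) = |A|/G and independently to B with probability
p(B) = |B|/G, the expected shared count is |A|·|B|/G. PMI is the natural
log-ratio of observed to expected joint coverage; NPMI rescales it to
[−1, 1] by dividing by −ln p(A∩B).

Assumptions worth stating: a single genome background G for both sets
(chromosome-name mismatches are errors, not silently dropped); strand is
ignored; every input interval contributes to the base counts whether or
not it overlaps the other set (this differs from tools that compute
Jaccard only over intervals that overlap at all).

## Boundary and degenerate cases

- Either set empty: C = J = SD = SS = 0 by definition; PMI and NPMI are
  reported as NA (NaN) because p(A) = 0 makes the log-ratio meaningless —
  returning 0 would wrongly assert independence.
- Empty intersection: PMI = −inf (rendered `-inf` in reports),
  NPMI = −1 (its limit value).
- p(A∩B) = 1 (both sets cover the whole genome): NPMI's denominator
  −ln 1 = 0; NPMI is defined as 1 there (it is an A = B case), and
  PMI = 0 by the formula.
- All ratios are computed in double precision from exact integer base
  counts; the library never rounds (reports print 6 significant digits).

## Interval algebra

Merging and intersection are numpy sweep-line operations on sorted
start/end arrays: merging collapses intervals whose start does not
exceed the running maximum end (abutting intervals are merged — this
changes interval counts, never base counts); intersection walks two
canonical arrays with two pointers. Intervals extending past their
chromosome are an error by default; an opt-in `clip` mode truncates to
`[0, length)` with a logged warning, because silent clipping hides
genome-version mismatches. The test suite checks these primitives
base-for-base against a literal boolean-mask-per-chromosome oracle on
1,000 random fixtures, and against `bedtools intersect` on one.

## Bootstrap confidence intervals

Defaults: fraction 0.75, 20 replicates, both configurable. Each
replicate independently subsamples ⌊0.75·n⌋ (at least 1) of the *raw*
(pre-merge) intervals of each set, without replacement, and recomputes
the metric. Subsampling both sets is the symmetric choice for a
symmetric statistic.

The primary 95% interval is the normal-approximation bootstrap interval
centered on the full-data point estimate, point ± 1.96·SD(replicates),
clamped to the metric's theoretical range; the 2.5–97.5 percentile
interval of the raw replicates is reported alongside. Centering on the
point estimate rather than the replicate mean is deliberate: retaining
each set at fraction f keeps a shared base only when both copies
survive (≈f²) while the marginals shrink by f, so replicate scores sit
systematically below the full-data score; an interval centered on the
replicate mean would rarely contain the estimate it is meant to
qualify. PMI replicates of −inf (an empty resampled intersection) are
excluded with a logged count; if more than half the replicates are
non-finite the interval is NA. Replicate streams derive from a single
seed via `numpy` `SeedSequence` spawning, so results are bit-reproducible.

## Scan, combined Z, outliers

For a query against a database of n targets, each metric column is
standardized across the n targets: Zᵢ = (x − μ)/σ with the sample SD
(ddof = 1 — with databases as small as n = 3 the denominator choice is
visible, and the sample SD is the honest small-n estimator). −inf PMI
entries cannot be standardized and are treated as NA in that column; a
zero-variance column gets Z = 0 everywhere with a warning. The combined
score is Σ Zᵢ/√k over the k metrics defined for that target (√k keeps
the combination's variance stable as k varies; Σ Zᵢ/k is exposed as an
option, and both orderings are identical since they differ by a positive
factor). Records are ranked by combined Z descending with lexicographic
name tie-breaks; outliers are records whose combined Z is more than 3
sample SDs from the scan mean. A self-match label can be excluded
before standardization, mirroring the usual practice of dropping the
query's own entry from the database.

The threshold-and-count baseline labels each raw query peak overlapped
when its total overlap with the merged target (fragments summed)
reaches the cutoff — 1 nt absolute, or 10/30/50/80/100% of that peak's
own length — and ranks targets by the overlapped proportion. It exists
for comparison: the scan demonstrates, on synthetic data, the known
failure mode where the baseline's top ranks go to targets with the most
peaks rather than the most shared bases.

## Synthetic fixtures

The generators emulate peak files and chrom.sizes inputs without any
download. Placement draws interval lengths (fixed, uniform, or
geometric) and packs them uniformly into free regions with at least one
base of separation, so canonical interval counts equal requested counts;
packing that cannot fit raises rather than silently degrading.

- `generate_pair` plants an exact shared-base fraction: B re-uses
  (copies, trimming the last copy) A's intervals until the target base
  count is met, and places its remaining intervals in the complement of
  A, so the realized fraction it reports is exact and verifiable by
  re-measurement.
- `generate_independent_pair` lays out contiguous blocks on the
  concatenated genome (seed-rotated, split at chromosome boundaries) so
  |A∩B| = |A|·|B|/G exactly; it requires |A|·|B| divisible by G and
  suggests the nearest feasible cardinality otherwise.
- `generate_biased_database` / `demo_scan_scenario` build the
  peak-count-bias scenario: a 10 Mb single-chromosome genome, a query of
  500 × 1 kb peaks, one planted target copying 40% of the query's peaks
  (deep overlap, few peaks), and 19 independent targets with 1 kb peaks
  log-spaced from 20 to 5,000. The sizes were chosen once so that the
  largest independent target covers roughly half the genome — enough
  for ~85% of query peaks to touch it by ≥1 nt, comfortably above the
  planted target's exact 40% — while the planted target's shared-base
  scores dominate every metric column. These are the package's standard
  demonstration conditions, not tunables.

What the generators do *not* emulate: realistic peak-width
distributions, GC- or mappability-dependent placement, clustered or
strand-specific binding, and inter-peak spacing structure of real
ChIP-seq data. Passing tests therefore certify the statistics, the
standardization machinery, and the ranking behavior under controlled
overlap structure — not performance on any particular real antibody or
assay.

## Problem sizes in the test suite

Tests run on genomes of 1 kb–10 Mb with tens to thousands of intervals:
large enough for stable realized fractions, small enough that the
per-base oracle and 1,000-fixture equivalence sweep complete in seconds.
The bootstrap coverage check uses 100 simulated pairs of 120 intervals
each. These sizes are the package's own reproducibility defaults.

## Known limitations

- PMI/NPMI depend on G, so scores are comparable only across analyses
  using the same chrom.sizes background.
- The bootstrap quantifies sampling-of-intervals variability only; it
  has no notion of biological replicates, and with 20 replicates the
  normal approximation is crude by construction.
- Scan standardization uses the scanned database as its population;
  Z-scores from scans over different databases are not comparable.
- No significance testing is attached to pairwise scores (deliberately:
  occurrence-style Fisher/permutation tests are the approach the
  base-level statistics replace).
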