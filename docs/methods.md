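# Methods

## Scope and model

`ascn-assoc` tests whether germline genotype at a risk variant predicts the
cohort frequency of somatic allele-specific copy-number (ASCN) events. Its
input contract is the output of an ASCAT-style caller: per sample, integer
allele-specific copy numbers (nA, nB) at each array probe — already
corrected for normal-cell admixture — plus a sample-level mean ploidy. The
package does not segment, call, or correct raw intensities; everything
upstream of (nA, nB) is out of scope.

The analysis assumes:

* probes are exchangeable units within a sample for the purpose of the
  positional null (see *Recurrence cutoff* for the caveat);
* genotype groups are exchangeable under the no-association null, which is
  what justifies the label-permutation p cutoff;
* events are scored per probe, so segment structure enters only through
  the input profiles.

## Ploidy normalization and the event calculus

Samples with ploidy above `ploidy_cutoff` (default 2.8, dimensionless mean
copies per locus) are classed tetraploid-like — the value sits in the gap
of the empirically bimodal ploidy distribution of glioma cohorts, between
the diploid mode near 2 and the duplicated mode near 4 — and their copy
numbers are divided by two. The boundary value itself is diploid-like.

Halved copy numbers are kept as **exact half-integers** and the eight event
predicates are evaluated literally on them: (3, 1) in a tetraploid-like
sample becomes (1.5, 0.5), which satisfies the copy-number-neutral-event
predicate (nA≠1, nB≠1, nTot=2) but not LOH. Multiples of 0.5 are exactly
representable in binary floating point, so equality comparisons are exact.
An alternative `rounding="nearest"` mode (ties to even) is available but
off by default; literal evaluation is the most faithful reading of
"divide the copy numbers by two". All eight event types, including
homozygous deletion (nTot = 0 survives halving) and amplification (the
threshold 8 applies post-halving), are computed on the rescaled values.

The four base types NORMAL / LOSS / ICN / CNNE partition every non-missing
probe; LOH, HD, AMP and LOH_ICN overlay them (HD ⇒ LOSS ∧ LOH, AMP ⇒ ICN,
LOH_ICN ⇒ LOH ∧ ICN). These invariants are enforced by exhaustive tests
over the half-integer grid.

Missing data are explicit: a probe with missing (nA, nB) is missing in all
eight event matrices, is dropped from every per-probe denominator, and is
never encoded as 0 (0 means a deleted allele).

## Recurrence cutoff

For each event type, the per-probe cohort frequency is compared against a
cutoff derived by permuting genomic positions: in each of `n_perm_freq`
(100) repetitions, every sample's autosomal calls are shuffled uniformly
across autosomal probe positions (conserving that sample's event and
missing counts), per-probe null frequencies are computed, and the
repetition's intermediate cutoff is their empirical `1 − freq_fpr`
(99.5th percentile) quantile; the final cutoff is the mean of the 100
intermediates. X- and Y-chromosome probes are classified but excluded from
the permutation, whose null is only meaningful on autosomes.

Numerical conventions, fixed for reproducibility: empirical quantiles use
linear interpolation (`numpy.quantile` default); "above the cutoff" is a
strict inequality; a missing frequency is never recurrent; an all-false
matrix yields cutoff 0 with a warning.

The uniform shuffle destroys segment correlation, so the null is
optimistic about the number of independent units per sample. A
`method="circular"` variant (random per-sample circular shift, preserving
run lengths) is provided for sensitivity analysis; the shuffle remains the
default because it matches the positional-permutation description of the
procedure this package operationalizes.

## Association testing

Samples split per variant into major-allele homozygotes versus
heterozygotes plus rare homozygotes; the **risk group** is whichever group
carries the risk allele (both orientations occur among the packaged
variants). Unassayed variants fall back to their declared surrogate
marker; surrogate selection from an LD table takes the largest r², with
ties broken by genomic distance and then lexicographic id — the paperless
tie-break exists only to make runs deterministic. Samples with missing
genotype join neither group.

The primitive is the one-sided Fisher's exact test: the upper-tail
hypergeometric probability that the risk group shows at least the observed
event count under fixed margins (computed via `scipy.stats.hypergeom`; an
independent exhaustive-enumeration oracle cross-checks it in the tests for
every table with N ≤ 30). The empty table (N = 0) is defined as p = 1.
Per-probe 2×2 tables drop samples missing at that probe, so group sizes
are per-probe — the only consistent choice with missing data.

The global scan tests only probes where the **risk group's** frequency
exceeds the recurrence cutoff; whole-cohort frequency tracks are exported
for reporting but do not gate the scan.

### Genome-wide p cutoff

For each (variant, event) pair, group labels are reassigned at random
`n_perm_p` (100) times with group sizes fixed; each permutation re-runs
the full scan — recurrence mask recomputed from the permuted risk group
(a fixed-mask variant is available behind a flag) — and stores its minimum
p (1.0 when the permuted mask is empty). The cutoff is placed so that
`p_cutoff_percentile` percent (95) of the stored minima lie **above** it,
i.e. only ~5% of null relabelings produce any probe below the cutoff.
This is the familywise-error reading of the min-p permutation method: on
label-exchangeable synthetic nulls the pipeline calls at least one
significant region in ≈5% of cohorts, which the test suite verifies over
40 seeded runs. (The opposite ordering of the percentile would flag ~95%
of null cohorts, so it cannot be the intended construction.) Significant
regions are maximal runs of consecutive masked probes with p strictly
below the cutoff, never crossing a chromosome boundary.

### Genes-of-interest route and validation

A sample is positive for an event in a region when strictly more than
`goi_fraction` (50%) of its **non-missing** probes in the 1-based
inclusive interval are positive; a sample with no covered probe is
missing. Each (gene, event, variant) table is tested at `goi_alpha`
(0.05). No multiple-testing correction is applied in discovery — by
design, the error control is the independent validation cohort, exactly
as in the two-stage design this package implements; users screening many
variants should keep that in mind.

Validation re-tests every shortlisted row — including regions found by
the global route — with the gene-level method on an independent cohort
(disjoint sample ids are enforced). Regions with fewer than
`min_validation_probes` (3) probes on the validation manifest are marked
untestable rather than negative.

## The synthetic-data generator

`simulate_cohort` emulates the caller's output contract, not the caller:

* genotypes: Hardy–Weinberg draws at a configurable MAF, or exact group
  sizes with the het/rare-hom split at conditional Hardy–Weinberg odds;
* ploidy: a bimodal mixture — diploid-like baseline (1,1) with ploidy
  ~N(2.05, 0.15) clipped to (1.7, 2.8], tetraploid-like baseline (2,2)
  with ploidy ~N(3.7, 0.3) clipped to (2.9, 4.6);
* background aberrations: Poisson-per-sample segments (rate per Mb, mean
  length exponential) with a weighted (nA, nB)-state mixture dominated by
  hemizygous loss, single-copy gain and copy-neutral LOH;
* planted events: whole-region (nA, nB) overwrites with per-group
  probabilities, recorded in a truth table. Planted states are defined on
  the diploid scale and doubled for tetraploid-like samples, so a
  homozygous deletion is (0,0) at any ploidy. An optional `co_occur`
  parameter correlates the first two loci through a shared latent uniform;
  the default is independent planting.

Defaults mirror the published study conditions: 81 discovery samples
(285 for validation-style cohorts), a ~60/21 major-homozygous split
(MAF 0.14), 23% tetraploid-like, planted EGFR-LOH and CDKN2A/B-HD effects
at the published per-group frequencies, and a reduced genome (chr7, chr9,
chrX) at 100 kb probe spacing with extra probes densified inside planted
loci, emulating the gene-centric density of genotyping arrays. The
desk-scale genome and probe counts are the package's own choice of
problem size; the statistical structure, not the physical scale, is what
the tests exercise.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: raw LRR/BAF noise and ASCAT's inference errors,
LD between the risk variant and other markers, realistic breakpoint
clustering and recurrent-lesion landscapes, subtype structure, and
batch/array effects. Calibration results on synthetic nulls demonstrate
the correctness of the permutation constructions, not field performance.

## Problem sizes in tests and the acceptance script

Calibration checks run at 80 samples × ~5,000 probes (40 seeds) for the
null positive rate, and 81/285-sample cohorts at ~900 probes (25 seeds)
for planted-effect recovery; the null-calibration background uses a
heavier aberration rate (0.15 segments/Mb, LOH as the scored event) so the
min-p distribution is quasi-continuous, as it is genome-wide on real
arrays — with sparse discrete events the 95%-of-minima construction is
degenerate and no percentile placement is meaningful. These sizes are the
package's standard validation configuration.

## Known limitations

* Probe-level testing inflates the number of nominally independent tests
  within a CNV segment; the run-based region reporting mitigates but does
  not model this.
* The positional-permutation null ignores segmental correlation (see the
  circular-shift alternative).
* The gene-level >50% rule is sensitive to probe placement in small
  regions with few probes.
* Table coordinates for the packaged gene regions are shipped verbatim in
  the genome build of the source arrays (hg18-era); no liftover is
  attempted, and manifests must use a compatible build.
* One p cutoff is computed per (variant, event) pair; cutoffs are not
  shared or pooled across events.
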