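# Methods

This note documents the models, conventions and numerical choices behind
`bldm`, and what the synthetic test-bed does and does not establish.

## Coordinates and file dialects

All coordinates are 0-based half-open (BED convention); a CpG is located by
the forward-strand position of its C. Read-level haplotypes use an
mHap-style 6-column TSV (chrom, start, end, 0/1 pattern, count, strand),
optionally gzipped, one file per sample. Reads aligned to the reverse strand
are assumed already projected onto forward-strand CpG coordinates by the
upstream methylation extractor; the strand column is carried but ignored by
every measurement. Missing metadata is an empty field, never a sentinel
number; exported matrices encode missing values as the literal token `NA`.

## Block calling

Methylation LD between two CpGs is the squared Pearson correlation (φ²) of
the two binary state vectors over the reads covering both sites, weighted by
read multiplicity. An estimate is *flagged undefined* — never coerced to
0 — when fewer than `min_pairs` reads cover the pair or either site is
constant; an undefined pair conservatively breaks a block.

Calling proceeds per candidate run (maximal stretches of consecutive CpGs
≤ `max_gap_bp` apart with at least one jointly covering read, since RRBS
coverage is patchy): within a run, maximal stretches whose every
*consecutive* pair has defined r² ≥ `r2_min` are emitted when they hold at
least `min_cpgs` CpGs. Defaults: `r2_min = 0.5`, `min_cpgs = 3`,
`min_pairs = 10`, `max_gap_bp = 200` — conventional values for
methylation-LD block calling; all exposed. Consecutive-pair r² (not
all-pairs) with greedy left-to-right extension was chosen for determinism
and O(L) behaviour; a brute-force maximal-sub-run oracle in the test suite
confirms the greedy result is the exhaustive one. Blocks are called on
pooled discovery reads only and then frozen for all downstream cohorts.

Note that tightening `r2_min` can *increase* the number of blocks (one long
block may split into two qualifying halves); what is monotone is the total
number of CpGs inside called blocks, and that is the property tested.

## The six measurements

Substrings are enumerated within reads only and only over the CpGs a read
actually covers — haplotype load measures observed co-methylation, never
imputed states. For MHL/UMHL the weight is w_l = l; MHL3/UMHL3 use w_l = l³.
The cubic exponent is this package's reading of "a different weight": it is
configurable (`weight_exponent`) and recorded in output metadata, so an
alternative convention is one flag away. The normaliser sums weights over
exactly the substring lengths observed at least once.

PDR eligibility requires a read to cover ≥ 3 block CpGs (configurable); with
blocks of ≥ 3 CpGs this matches the classical read-floor idea while
remaining defined for clipped reads. Coverage is the mean per-CpG read depth
over the block's CpGs ("X" units), not the raw read count — the 10–500X
filter is interpreted in those units.

MHL ≤ AMF is *not* generally true and is not asserted; for single-CpG blocks
AMF = MHL = 1 − UMHL, which is tested.

## Marker funnel

Screening uses the two-sided Mann–Whitney U test on observed values
(pairwise deletion), exact when both groups have ≤ 8 observations without
ties, otherwise the tie-corrected normal approximation with continuity
correction; completely tied data give p = 1. Per block the lowest-p
measurement is chosen, with exact p ties broken by the fixed precedence AMF,
MHL, UMHL, MHL3, UMHL3, PDR for determinism. The p < 0.001 gate is a raw
(uncorrected) screen by design. Because the six measurements of one block
are strongly dependent, the min-p construction does not have a nominal
per-block level; the null-calibration tests therefore exercise the screen on
a single measurement, where the pass rate must match α.

Imputation happens after screening, on the screened matrix, via KNN over
samples (k = 5, masked Euclidean distances, uniform mean of neighbours).
Held-out samples are imputed strictly one at a time against the pooled raw
discovery rows, so they never inform each other.

RFECV eliminates one marker per step, scoring candidate sizes by 10-fold
stratified CV AUC (accuracy available via `scoring`), ties resolved toward
the smaller set. The elimination-loop estimator is a 100-tree balanced
random forest: importance *ranking* is stable well below the final model's
500 trees, and the loop dominates runtime otherwise; both counts are
configurable. Screened and final marker counts are data-dependent and are
validated on planted synthetic truth, not on fixed counts.

## Classifier, cutoff, evaluation

Markers are z-scored with the discovery mean and *population* SD (ddof = 0,
recorded in the fitted state). The forest (500 trees, √p features,
class-balanced) is tuned over a small exposed grid by 10-fold stratified CV
and refit on all discovery samples.

The decision cutoff is the mean of the held-out Youden-optimal thresholds
over 3 repetitions of stratified 5-fold CV, with the full pipeline
(imputation, standardization, forest) refit inside each fold. "Averaging
the Youden index" is interpreted as averaging the per-fold optimal
*thresholds*; the index itself is unit-free and cannot serve as a cutoff.
The call rule is score ≥ t → malignant (boundary positive). Threshold
candidates are midpoints of adjacent distinct scores plus both boundary
rules, with J ties compared in exact integer arithmetic
(tp·n_neg + tn·n_pos) and resolved toward the smallest threshold.

AUC uses the rank-statistic (Mann–Whitney) formulation with midrank ties —
identical to the trapezoidal ROC area — and a stratified bootstrap
percentile CI (2,000 resamples, seeded; classes resampled separately).
Diagnostic percentages are computed at full precision and rounded to two
decimals only for presentation; empty denominators are flagged undefined,
never reported as 0.

The ultrasonography comparator counts ACR TI-RADS ≥ 4 as test-positive
(consistent with a triage framework that sends TR 4–5 to blood testing;
configurable). The micronodule boundary is ≤ 10 mm inclusive. The
reference operating characteristics of the original clinical cohorts
(e.g. a 0.51 probability cutoff, AUC ≈ 0.86) depend on patient data that is
not publicly deposited; they are reference values only and nothing in this
package claims to reproduce them.

Sample size: n = ⌈z²·P(1−P)/d²⌉ with z = Φ⁻¹(1 − (1−α)/2); boundary
P ∈ {0, 1} yields n = 0.

## Synthetic cohorts

The generator's defaults are the study conditions used throughout the
tests: three-phase cohort sizes 59+49 / 55+42 / 53+35, 200 blocks of 3–6
CpGs, 30 differential blocks, effect Δ = 0.2 on the linear probability
scale (logit option available) with direction chosen to stay inside [0, 1],
per-block Beta-distributed sample means (concentration 20), negative-
binomial depth (mean 30X, size 5, clipped at 500X), 5% whole-block dropout,
20% of reads clipped to a contiguous sub-range, and within-read Markov
concordance c = 0.8 (each CpG copies its left neighbour with probability c,
else resamples Bernoulli(p)). The Markov mechanism is the simplest that
yields bimodal block-like haplotypes as c → 1 and noisy reads as c → 0.
TI-RADS is drawn conditional on the true label with high sensitivity and
moderate specificity, and nodule sizes are log-normal with malignant
nodules somewhat smaller — these exist to exercise subgroup reporting and
encode no claim about real ultrasonography. Presets: `paper_shaped`
(Δ = 0.2), `easy` (Δ = 0.3), `hard` (Δ = 0.1 at 10X), `null` (no planted
effect).

What the generator does *not* emulate: sequencing error and bisulfite
non-conversion, leukocyte cell-type composition shifts, batch effects,
genome-wide block-size and coverage distributions, or correlations between
neighbouring blocks. Passing the synthetic-recovery suite therefore shows
the pipeline's machinery is correct and well-calibrated under its stated
assumptions — not that comparable performance would be achieved on real
cohorts.

Problem sizes in the tests and the acceptance script (200 blocks, the
three-phase cohort sizes, 5,000 null screen columns, 500 oracle blocks) are
the package's chosen desk-scale conditions; the genome-wide analysis the
design emulates would run the identical code on ~10⁴–10⁵ blocks.

## Known limitations

- Block calling fixes one reading of methylation-LD blocks
  (consecutive-pair r², greedy maximal extension); D′-based or all-pairs
  definitions are out of scope.
- The screen's min-p-over-measurements construction is intentionally
  uncorrected; its family-wise behaviour across six dependent measurements
  is characterised only empirically.
- `ModelBundle` serialization uses joblib pickling; bundles are an internal
  persistence format, not an interchange format, and round-trip bit-stable
  scores are enforced by test.
- The clinical-management pathway downstream of the score (who proceeds to
  biopsy) is documented prose, not executable logic.
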