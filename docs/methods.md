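# Methods

## Quantification model

Per subject, mean tracer activity is taken over regions of interest covering
six cortical target regions (frontal, occipital, parietal, lateral temporal,
anterior and posterior cingulate) and four reference structures. SUVR is the
ratio of target to reference activity; the whole-cerebellum reference
activity is the **unweighted** mean of cerebellar gray- and white-matter
activity (no volume weighting is assumed; the run manifest records this
choice). The composite SUVR is the unweighted arithmetic mean of the six
cortical SUVRs and is missing whenever any constituent region is missing.
SUVRs can also enter the pipeline precomputed; each record carries a
`source` field saying which path produced it.

**Positivity rule.** A scan is positive iff SUVR ≥ cutoff. The inclusive
boundary is forced by the reconstructed validation data at two-decimal
precision: one subject sits exactly at the pons cutoff (0.78) and is scored
a true positive, while another sits one hundredth below the cerebellar-gray
cutoff (1.42 vs 1.43) and is scored a false negative. Comparisons happen at
the precision the inputs were supplied in; nothing is re-rounded before
classification. Subjects missing the SUVR for one reference region are
excluded from that region's analyses only, not globally.

## Visual assessment model

Each reader scores four cortical regions (lateral temporal, frontal,
parietal, posterior cingulate/precuneus) on the 3-level regional cortical
tracer uptake scale (1 no uptake, 2 moderate, 3 pronounced). The whole-brain
amyloid plaque load score is driven by the most affected region: any region
at 3 → 3, else any region at 2 → 2, else 1; the scan is visually negative
iff the whole-brain score is 1, and a region is negative iff its regional
score is 1. The max-based derivation is a reconstruction of the published
score definitions; it is isolated in one function (`rctu_to_bapl`) so a
site using a different convention can swap it.

Readers are aggregated by strict majority. An even split is reported as
*indeterminate* with both tallies — never broken by a casting rule — since
the study design (odd panels, or 8 readers with no observed draw) makes
draws exceptional and worth surfacing. Reader skill (expert vs naive) is
metadata only; it never changes the aggregation.

## Histopathology model

Neuritic amyloid is *present* in a region when either stain (Bielschowsky
silver or immunohistochemistry) grades it moderate/frequent, *absent* when
every available stain grades it none/sparse; a single missing stain does not
block classification, both missing gives an indeterminate region. Only the
two regions that are also visually assessed (frontal, posterior cingulate)
are considered. Subject-level positivity uses an any-positive-region rule by
default — the source protocol names the considered regions but not the
aggregation, so the rule is a parameter (`rule="any"|"all"`).

## Cutpoint estimation

Candidate thresholds are the sorted unique observed scores plus a +inf
sentinel; under the ≥ rule the smallest observed score is the
sensitivity-1/specificity-0 corner and the sentinel the opposite corner. At
each threshold, sensitivity is the fraction of truth-positives at or above
it and specificity the fraction of truth-negatives below it. The selected
cutoff maximizes Youden's *J*; ties are broken toward higher specificity,
then the smallest threshold — deterministic output, and a preference for
specific operating points in a screening-confirmation setting. Both choices
are arguments of `CutpointModel.fit`. A midpoint-candidate variant
(`candidates="midpoint"`) gives identical operating points with thresholds
strictly between classes; observed-score candidates are the default because
the selected cutoff is then itself an observed SUVR.

AUC is the trapezoid rule over the empirical curve traversed in
descending-threshold order, which equals the Mann-Whitney probability with
half credit for score ties (checked against an O(n²) pairwise oracle).

Truth conventions mirror the two-stage design: composite cutoffs are
generated against the scan-level (whole-brain) visual classification,
regional cutoffs against the per-region visual classification. Regions are
processed independently; no information crosses reference or target regions.

## Uncertainty and comparisons

All proportions carry exact two-sided Clopper–Pearson intervals from beta
quantiles: lower = Beta_{α/2}(x, n−x+1) for x>0 else 0, upper =
Beta_{1−α/2}(x+1, n−x) for x<n else 1. Accuracy, sensitivity and
specificity differences between classifiers are tested with a Pearson
chi-squared on the 2×2 correct/incorrect table, df 1, **no continuity
correction**, treating the classifiers as independent samples (the variant
is a package choice; the source analysis does not state one — its printed
χ² = 5.36 for the SWM-vs-majority comparison reconstructs as 5.35 under
this variant, a documented near-miss that is reported, not forced).
Families of pairwise tests are corrected with Bonferroni–Holm, applied
within each metric family; significance is declared at α = 0.05. Report
percentages are rounded half-up to integers; underlying counts and
full-precision proportions are always emitted alongside.

## Reconstructed validation cohort

The packaged 78-subject cohort consists of the 20 published misclassified
subjects (composite SUVRs for four reference regions, histopathology,
visual majority result, reader vote split; one subject's subcortical-white
SUVR is unavailable) plus 45 synthetic concordant pathology-positive
subjects and 13 synthetic concordant pathology-negative subjects. The 53/25
pathology split is a **derived constant**, not printed data: it is the
unique pair of binomial denominators simultaneously consistent with every
published composite sensitivity/specificity interval and with the error
counts in the 20-subject listing (e.g. 49/53 → 92% (82–98) and
24/25 → 96% (80–100)). Padding SUVRs are deterministic linspaces strictly
above (positives) or below (negatives) every composite cutoff, with visual
votes 8–0; padded rows are flagged `synthetic=True`.

Two published numbers are *not* exactly recoverable from this
reconstruction and are reported as computed: the SWM-vs-visual-majority
agreement comes out 66/77 = 86% against a printed 85% (the printed value may
include the subject whose SWM SUVR is missing, 66/78 = 85%), and the
χ² = 5.36 reconstructs as 5.35 (see above).

## Synthetic cohort generator

The generator emulates the study structure, not its images. Per subject, a
latent amyloid status is drawn at the configured prevalence (default 0.5,
matching a roughly balanced patient/control cutoff-generation cohort of
n = 143; the validation preset uses n = 78 at prevalence 53/78 with 3 expert
plus 5 naive readers). The composite SUVR on the cerebellar-gray scale is
class-conditional Gaussian — negative N(1.20, 0.10), positive N(1.75, 0.20),
values in SUVR units — chosen (no distributions are published) so the
Youden-optimal boundary sits near 1.43 and recovery tests are meaningful.
Other reference-region scales are fixed multiples of the cerebellar-gray
scale (ratios of the published cutoffs: 0.96/1.43, 0.78/1.43, 0.71/1.43),
so one latent burden drives all four scales and cross-region
classifications correlate, as in real data. The six regional SUVRs are the
latent composite plus Gaussian jitter (sd 0.06); the stored composite is
their exact mean.

Readers miscode a region's score with a base probability (expert 0.02,
naive 0.10) inflated fourfold (capped at 0.49) inside a ±0.10 borderline
zone around the boundary. Pathology scores are concordant with the latent
status except for diffuse-plaque discordance draws (validation preset 0.05):
a latent-positive subject keeps its positive-like SUVR but its neuritic
stains read none/sparse — the mechanism behind scan-positive,
pathology-negative cases. Stain-level missingness is a separate rate. A
fixed seed yields bit-identical tables.

What the generator does **not** model: atrophy and vascular lesions (their
effects enter only through SUVR noise and the discordance rate), site or
scanner effects, per-region heterogeneity of amyloid burden, and reader
correlation beyond the shared truth. Passing tests on synthetic cohorts
therefore demonstrate correctness of the estimators under the stated
generative assumptions, not performance on real scans; the `noise_free`
configuration additionally clamps each class to its own side of the
boundary so end-to-end perfect-agreement checks are exact by construction.

## Problem sizes and numerical choices

Tests and the acceptance script use the study-scale sizes throughout:
143-subject cohorts for cutoff generation (100 repeated seeds for the
boundary-recovery median), the 78-subject reconstructed cohort for
validation, 10,000 binomial draws for interval-coverage checks. Youden-tie
comparisons use an absolute tolerance of 1e-12 on *J*; SUVRs are clipped
below at physically positive floors in the generator (0.30 composite, 0.20
regional). Degenerate inputs: single-class truth raises a named error;
zero-denominator proportions raise rather than returning NaN; an even
reader split or a doubly-missing pathology region propagates as
indeterminate and is excluded-and-counted by every downstream tally.

## Known limitations

The reconstruction pins only composite SUVRs; published regional-cutoff
performance rows cannot be re-derived from shipped data and are not
claimed. The per-reader agreement figures of the source study require
per-reader reads that are not public; the pipeline computes them whenever a
reads table is supplied. The cutpoint carries no confidence interval (none
is published to compare against, and bootstrap CIs are out of scope).
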