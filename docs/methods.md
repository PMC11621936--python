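# Methods

`phosphodyn` implements a dynamic phospho-proteogenomic analysis of drug
response in cancer cell-line panels, of the kind used to dissect resistance
to DNA-damaging chemotherapy (5-fluorouracil, cisplatin, etoposide) in
gastric cancer models: reverse-phase protein array (RPPA) quantification,
GI50/AUC-based sensitivity calls, kinetic classification of drug-induced
protein time courses, copy-number association, correlation screens, and
marker-stratified survival analysis. Because the cell-line and cohort data
such studies rest on are deposited or restricted, every stage is exercised
against a synthetic-data generator that plants known ground truth; this
note records the models, the defaults and why, and what the synthetic
validation does and does not establish.

## RPPA quantification

An RPPA slide carries one antibody over thousands of printed dots. The
modelled design is 12 drug-dose conditions (4 drugs x low/medium/high) x 5
time points x 8 cell lines, spotted in tetraplicate, plus 80 control MIX
and buffer dots — 2000 dots per slide.

*Replicate aggregation* is the median after MAD-based outlier exclusion: a
replicate farther than `3.5 x 1.4826 x MAD` from the replicate median is
dropped (rule skipped when all replicates are equal). The median/MAD pair
is the standard robust choice for tetraplicates, where a single bad spot
otherwise dominates a mean. When the MAD is zero with unequal values, only
replicates equal to the median survive.

*Normalization* divides each antibody by its aggregated control MIX level
(removing antibody-specific staining scale) and then median-centers each
sample in log space (removing per-sample loading and staining factors).
Output is strictly positive, invariant to per-antibody global rescaling,
and preserves within-sample rank order. Published RPPA pipelines differ in
this step; the scheme here is deliberately simple, auditable, and isolated
behind one function so an alternative can be swapped in.

*Time courses* are assembled per (cell line, drug, dose) series and
antibody as log2 fold change against the series' own t = 0 sample (the
design samples baseline per condition, so vehicle subtraction is not
needed); `log2fc = 0` at t = 0 by construction, and series lacking a
baseline sample are skipped with a report. 96 series x 202 antibodies gives
the reference bookkeeping count of 19,392 courses.

## Dose response

GI50 is read from the measured viability curve by log-linear interpolation
at the first downward crossing of 50% — the pharmacological convention and
robust at the 3–9 doses per drug typical of these panels; a full 4PL fit
adds parameters the data cannot constrain (the generator owns the 4PL).
Curves that never reach 50% are right-censored at the top dose (maximally
resistant in-range); curves below 50% everywhere are left-censored at the
lowest dose (maximally sensitive). AUC is the trapezoidal integral of the
viability fraction over log10 dose normalized by the log-dose span, so it
lies in [0, 1] and is comparable across drugs with different dose ranges.

Sensitive/resistant segregation sorts log10 GI50 (right-censored at +inf)
and splits at the largest adjacent gap, the lower block being sensitive.
The published practice is segregation by inspection of the GI50 profile; a
reproducible rule is required here, and the largest gap is its natural
formalization. A `threshold` override (log10 GI50 cut) is provided. An
infinite gap to a censored block always dominates, so finite lines stay
sensitive whenever right-censored lines exist.

## Kinetic classification

Drug-induced protein time courses fall into four classes by peak timing:
early (peaked by 6 h), intermediate (by 12 h), late (by 24 h), and no
response (flat). Classification is two-step: K-means with k = 7 (default)
on |log2FC| feature vectors, then each cluster centroid is mapped to a
class and the label propagated to members. Absolute fold change is used
because the classes are about timing, not direction; direction is kept as
metadata. A per-course "direct" mode applies the peak-time rule to each
course and is intended for clean or noiseless data only.

The centroid-to-class map calls a course flat when its post-baseline
|log2FC| profile has no distinguished peak, by either of two tests:

* absolute range below `flat_threshold` (default 0.25 log2 units — about
  a 20% change, the smallest movement worth calling a response on arrays
  whose replicate noise is of that order);
* peak below `peak_contrast` (default 3) times the profile's own floor.

Two tests are needed because rectified features have a positive noise
floor, `E|N(0, sigma)| ~ 0.8 sigma`, shared by all time points: the range
test cancels a uniform floor, and the contrast test catches noise clusters
that K-means has carved out by dominant coordinate — their centroids show
a fake peak with a scale-free peak/floor ratio of about
`E[max of 4 half-normals] / E[non-max] ~ 2.6`, while genuine single-peak
archetypes at workable noise sit at 5 or more. Ties in peak time go to the
earliest point (the "peaked by" reading). The rules reproduce all the
obvious hand cases, e.g. `(0, 1.2, 0.4, 0.1, 0.0) -> early` and
`(0, 0.1, 0.1, 0.0, 0.1) -> none` at threshold 0.25.

Group contrasts ("protein dynamics depletion") collapse classes to
responsive (early + intermediate + late) versus none and use a two-sided
Fisher exact test, pooling courses across antibodies and cell lines within
each arm. Pooling treats courses as exchangeable units; a per-line
stratified variant would treat cell lines as units and is deliberately not
the default.

## Exact test engines

The Fisher engine is the fixed-margin hypergeometric two-sided test (sum of
probabilities of tables no more probable than the observed one), delegated
to `scipy.stats.fisher_exact`, with p = 1 by convention for a zero margin.
The Mann-Whitney engine (CNV locus-count contrasts) enumerates all rank
splits for combined n <= 12 — exact under ties, two-sided as twice the
smaller tail capped at 1 — and uses the tie-corrected normal approximation
with continuity correction beyond. Both are checked against independent
oracles in the test suite (own hypergeometric enumeration; scipy's
permutation machinery).

Exactness has a visible cost: the null distribution of an exact Fisher p is
discrete and conservative. With two balanced arms of 200 courses the
symmetric null puts an atom of ~0.11 at p = 1, so the null p is *not*
uniform in the Kolmogorov-Smirnov sense at that design size; what holds,
and what the suite asserts, is conservative calibration, P(p <= a) <= a.

## Copy-number analysis

Profiles are SEG-style integer segments, 1-based inclusive, on a diploid
baseline; loss is copy <= 1 and gain >= 3 (both are flags, since loss
calling conventions vary). ΔCNV between a resistant line and its matched
parental line is the piecewise difference on the union of breakpoints,
with chromosomes absent from one profile imputed diploid (warned). "CNV
loci" are events: adjacent qualifying segments merge, making counts
invariant to splitting a segment into equal-copy pieces. Shared-loss
analysis tests each gene's binary loss indicator against a two-group label
with the Fisher engine; per-line locus counts are contrasted with the
Mann-Whitney engine; gene copy number versus AUC uses Pearson correlation.

## Correlation screens

Pearson r with the two-sided t-test p (n − 2 df) throughout. Antibodies
are ranked by r against log10 GI50 across the panel (GI50 spans orders of
magnitude, so the log scale is the right linearization; censored lines are
excluded with a warning) or against an anchor phosphoprotein across all
samples, on log2 intensities. Rankings are by r, as is conventional for
these screens; a Benjamini-Hochberg q column is attached as auxiliary
information only, and constant antibody columns are dropped.

## Survival analysis

Markers are dichotomized at the cohort median with ties going to the
negative group (a fixed, documented policy — the convention matters for
reproducibility and nothing else). Kaplan-Meier curves carry Greenwood
variance; "5-year" read-outs evaluate the step function at 60 months.
Two-group comparisons use the log-rank test; treatment effects are
unadjusted univariable Cox proportional-hazards ratios with Wald 95%
intervals and Efron tie handling (calendar-month follow-up times are
heavily tied; note that Efron handling makes estimates only asymptotically
invariant to duplicating records). Monotone likelihood (separation) is
flagged and the interval reported as unbounded rather than trusted. The
subgroup analysis fits the arm effect within each marker stratum; the
hazard screen median-splits each gene and reports per-gene HRs sorted
ascending. Estimation is delegated to lifelines behind this module's
surface.

## Synthetic-data generator

All randomness flows from one root seed through named substreams (one per
generator), so generators are independently reproducible and adding one
does not perturb the others. Defaults, chosen once as realistic study
conditions:

| parameter | default | rationale |
|---|---|---|
| time grid | 0, 3, 6, 12, 24 h | five points over 24 h; 6/12/24 must be grid members to express the class windows; 3 h is the interior early point |
| drugs x doses | 4 x {low, medium, high} | the 12-condition slide design |
| cell lines, replicates | 8, 4 | the slide design |
| control spots | 80 | the slide design |
| class mix | early .20, intermediate .15, late .15, none .50 | most courses do not respond to any one perturbation |
| amplitude | 2.0 log2 | a 4-fold peak change, a strong phospho response |
| course noise sd | 0.3 log2 | replicate-aggregated RPPA log2FC noise; tetraplicate aggregation of ~15–25% spot CVs leaves ~0.2–0.35 |
| spot noise | multiplicative log-normal, sd = course noise | intensities are positive with scanner dynamic range |
| outliers | rate 0.01, x10 spikes | occasional gross spotting errors |
| cohort baseline hazard | ln 2 / 36 per month | 36-month median survival, advanced-stage mix |
| censoring | exp(0.008/month) + 120-month cut-off | ~30% censored |

Time-course archetypes are single-peak Gaussian bumps in log time,
`A exp(-(ln t - ln t_peak)^2 / (2 x 0.5^2))` with peak at 3 or 6 h (early),
12 h (intermediate) or 24 h (late), randomly signed, with i.i.d. Gaussian
noise at post-baseline points; flat courses are zero-mean noise. Any
single-peak family respecting the argmax windows would do. The spot-table
generator composes per-antibody baselines, per-sample staining factors and
the same archetype responses; the control MIX pool is modelled as tracking
each antibody's pre-treatment abundance (geometric mean of the t = 0
sample levels), which is what makes control normalization an exact round
trip in the noiseless limit. Viability curves are 4-parameter logistic
(top 100, bottom 0, Hill 1) so viability is exactly 50% at the planted
GI50. CNV profiles are diploid with a planted copy-1 region confined to
one group and sporadic background gains/losses. Cohorts draw exponential
event times with stratum-specific hazard ratios in the treated arm and
independent exponential censoring.

### What the synthetic validation shows — and does not

Passing tests establish that the estimators recover what the generator
plants at realistic noise: per-class kinetic recall >= 0.9 (measured
~0.99) at amplitude/noise ~6.7; GI50 exactly on noiseless curves and with
median |Δlog10| < 0.1 under 5% viability noise; a planted hazard ratio of
0.46 at n = 2000 recovered within [0.40, 0.53] in >~98% of runs with ~95%
CI coverage and nominal log-rank type-I error. They do not establish
performance on real arrays: the generator has no antibody
cross-reactivity, no slide-to-slide batch effects, no correlated noise
across time points (baseline-sharing induces such correlation in real
log2FC), no dose-dependent amplitude, and cohorts have exponential,
proportional hazards by construction. A note on the flat class: when the
amplitude-to-noise ratio falls to 4, a flat course with one noise
excursion beyond A/2 becomes likelihood-indistinguishable from a weak
responder (the union probability is ~17% across 4 post-baseline points),
so no classifier can keep flat recall above ~0.9 there; the class windows
are only meaningfully recoverable from ratio ~5 upward.

## Numerical choices and degenerate inputs

* Seeds: every stochastic routine takes an explicit seed; substreams are
  derived by CRC-hashing the generator name into a `SeedSequence` spawn
  key.
* K-means: best of 10 random restarts (scikit-learn, k-means++), fixed
  `random_state`; `k` larger than the number of courses is an error.
* GI50: exact 50% at a measured dose returns that dose; non-monotone
  curves resolve to the first crossing.
* Fisher/Mann-Whitney: zero-margin tables give p = 1; identical multisets
  give p = 1; two-sided p is capped at 1.
* Cox: |log HR| > 10 is treated as separation, flagged, CI (0, inf).
* Median split: values equal to the median are negative; an all-equal
  vector warns and returns all-negative.
* Aggregation: a single replicate is returned unchanged; empty input is an
  error.
* Pipeline TSVs are written at 10 significant digits; reruns with the same
  config and seed are byte-identical.

## Known limitations

The normalization is a deliberate simplification of published RPPA
protocols (pluggable, but only one scheme ships). The dynamics Fisher
contrasts pool courses, ignoring within-cell-line correlation, so their p
values are anti-conservative for cell-line-level claims. Dose-time
interactions are only represented as stratified proportions. Survival
modelling is univariable by design — no adjustment, no proportionality
diagnostics, no time-varying covariates. Problem sizes in the test suite
and acceptance script (4,032 courses for recall, 100–500 replicate
simulations, n = 2000 cohorts) were chosen as the smallest that make the
binomial assertion bands sharp; all scale linearly if enlarged.
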