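# Methods

## Setting and data model

The package operates on sample × metabolite tables of relative peak areas
(RPA): GC/MS peak intensities normalized per sample to the ribitol
internal standard, whose own intensity is thereby 1. The study design it
targets has three groups — healthy controls (n = 25), depressed patients
with early-life stress (ELS/MDD, n = 23) and without (non-ELS/MDD,
n = 23) — and four two-group comparisons: healthy vs all MDD (the pooled
patient union), healthy vs each subtype, and ELS/MDD vs non-ELS/MDD. The
pooled "MDD" group is always formed by union of the two subtype labels,
never stored as a label of its own.

All upstream spectral processing (S/N ≥ 10 peak filtering, deconvolution,
library identification, retention-time alignment) is assumed done by the
instrument software; the pipeline begins at the aligned intensity table.

## RPA normalization

Each sample's row is divided by that sample's internal-standard peak
(per-sample division, the standard internal-standard practice, since the
standard is spiked into every sample). The operation is equivariant to
rescaling a whole row and preserves non-negativity; a non-positive
internal-standard peak is an error naming the sample.

## PLS-DA and VIP

PLS-DA is PLS1: the response is the 0/1 group indicator, centered; the
metabolite matrix is column-wise mean-centered and unit-variance scaled
(UV scaling, the metabonomics default, which also makes VIP scale-free).
Components are extracted by NIPALS with sequential deflation
(deterministic initialization from the response; convergence when the
weight vector changes by < 1e-10, at most 500 iterations — for a
single-column response the update is a fixed point after one pass). The
default is A = 2 components, matching the two-dimensional score plots
conventional in the field; if the residual is exhausted earlier the model
truncates with a warning. Per component the captured response sum of
squares is SSY_a = q_a²·t_aᵀt_a.

VIP follows the standard weight-based form

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),

normalized so Σ_j VIP_j² = p. Differential metabolites are those with
VIP *strictly* greater than 1.0 (a VIP printed as exactly 1 does not
pass), returned in descending VIP order; an empty selection returns no
panel rather than an empty one.

Open design point: published VIP values could have come from one model or
four; this package fits one PLS-DA per comparison.

## Nested logistic panels and ROC

The differential panel's top-k prefixes (k = 1…k_max, default 9) are each
fitted by logistic regression and scored by ROC AUC on the fitted data.
Because strong panels separate the groups completely — where unpenalized
maximum likelihood diverges — the fit carries a small L2 penalty
(λ = 1e-4 on the slopes, none on the intercept; scikit-learn's
`LogisticRegression` with C = 1/λ). The penalty shrinks coefficients
monotonically and cannot change the score ranking, so AUC is unaffected.
AUC is the trapezoidal area under the ROC curve, identical to the
Mann–Whitney pairwise concordance with ties counted half. The best panel
is the highest-AUC one; ties prefer fewer metabolites, since a diagnosis
on fewer assays is cheaper.

## The Tclass system

### Base learners

*Fisher linear discriminant classification functions*: per-class affine
scores g_k(x) = μ_kᵀΣ⁻¹x − ½μ_kᵀΣ⁻¹μ_k + ln π_k with pooled within-class
covariance Σ and equal priors (the cohorts are near-balanced by design).
Σ is ridge-stabilized as Σ + λ·(tr Σ/p)·I with λ = 1e-6, escalating ×10
up to 1e-2 before erroring — forward selection can propose collinear
panels. The two scores are exactly the published per-class "C"/"MDD"
equations, and the packaged example classifier is stored in this form.

*Gaussian naive Bayes*: per-class per-feature mean and variance (sample
variance, floored at 1e-9 × the feature's overall variance, with a 1e-12
absolute floor), equal priors, classification by the larger log-posterior.

Score ties always resolve to the control (first) label — conservative
toward non-case calls.

### Forward selection under LOOCV

Greedy search: starting from the empty panel, each step adds the
metabolite maximizing the leave-one-out cross-validated accuracy of the
augmented panel, ties breaking to the lower catalog index; the search
stops at k_max metabolites (default 10) or as soon as accuracy reaches 1.
The chosen panel is the smallest prefix attaining the maximum accuracy
seen. LOOCV folds that leave a class very small go through the same
ridge/variance-floor path as any fit; no fold is skipped.

Selection optimizes LOOCV on the full cohort — selection sits outside the
folds, so the selected panel's LOOCV accuracy is optimistic. That bias is
deliberate (it is the procedure being modeled); its mitigation is the
stability index below, always reported alongside.

### Stability index and ensemble

The cohort is split 1000 times into random stratified 85 %/15 %
train/test partitions (per-class test size max(1, round(0.15·n_class));
splits are drawn on a canonical sample-id-sorted ordering, so results are
invariant to row order). Each split trains a classifier on the 85 % and
scores accuracy on the 15 %; the stability index is the mean of the 1000
test accuracies. The same seeded split stream also defines the ensemble:
classifier i is the one trained on split i's training part. A new sample's
P is the fraction of the 1000 classifiers voting the case label; the case
is called iff P > 0.5 *strictly* (exactly 500 of 1000 votes is a control
call). At prediction time truth is unknown, so P is defined as the
case-vote fraction — the only computable quantity.

When no learner is specified the `auto` path runs forward selection with
both learners and keeps the higher chosen-panel LOOCV accuracy, ties
broken by the higher stability index.

### Hierarchical subtype prediction

Four ensembles (healthy vs MDD, healthy vs each subtype, ELS vs non-ELS)
combine into a two-stage call: the MDD screen first; if negative, the
subtype is NOT_APPLICABLE. If positive, ELS/MDD is called only when both
the healthy-vs-ELS and the ELS-vs-non-ELS ensembles vote ELS/MDD, and
symmetrically for non-ELS/MDD. Any other pattern — including all subtype
models voting "healthy" after a positive screen, a case the agreement
rule leaves undefined — is surfaced as INDETERMINATE rather than forced,
with all four component P values reported for audit.

## Synthetic cohorts

The generator draws each metabolite independently from a Gaussian with
the reference catalog's per-group mean and SD (`table2` mode), at the
study's group sizes by default. Distributions are *untruncated* by
default so generated moments match the catalog exactly; several
metabolites (e.g. sorbitol, healthy mean 0.0175 ± SD 0.0335) would take a
large truncation bias otherwise. The `nonneg` option resamples negative
cells (rejection at zero) for workflows needing physical RPAs, at the
documented cost of biased moments for such metabolites. Two calibration
modes exist: `null` draws all groups from the healthy parameters (no
signal; pipelines should score at chance), and `separated` spaces group
means 10 pooled SDs apart per metabolite (pipelines should be perfect).
One catalog oddity is kept verbatim: mannose's non-ELS SD is stored as
printed (0.2214) although it is ~5× the other groups' and may be a
misprint.

What the generator does **not** emulate: between-metabolite correlation
(only marginal moments are published), non-Gaussian shape, batch or drift
effects, and missingness/limit-of-detection. Passing calibration tests
therefore shows the statistical machinery is correct and well-calibrated
under independent Gaussian marginals with the published effect sizes —
not that the published clinical accuracies would replicate on real
plasma, whose per-sample data are not public.

## Problem sizes and numerical choices

Stability analyses and ensembles default to 1000 splits (about one second
at n = 48 on one core); a few broad calibration sweeps in the test suite
use 100–200 splits per seed, which estimates the stability index to ±~0.01
and is ample for band checks. Monte-Carlo moment checks use n = 1e5 draws
(3-standard-error bands). Serialization stores floats at full precision;
table round trips are lossless to well below 1e-12. Fixed seeds flow
through `numpy.random.default_rng` only; identical configurations are
bitwise reproducible.

## Known limitations

- Independence of metabolites in the generator understates the
  collinearity real panels face; forward selection on real data may
  behave differently around correlated features.
- The LOOCV objective's optimism is reported, not removed; no nested
  cross-validation variant is provided (deliberately, to model the
  procedure as practiced).
- No confidence intervals on AUC or the stability index; no permutation
  testing of PLS-DA models; no O-PLS variants.
- The printed example classifier is published in linear-discriminant form
  although its panel was introduced as the naive-Bayes winner; the
  package stores it as the affine pair it is printed as and treats the
  variant spelling "glyceic acid" as the catalog's glyceric acid, its
  closest entry.
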