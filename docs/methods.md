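# Methods

## Overview

`mirbayes` implements the computational chain of a circulating-miRNA
biomarker study in dementia: processing of capture/scramble qPCR miRNome
panels into per-miRNA enrichment calls, plasma ΔCt quantification with
hemolysis quality control and group statistics, single-marker ROC analysis,
and a two-class Gaussian Bayes classifier over a grid-searched linear
combination of three marker ΔCt values. A synthetic-data module generates
cohorts and panels with the statistical structure the analysis assumes, so
the whole chain is testable without access to patient data.

## Panel enrichment chain

Input is a long-format table of plate-level Ct values (sample, miRNA,
plate, Ct, detected flag) for capture and scramble pull-down replicates,
with UniSp3 inter-plate calibrator (IPC) spike-in wells on every plate.
The stages, in order:

1. **Inter-plate calibration.** Each plate's additive factor is the grand
   mean of per-plate IPC means minus that plate's IPC mean; all detected
   Cts on the plate are shifted by it. This makes the final results
   invariant to per-plate constant offsets (verified by a property test).
2. **Imputation.** Undetected wells become Ct = 40 (the cycle ceiling),
   flagged as imputed.
3. **Detection filter.** miRNAs genuinely detected in fewer than 66% of
   wells (capture and scramble pooled) are removed. A per-sample
   completeness variant is available behind `per_sample=True`; the
   per-miRNA reading is the default because the downstream unit of
   analysis is the miRNA.
4. **Global-mean normalization.** ΔCt(miRNA) = Ct(miRNA) − mean Ct of all
   retained miRNAs in that sample; per-sample ΔCt means are exactly zero.
5. **ΔΔCt and test.** ΔΔCt = mean ΔCt(capture) − mean ΔCt(scramble), fold
   change FC = 2^−ΔΔCt, p-value from a two-sided Welch t-test on the
   per-replicate ΔCt values. *Enriched* ⇔ FC > 1 and p ≤ α (default 0.05,
   uncorrected; a Benjamini–Hochberg option exists but is off by default
   because enrichment screens of this kind are conventionally reported at
   nominal α and confirmed by single assays). Identical fold changes are
   obtained as the ratio of per-arm geometric means of 2^−ΔCt; a test
   checks the two routes agree to 1e−10.

Degenerate contrasts (zero variance in both arms) get p = 1 when the
means agree and p = 0 with a warning flag otherwise.

## Plasma quantification

ΔCt = Ct(target) − Ct(miR-93a-5p endogenous control); relative expression
is 2^−ΔCt, so lower ΔCt means higher expression. Hemolysis is screened by
the miR-23a-3p / miR-451a contrast: a sample fails when
Ct(miR-23a-3p) − Ct(miR-451a) ≥ 7.0 cycles (the conventional cutoff for
this indicator pair; the boundary value fails, and the threshold is
configurable). Failed or unevaluable samples are excluded before
statistics unless overridden.

Two-group contrasts use a t-test (Welch by default — group variances on
the expression scale differ strongly between diagnostic groups; a pooled
option exists), three groups use one-way ANOVA with Bonferroni-adjusted
pairwise post-hocs, correlations use Pearson. Group summaries (mean ± SEM)
are emitted on both the ΔCt and the 2^−ΔCt scale; tests default to the
2^−ΔCt scale on which the group contrasts of interest are defined.
Bonferroni correction applies to the three pairwise comparisons within one
miRNA, not across miRNAs.

## The Bayes classifier

Each subject is scored with

    Score = ΔCt_92a + a · ΔCt_320a + b · ΔCt_320b

and the scores of the two diagnostic classes are modelled as
N(μ₀, σ₀²) and N(μ₁, σ₁²) with priors π₀, π₁ (empirical class proportions
by default; equal priors optional). Classification assigns the class with
the larger prior-weighted density, so the decision boundary solves
π₀·φ(x; μ₀, σ₀) = π₁·φ(x; μ₁, σ₁):

- equal σ: a single threshold, (μ₀+μ₁)/2 − σ²·ln(π₀/π₁)/(μ₀−μ₁) — exactly
  the midpoint under equal priors;
- unequal σ: a quadratic with up to two real roots; the decision regions
  follow the sign pattern of the quadratic. With no real root one class is
  never predicted and the accuracy degenerates to that class's prior.

Accuracy is the prior-weighted probability of correct classification,
computed in closed form from normal CDFs:
acc = π₀·P(region₀ | class 0) + π₁·P(region₁ | class 1). With
Bayes-optimal regions this is never below max(π₀, π₁), hence never below
0.5. Validation uses three independent oracles: quadrature of
∫ max(π₀φ₀, π₁φ₁) (agreement ≤ 1e−6; adaptive quadrature loses a few
1e−7 at the density-crossing kink), 10⁶-draw Monte-Carlo classification
(agreement ≤ 0.002 over 100 random models), and the equal-variance closed
form Φ(Δ/2σ).

**Grid search.** Both coefficients sweep [−50, 50] in steps of 0.1
(1001² ≈ 1.002 million combinations). Because the score is linear, each
grid point's class means and variances follow from the per-class mean
vectors and covariance matrices (μ_c = wᵀm_c, σ_c² = wᵀS_c w with
w = (1, a, b) and unbiased S_c), so the whole grid is evaluated with
array arithmetic — the full sweep on ~120 subjects takes seconds — and is
exactly equivalent to refitting per point (checked against a brute-force
oracle). Ties on accuracy are broken by smallest ‖(a, b)‖, then
lexicographically; accuracies within 1e−12 are treated as tied, since
algebraically identical grid points (e.g. when a marker is constant)
differ by ulp-level float noise. Grid points with numerically constant
class scores are rejected.

Reported per optimum: coefficients, per-class Gaussian fit,
threshold(s), analytic accuracy with a binomial standard error
√(acc(1−acc)/n) (a within-class bootstrap SE is available), empirical
sensitivity of the disease class under the analytic decision regions, and
per-class Shapiro–Wilk normality results for the optimal score
(delegated to the standard implementation, cross-checked against an
independent reference to 1e−6).

**ROC.** Single-marker ROC curves are computed over all empirical
thresholds; the trapezoidal AUC is identical (to 1e−10, tested on 1000
random tie-containing datasets) to the Mann–Whitney estimate U/(n₀n₁),
and the AUC p-value comes from the two-sided Mann–Whitney U test (exact
when n₀n₁ ≤ 400 and tie-free, normal approximation otherwise). Score
orientation is auto-selected so AUC ≥ 0.5 and recorded. "Best accuracy"
(maximum over empirical thresholds, with sensitivity at that threshold)
and the classifier's analytic accuracy are distinct quantities and are
labelled as such in outputs.

The in-sample accuracy of a grid-searched combination is optimistically
biased at small n; the acceptance suite measures this optimism at the
study scale (~40 subjects per class: about +0.004 on a true accuracy of
0.85, versus +0.0007 at 500 per class). No cross-validation machinery is
provided — the design fits on the full cohort — so reported accuracies
should be read as in-sample.

## Synthetic data

**Cohort.** ΔCt is the Gaussian variable; 2^−ΔCt is therefore lognormal,
matching the classifier's normality assumption on ΔCt-based scores. Group
parameters are calibrated from expression-scale (mean, SEM) pairs by the
lognormal moment inversion σ² = ln(1 + s²/m²)/ln²2,
μ = (−ln m + σ²ln²2/2)/ln 2, with SEM·√n recovering the between-subject
SD. Defaults emulate the study cohort: 43 HC (18M/25F), 42 FTD (14M/28F;
17 bvFTD 9M/8F, 17 svFTD 4M/13F), 33 AD (14M/19F); age/onset/MMSE drawn
per group from the published mean ± SD (MMSE clipped to [0, 30]); marker
levels per group from the published 2^−ΔCt means ± SEM. The HC level of
miR-320a is not printed for the whole population (the marker does not
separate patients from controls), so 1.20 — between the two patient-group
means — stands in for it. Raw Cts are reconstructed as a reference Ct
(nominal 25 ± 0.25 cycles, recorded in the spec so reconstruction is
reproducible) plus ΔCt. Hemolysed subjects (default rate 0.05) get their
miR-451a Ct lowered until the indicator gap exceeds the QC threshold by
5 cycles (configurable).

**Panels.** 752 miRNAs, 3 capture + 3 scramble samples, two plates per
sample, IPC wells with per-plate offsets (N(0, 0.5) cycles by default, or
fixed). A fraction of miRNAs (default 272/752) has template at all; the
rest never amplify, so the 66% filter leaves a measurable count emulating
the study's 272-of-752. Detected wells get replicate noise (SD 0.1
cycles); dropout probability rises logistically with true Ct (midpoint 37,
scale 1), and Ct > 40 is always undetected. Spiked (enriched) miRNAs have
their capture-side Ct lowered by the configured shift and are drawn from
the abundant range Ct 22–28: truly captured miRNAs sit well above the
detection limit, and a dropout imputed at Ct 40 would otherwise wreck the
three-replicate Welch test for reasons unrelated to the chain under test.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: amplification-efficiency differences between
assays, correlated markers within subject (markers are drawn
independently given the group), sex-specific marker effects (group-level
only, though sex metadata supports stratified analyses), batch effects
beyond per-plate additive offsets, non-Gaussian ΔCt tails, and any
relation between marker levels and covariates (correlation analyses on
synthetic cohorts are null by construction).

## Problem sizes used in validation

Acceptance-level checks run at: 100 random models × 10⁶ Monte-Carlo draws
(analytic-accuracy oracle); 1000 random ROC datasets (AUC identity);
full 1001² grids on 120–1000 subjects (grid oracle, recovery); 100 seeds
at 500/class and 40/class (recovery bias and optimism); 20 seeds of
752-miRNA panels with 25 three-cycle spikes (spike recovery and
specificity); 200 cohort simulations at the study's group sizes (power of
the miR-320b contrast).

## Known limitations

- Accuracy and sensitivity are in-sample; no train/test split.
- The analytic accuracy is exact only under the two-Gaussian model; the
  Shapiro–Wilk results are reported precisely so users can judge it.
- The Welch test on n = 3 panel replicates is fragile when an imputed
  Ct-40 well inflates a within-arm variance; this is a property of the
  imputation convention, not of the implementation.
- Empirical priors make the analytic accuracy depend on the cohort's
  class balance; use `priors="equal"` for balance-free comparisons.
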