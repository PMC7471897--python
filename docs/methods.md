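# Methods

`ssnod` re-implements, as a tested pipeline, a 3-class invasiveness analysis
for subsolid lung nodules on CT: H1 (pre-invasive: atypical adenomatous
hyperplasia / adenocarcinoma in situ) < H2 (minimally invasive
adenocarcinoma) < H3 (invasive adenocarcinoma). Because no nodule-level
dataset is publicly deposited, every stage is exercised on synthetic cohorts
whose generators are first-class, tested code.

## Synthetic cohorts

**Mechanistic generator** (`cohort.generate_mechanistic_cohort`). Each
nodule is an axis-aligned digital ellipsoid with max/min axis ratio drawn
uniformly in [1.2, 1.9] (the interquartile range of reported diameter
ratios). Volumes are lognormal around class-specific medians
1362 / 1297 / 3436 mm^3 with a log10 SD of 0.46, matching the reported
volume(log) spread of 3.4 +/- 0.49. In-mask HU values come from a
two-component mixture: ground-glass N(-700, 60^2) HU and solid
N(-100, 80^2) HU, truncated to the CT window [-1024, 400]. The solid
*volume* fraction is drawn per nodule from a class-specific interval —
H1 (0, 0.17), H2 (0.10, 0.35), H3 (0.25, 0.65) — chosen so the implied
class mean HU, -700 + 600 x (midpoint fraction), tracks the reported class
means of about -649 / -569 / -432 HU. The solid component occupies the
voxels nearest the centroid; the measured solid diameter is the
equivalent-sphere diameter of the solid subvolume (0 for non-solid
nodules). A bivariate-normal copula couples volume and solid fraction with
correlation 0.3, the reported (modest) volume–attenuation association.
One RNG stream per cohort, seeded once, gives bitwise reproducibility.

What the generator does *not* emulate: CT texture, scanner noise,
reconstruction-kernel effects, irregular lesion shapes, or segmentation
error. Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed generative structure, not clinical performance
on real nodules; the real-data cross-validated AUCs are not reproducible
from synthetic data and are not claimed.

**Proportional-odds generator** (`cohort.generate_po_cohort`). Labels are
drawn directly from P(Y <= j | x) = expit(alpha_j - x.beta) with known
coefficients and Gaussian predictors. It is the ground-truth oracle for
parameter recovery, deviance-test calibration, and cross-validation
envelope checks.

## Feature extraction

First-order attenuation features (mean, SD, skewness, non-excess kurtosis,
Q.50, Q.75, Q.875, IQR) are sample moments and order statistics of the
in-mask HU values. Conventions, since the source workstation's rules are
unpublished:

* quantiles: linear interpolation between order statistics at
  p(k) = (k-1)/(n-1) (numpy default). This pairing is what makes median
  volume 2242 mm^3 consistent with volume(log) ~ 3.4 under log10.
* kurtosis: non-excess (normal = 3), consistent with reported per-class
  kurtosis values sitting around 3.
* max diameter: largest pairwise 3-D distance between in-mask voxel
  centers; min diameter: smallest extent of the PCA-aligned bounding box,
  floored at one voxel spacing (a degenerate-mask guard). Both are
  validated against analytic ellipsoids to within one voxel diagonal.
* histogram-only inputs are supported by expanding (bin_left, count) pairs
  at bin midpoints; geometric quantities then come from scalar sidecars.

## Density curves and functional PCA

Per-nodule histograms are smoothed by a Gaussian kernel (Silverman's rule
bandwidth by default) on a 1-HU grid covering the data range padded by 4
bandwidths and clipped to [-1024, 400]; restricting the grid to the
(padded) support keeps the subsequent log-quantile-density values O(1) at
the ends of the unit interval. The density is floored at 1e-6 per HU and
renormalised to integrate to 1 (trapezoid rule), which keeps the transform
finite; the floor's effect on scores is < 1e-3.

The log-quantile-density (LQD) transform maps each density to
psi(t) = -log f(Q(t)) on a common 101-point grid over [0, 1], where Q is
the quantile function obtained by numerically inverting the trapezoid CDF.
This places all curves in an unconstrained function space where ordinary
functional PCA is valid. FPCA discretises the sample covariance operator
with trapezoid quadrature weights and takes the symmetric eigendecomposition;
eigenfunctions are orthonormal under the quadrature inner product and
scores are quadrature inner products of centred curves with the
eigenfunctions. Eigenfunction signs are arbitrary; each is flipped so its
score vector correlates positively with a per-curve anchor (Q.875 in the
pipeline; fallback: positive integral over t in [0.75, 1]), pinning the
clinical reading "high FPC1 = heterogeneous, high-attenuation curve".
K = 2 components are retained by default. The basis is fit once on the
whole cohort; cross-validation keeps it fixed per fold (the curve ensemble
is treated as a cohort-level construction), with centring refit per fold.

## Feature screening

Univariate screening computes, per feature and per ordinal cutoff
(1: H1 vs H2-or-H3; 2: H1-or-H2 vs H3), the tie-corrected Mann–Whitney
AUC, a DeLong placement-variance CI, and the Youden-optimal threshold
searched over midpoints of consecutive distinct scores (ties resolve to
the higher-sensitivity threshold). Features failing the DeLong z-test of
AUC > 0.5 at P < 0.001 are flagged excluded. Orientation is automatic:
features that discriminate downward are reported as "<= t" rules with the
flipped AUC.

The confounder plot uses absolute Spearman correlation as the similarity
measure — to the ordinal class rank on one axis and to the reference
predictor (volume(log)) on the other. Rank correlation handles mixed
scales and is invariant to monotone transforms; the "recommended" set
(above the median response similarity, below the median reference
similarity) is a documented heuristic, not a published rule.

## Ordinal regression

The core model is the cumulative-logit proportional-odds model
P(Y <= j | x) = expit(alpha_j - x.beta) with one shared slope vector and
J-1 = 2 intercepts, so exp(beta_k) is the cutoff-free odds ratio of more
invasive disease per unit of feature k. Features are centred at training
means (centres stored, folded back at prediction). Estimation is
Newton–Raphson on the exact log-likelihood with analytic gradient and
Hessian, step-halving on likelihood decrease or invalid probabilities,
convergence at max |score| < 1e-8. Predictors are standardised to unit
variance internally (estimates and covariance mapped back) so the Newton
system stays well conditioned when feature scales differ by orders of
magnitude (HU vs log-volume); if the line search stalls at the floating-
point resolution of the log-likelihood — near-separated resamples — a
Newton decrement below 1e-8 (the remaining attainable likelihood gain,
which is scale-invariant) also counts as converged. The covariance is the
inverse observed information and Wald statistics use a 1.96 multiplier
for 95% intervals.
Slopes exceeding |beta| > 30 with a non-vanishing gradient raise an
explicit separation error. With two classes the model reduces exactly to
binary logistic regression (verified against statsmodels).

**Proportional-odds assessment.** Two complementary diagnostics:
(a) per-cutoff binary logistic slopes with a pooled-SE z for their
difference (Brant-style); (b) observed vs model-implied class-conditional
feature means (ordinality check). The formal test is a genuine nested
likelihood-ratio test: the unconstrained cumulative-logit model with
separate slopes per cutoff is fit by multinomial MLE (Newton, initialised
from the PO fit, step-halving keeps all sample probabilities positive) and
chi2 = deviance(PO) - deviance(unconstrained) is referred to chi-square
with df = p. Summing two independent binary-logit deviances was rejected
as the comparator because the binary cumulative-split Bernoulli
likelihoods do not add up to the 3-class multinomial likelihood, so their
deviance gap is not chi-square distributed; the nested LRT's simulated
null rejection rate at alpha = 0.05 is ~0.04–0.07.

**Effect interpretation.** Quartile class-probability changes are computed
by simulation: parameter vectors are drawn from N(estimates, covariance)
(Cholesky), class probabilities are evaluated with the predictor of
interest at its cohort Q3 vs Q1 and the other predictor held at its
cohort mean, and the per-class change is summarised by its mean, 2.5/97.5
percentile interval, and the two-sided simulation p-value
2 min(Pr(delta > 0), Pr(delta < 0)). Default 1000 draws (no draw count is
prescribed by the source analysis); holding the other predictor at the
mean is this package's documented conditioning choice.

**Comparators.** Per-cutoff binary logistic pairs (two 2-class fits whose
cumulative probabilities are differenced, clipped, and renormalised) and
3-class LDA with pooled within-class covariance (denominator n - J) and
empirical priors.

## Cross-validated performance

Monte-Carlo cross-validation: 200 repeats of stratified 80/20 splitting
(per-class test size = round-half-up of 20%, minimum 1), refit on train
(centres recomputed per fold), evaluate on test. Cutoff-1 metrics score
P(H2) + P(H3) against Y >= H2; cutoff-2 metrics score P(H3) against
Y = H3. Metrics: Mann–Whitney AUC; the scaled Brier score
100 x (1 - Brier/Brier_max) with Brier_max = prevalence x (1 - prevalence)
(0% = non-informative, 100% = perfect); and EAVG, the mean absolute gap
between predictions and a lowess-smoothed (span 2/3, 0 robustifying
iterations — appropriate for binary outcomes) observed-frequency curve.
Repeats whose test outcome is single-class at a cutoff are excluded from
that metric's summary and counted, never imputed. Summaries are the mean
and linearly interpolated 2.5/97.5 percentiles across repeats. All
randomness flows from the single config seed, making whole CV loops
byte-reproducible.

## Numerical choices and degenerate inputs

* zero-variance HU samples are rejected by the smoother (callers may add
  +/-0.5 HU jitter);
* identical LQD curves yield zero eigenvalues, zero scores, and zero
  variance fractions (a numerical floor prevents eps-level eigenvalues
  from being promoted to fractions);
* constant features get similarity 0 with a warning; degenerate constant
  predictions fall back to |prevalence - p| for EAVG with a warning;
* separation in a diagnostic sub-fit is reported per cutoff instead of
  aborting the diagnostic report.

## Problem sizes

Simulation-based checks use: 50 seeds x n = 5000 for parameter recovery,
200 cohorts x n = 500 for deviance-test calibration, n = 500 curves for
planted-mode FPCA recovery, and a 227-nodule mechanistic cohort with
200-repeat cross-validation for the end-to-end runs — sizes at which the
targeted asymptotic behaviours (coverage, test calibration, variance
fractions) are already stable.

## Known limitations

The synthetic cohort is more separable than real cohorts (clean two-
component mixtures, exact segmentations), so its cross-validated AUCs
(~0.93–0.97) sit above the 0.83–0.87 range expected on clinical data; on
the synthetic cohort the Q.875 model can also genuinely violate
proportional odds, which the deviance test duly reports. Partial
proportional-odds models, non-linear comparators (SVM, kNN, random
forests, naive Bayes), Wasserstein density PCA, and automated
solid-component segmentation are out of scope.
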