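# Methods

## The model

`trajmix` implements a parallel-process latent class growth analysis (LCGA)
for two parent-rated symptom domains — inattention (IA) and
hyperactivity-impulsivity (HI), each on a 0–30 scale — observed over seven
age bins (≤9, 10–11, 12–13, 14–15, 16–17, 18–19, ≥20 years) in a
cross-sequential cohort: participants enter at different ages and are
re-assessed at calendar offsets of 0/+4/+6/+10 years, so no single
participant covers the full span but the bins overlap strongly across
participants.

Participant *i* in latent class *k* has expected score in domain *d* at bin
*t*

    mu_dtk = i_dk + lambda_dt * s_dk,

with free loadings `lambda_dt` estimated from the data subject to
`lambda_d0 = 0` and `lambda_d,T-1 = 1`.  Under this identification the
intercept `i_dk` is the expected first-bin score and the slope `s_dk` the
total first-to-last change, while the interior loadings give the common
(class-independent) shape of change, allowing non-linear mean courses.  As
in any LCGA, within-class growth-factor variance is fixed to zero; both
domains share one class variable, which is what lets classes differ in the
*joint* course of the two domains.  Residuals are Gaussian with a free
variance per (domain, bin), independent across bins and between domains
given class.  That diagonal structure makes full-information maximum
likelihood a product over each participant's observed cells: missing cells
(unvisited bins) simply drop out, with no listwise deletion.

Loadings and residual variances are shared across classes by default — the
conventional free-time-scores LCGA parameterization; `ModelSpec` flags allow
class-specific versions of either.  The default 7-class model on 7 bins has
`(K-1) + 2·2K + 2·(T-2) + 2·T = 58` free parameters.

## Estimation

EM with conditional M-steps (ECM).  Given posteriors, one sweep updates, in
order: mixture weights; per-(domain, class) growth factors by weighted
generalized least squares of observed cells on `(1, lambda_dt)` with weights
`posterior / sigma2_dt`; the interior loadings pooling all classes; and the
residual variances.  Each block maximizes the expected complete-data
log-likelihood given the others, so the observed log-likelihood never
decreases — asserted at every iteration, with any decrease beyond 1e-8
raised as an internal error rather than tolerated.  Convergence is an
absolute log-likelihood change below 1e-6 (max 500 iterations).

Starts: each random start partitions per-participant profile features
(observed mean and crude first-to-last change per domain, standardized,
jittered with SD 0.3 Gaussian noise) by a short k-means run, then turns the
hard partition into parameters with one ECM sweep.  A two-stage multi-start
— `n_initial` starts run for 20 iterations, the best `n_final` run to
convergence — guards against local maxima; the sorted final log-likelihoods
are retained so replication of the maximum can be inspected.  Starts whose
smallest class falls below 1/(2N) are discarded and redrawn.  The desk-scale
default budget is 100/20 starts; at that budget the maximum is replicated by
many final starts on cohorts of the default size, and fitting K=7 to N≈1064
takes well under a minute on one core.  Classes are reported in descending
inattention severity (intercept + slope × mean loading), with ties broken on
HI severity; for K=7 the seven canonical trajectory labels are attached by
minimum-distance matching of growth factors to the archetype profiles.

## Class enumeration

For each candidate K the table reports log-likelihood, AIC, BIC,
sample-size-adjusted BIC (`aBIC`, with n* = (n+2)/24), relative entropy
(1 − normalized posterior Shannon entropy), the smallest mixture weight and
the smallest class size in modally assigned participants.  Candidate fits
are taken from the multi-start finalists; within each K the reported fit is
the best *admissible* one — smallest assigned class ≥ 20 participants — so a
duplicate-class local maximum (a component attracting no assigned members)
cannot mask a structured solution of the same order.  Beyond the random
starts, each K is also warm-started from the converged K−1 solution by
splitting every class in two, the standard device that keeps the order
search on the structured branch.

The default reported selection is the BIC minimizer among admissible
converged fits — a reproducible proxy for the
fit-statistics-plus-clinical-relevance judgement such studies apply; the
table, not the verdict, is the primary output.  BIC is preferred over aBIC
as the default because its heavier penalty is the standard consistent
choice for mixture order selection; in simulation the aBIC margin between
the generating order and one extra class is comparable to its own penalty
difference, so aBIC resolves the order essentially at random whenever the
residual distribution deviates even mildly from Gaussian near the scale
bounds.  Natural logarithms throughout.

## Three-step covariate analysis

Covariate–class associations use the classify–analyze route with an explicit
classification-error correction: (1) the growth mixture is fitted without
covariates; (2) each participant is assigned to the modal class and the
error matrix `D[s,k] = P(assigned s | true k)` is estimated from the
posteriors; (3) class membership is regressed on one covariate at a time,
age-adjusted and grand-mean centred, by maximizing

    sum_i log sum_k P(C=k | x_i; beta) · D[W_i, k]

with D held fixed — the maximum-likelihood three-step correction, chosen
over BCH-style weighting for numerical stability with seven classes.
Standard errors are a cluster-robust sandwich over family ids, the
fixed-effect reading of "multilevel" for sibling-clustered data: the
estimand is the same fixed-effect odds ratio, and a random-intercept
multinomial model is deliberately out of scope.  Coefficients are bounded at
±15; fits hitting the bound are flagged as separated (this occurs naturally
for near-deterministic covariates such as lifetime diagnosis, and mirrors
the extremely wide intervals those variables produce in practice).  The four
pre-specified contrasts compare classes with similar childhood severity but
diverging course; contrast odds ratios are `exp(beta_a − beta_b)` with
delta-method intervals, and no multiple-testing adjustment is applied.

## Missing covariates

Covariates are imputed by chained equations: Bayesian linear-regression
draws for continuous columns (variance from a scaled inverse chi-square,
coefficients from their normal posterior, predictive noise, clipped to the
scale range) and logistic draws for binary columns, sweeping columns in
fixed table order with 10 burn-in sweeps.  Polygenic scores are excluded
from imputation and analyzed on complete cases, with any configured
ancestry-adjustment covariates added.  Per-imputation contrast estimates are
pooled on the log-odds-ratio scale by Rubin's rules
(`T = W + (1+1/m)B`, large-sample degrees of freedom, t-based intervals and
p-values) and exponentiated for reporting.  The reference setting is m = 50
imputations; m = 10 is the desk-scale default used in the test suite, where
pooled estimates already stabilize.

## The synthetic cohort generator

The generator is first-class, tested code that reproduces the study design
constructively:

- 1513 participants with wave pattern exactly 140/645/305/423 for 4/3/2/1
  waves (counts deterministic, the identity of the waves random).
- Each participant draws a mean assessment age from their class's age
  profile; observed-wave ages are mean-centred calendar offsets, so
  class-wise mean age matches the configured profile in expectation.  Ages
  are redrawn until every observed wave of an included participant falls in
  its own age bin, which keeps record counts faithful to the wave pattern.
- Exactly 26 of the two-wave participants are forced to contribute both
  waves (the +4/+6 pair) inside the ≤9 bin, so exactly 1064 of the 1090
  multi-wave participants pass the ≥2-distinct-bin inclusion rule — a
  constructive reconciliation of the two printed counts.
- Scores come from the 7-class generating model (mixing proportions
  4.8/4.8/13/7.5/12.7/12.9/44.3%, shared loadings 0, .25, .45, .60, .75,
  .90, 1, residual SD 3) with truncated-Gaussian residuals on [0, 30] —
  truncation, not censoring, so the scale bounds carry no point mass.  The
  truncation still matters at the floor: the two mildest classes have means
  within one residual SD of zero, so their observed cell means sit slightly
  above the generating curve and the residuals there are mildly skewed.
  Recovery tests therefore target the generator's own values with bands
  that include this bias, and an eighth class can soak up a little of the
  floor-effect structure (which is why enumeration defaults to BIC).
- Covariates are drawn from class-conditional profiles (Gaussian for
  continuous scales, truncated to their ranges; Bernoulli for binary ones);
  polygenic scores are standardized to exact cohort mean 0 / SD 1 before
  mild severity-graded class shifts are added.  Missingness is injected
  completely at random: 26.8% on lifetime medication, a common rate on the
  other twelve imputable columns chosen so the average is 5.5%, and 12% on
  polygenic scores (the non-genotyped fraction).
- Families: participants in the six clinical classes are paired into
  two-sibling families, the mildest class are singletons.  This structure
  exists only to exercise clustered standard errors.

What the generator does *not* emulate: item-level questionnaire structure,
rater effects, attrition that depends on severity (missingness is MCAR
throughout, both for waves and covariates), genotypes (polygenic scores are
drawn directly), and any within-class growth-factor heterogeneity.  Passing
recovery tests therefore show that the estimation machinery inverts the
generating process at the study's size and missingness — not that the model
is well-specified for real cohort data.

## Numerical choices and degenerate inputs

Age-bin assignment truncates age to completed years before binning (11.9 →
11 → bin 10–11).  Residual variances are floored at 1e-6; a (domain, class)
regression with posterior mass at fewer than two distinct bins freezes that
class's parameters for the sweep and flags it.  Posterior ties in modal
assignment go to the lowest class index and are logged.  Empty classes in
descriptive tables report N = 0 with undefined statistics.  All randomness
flows from explicit seeds through named, splittable streams
(`numpy.random.SeedSequence`); regenerating with the same seed is
byte-identical, including CSV output.

## Known limitations

- Class-specific loadings/variances are estimable but lightly exercised;
  identification with many classes and sparse bins can be weak.
- The ML three-step correction assumes the estimated D matrix is exact;
  with very low entropy (< ~0.6) the correction grows unstable.
- The wave-2 short-form rescaling is treated as the same linear 0–30 map as
  the other waves; the alternative (domain maxima of 36/27) is noted as an
  inconsistency in the source tables and not modelled.
- Imputation draws are approximate-Bayesian (asymptotic posteriors), not
  full posterior draws; with ≥ 10 observed values per column, required and
  enforced, the difference is immaterial at these sizes.
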