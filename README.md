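# trajmix

Trajectory mixture analysis for longitudinal two-domain symptom data.

`trajmix` is built for developmental studies that track parent-rated ADHD
symptoms — inattention (IA) and hyperactivity-impulsivity (HI), each
rescaled to a common 0–30 scale — across childhood into young adulthood in
a cross-sequential family cohort: participants enter at ages 5–17, are
re-assessed up to three more times, and their observations are pooled into
seven age bins (≤9, 10–11, 12–13, 14–15, 16–17, 18–19, ≥20 years).  The
package answers two questions: *which latent trajectory classes describe
the joint course of the two symptom domains*, and *which genetic,
demographic and clinical factors distinguish classes that look alike in
childhood but diverge later*.

## What it computes

**Parallel-process latent class growth analysis.**  Class k's mean for
domain d at bin t is `i_dk + lambda_dt * s_dk` with free loadings
(`lambda_d0 = 0`, `lambda_d,T-1 = 1`), zero within-class growth-factor
variance, and per-(domain, bin) Gaussian residuals.  Missing bins drop out
of the likelihood (full-information maximum likelihood).  Estimation is
multi-start ECM with an asserted monotone log-likelihood.

**Class enumeration.**  AIC / BIC / sample-size-adjusted BIC, relative
entropy and class sizes per candidate K, with a default selection rule
(aBIC minimum subject to a 20-participant smallest-class screen).

**Three-step covariate regression.**  Modal assignment, classification-error
matrix D, and a maximum-likelihood corrected multinomial logit of class
membership on one covariate at a time — grand-mean centred, age-adjusted,
with family-cluster-robust standard errors — reported as odds ratios for
four pre-specified class contrasts.

**Multiple imputation.**  Chained-equations imputation of covariates and
Rubin's-rules pooling of the per-imputation log-odds ratios.

**Synthetic cohorts.**  A generator that reproduces the study design
exactly — 1513 participants, wave pattern 140/645/305/423, 1064 passing the
two-distinct-bin inclusion rule — from a seven-class generating model with
class-conditional covariate profiles and calibrated missingness (average
5.5%, maximum 26.8% on medication use).  See `docs/methods.md` for the
model, the generator's scope, and all numerical choices.

## Worked example

```python
import numpy as np
from trajmix import (GeneratorConfig, ModelSpec, apply_inclusion_filter,
                     multi_start_fit, order_classes, simulate_cohort)

dataset, covariates = simulate_cohort(GeneratorConfig(seed=20210403))
included = apply_inclusion_filter(dataset)          # >=2 distinct age bins
Y, pids = included.to_wide()                        # (2, N, 7), NaN = missing
print(included.n_participants)

fit = order_classes(multi_start_fit(Y, ModelSpec(n_classes=7),
                                    n_initial=100, n_final=20, seed=7))
print(np.round(100 * fit.params.pi, 1))
print(np.round(fit.params.lam[0], 2))
```

```
1064
[ 5.   4.8  8.2 11.8 11.6 14.3 44.2]
[0.   0.31 0.49 0.66 0.8  0.94 1.  ]
```

1064 of 1513 simulated participants pass the inclusion rule.  The fitted
7-class model, ordered by descending inattention severity, recovers the
generating mixture — two small severe-stable classes near 4.8%, a
severe-decreasing class near 13% (estimated 11.8), a moderate-increasing
class near 7.5%, two moderate/mild classes near 12.7% and 12.9%, and the
large stable-low class near 44.3% — and the estimated common loading curve
tracks the generating shape (0, .25, .45, .60, .75, .90, 1): change is
spread over adolescence rather than concentrated at the start or the end of
the age range.

The same analysis from the shell:

```bash
trajmix run --seed 7 --generator-seed 20210403 --k 7 --out results/run1
```

writes `trajectory_means.csv`, `class_profiles.csv`, `bin_descriptives.csv`,
`contrasts.csv` and a `run_log.json` with seeds, the top replicated
log-likelihoods and the class labels.

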