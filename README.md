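# swgee

Marginal logistic analysis of stepped-wedge cluster randomised trials
(SW-CRTs) with binary outcomes: generalised estimating equations (GEE) with
small-sample sandwich standard-error corrections, estimated and design-based
t-distribution degrees of freedom, and a marginally-specified correlated
binary simulator for studying their operating characteristics.

## Who this is for

SW-CRTs randomise clusters (clinics, labs, villages) to *sequences* that
cross from control to intervention at staggered times. Most such trials
randomise fewer than ~25 clusters, and with few clusters the usual robust
(sandwich) variance estimator of GEE is biased downward, so confidence
intervals for the intervention odds ratio are too narrow. This package is
for trial statisticians analysing such trials and for methodologists
studying which correction/degrees-of-freedom combination to prespecify.

## The model and the estimators

The analysis model is population-average logistic regression

```
logit P(Y_ijk = 1) = period_j + theta * treated_ij
```

fitted by GEE with an independence or exchangeable working correlation
matrix; `theta` is the marginal log odds ratio of the intervention.
With bread `M = (sum_i D_i' V_i^-1 D_i)^-1` and per-cluster contributions
`g_i = D_i' V_i^-1 (y_i - mu_i)`, the uncorrected sandwich is
`M (sum_i g_i g_i') M` (Liang-Zeger, `LZ`). The corrections:

| method | idea |
|---|---|
| `KC` | deflate residuals by `(I - H_i)^(-1/2)` (cluster leverage `H_i = D_i M D_i' V_i^-1`) |
| `KC_approx` | one-sided inverse + symmetrisation — avoids the non-symmetric matrix square root |
| `MD` | deflate by `(I - H_i)^-1` (stronger; tends to overcorrect) |
| `FG` | per-coefficient diagonal adjustment `(1 - min(b, [Q_i]_jj))^(-1/2)`, `Q_i = D_i'V_i^-1 D_i M`, boundary `b = 0.75` |
| `MW` | multiply by `C/(C-p)` |
| `MBN` | rescale and add a model-based ridge `delta * phi * M` |

Intervals use a t-distribution with degrees of freedom from the trial design
(`C-P`, `CP-P`, `CP-C-P`), the Fay-Graubard Satterthwaite estimator (`FG`),
the Pan-Wall estimator (`PW`), or the normal approximation (`Inf`).

The simulator generates binary outcomes with *exact* marginal structure via
the Emrich-Piedmonte construction: a latent multivariate normal is
thresholded per observation, with latent correlations solved numerically so
the dichotomised data attain the target within-cluster correlations on the
proportion (phi) scale — exchangeable or AR(1) in measurement occasion,
optionally with a 50% correlation discount between control and intervention
observations.

## Worked example

Simulate one 12-cluster, 3-sequence trial (prevalence 30%, time trend OR
1.05/occasion, intervention OR 1.3, AR(1) correlation, ICC 0.05) and analyse
it with FG-corrected standard errors:

```sh
swgee simulate --sequences 3 --clusters 12 --cluster-size 24 \
    --structure ar1_0.8 --icc 0.05 --seed 9 --out trial.csv
swgee fit trial.csv --working exchangeable --correction fg --df fg --df c-p
```

prints (abbreviated):

```json
{
  "working": "exchangeable",
  "alpha": 0.0313,
  "log_or": 0.4248,
  "odds_ratio": 1.5292,
  "df": {"FG": 9.79, "C-P": 8.0},
  "methods": {
    "FG": {
      "se": 0.3859,
      "intervals": {
        "FG":  {"or_ci": [0.646, 3.622], "p": 0.297},
        "C-P": {"or_ci": [0.628, 3.724], "p": 0.303}
      }
    }
  }
}
```

Read: the estimated intervention odds ratio is 1.53 with exchangeable
working correlation `alpha = 0.031`; the FG-corrected standard error of the
log odds ratio is 0.386, and a t-interval with the estimated 9.8 degrees of
freedom gives an OR 95% CI of 0.65 to 3.62 (p = 0.30) — at 12 clusters this
trial cannot distinguish the true OR of 1.3 (used in the simulation) from
no effect.

The same machinery runs as a library (`swgee.fit_gee`, `swgee.sandwich`,
`swgee.wald_t_interval`, ...) and scales to full scenario grids:

```sh
swgee run-study --phase 1 --reps 200 --seed 1 --out phase1.csv
swgee report --in phase1.csv --group-by working,correction
```

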