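# Methods

## Data-generating model

The simulator produces repeated cross-sectional SW-CRT data: every
individual is observed once, at one of six measurement occasions, inside
one cluster. The marginal outcome probability of an individual in occasion
`t` under condition `z` is

    odds(t, z) = [p0/(1-p0)] * r_time^(t-1) * r_trt^z,    p = odds/(1+odds)

with defaults `p0 = 0.30`, `r_time = 1.05` per occasion, `r_trt = 1.3`.
Baseline odds are the exact `3/7`, not a rounded two-decimal value: rounding
would propagate visibly by occasion six (odds 0.5470, prevalence 35.4%).
Because the model is specified marginally, `log(1.3)` is the exact
population-average treatment coefficient; coverage and bias are evaluated
against it.

Within-cluster dependence is specified on the proportion (phi) scale.
Observations in the same cluster and occasion are exchangeable with
correlation `rho` (the within-occasion ICC). Across occasions at lag `k`
the correlation is `rho` (exchangeable family), `rho * r0^k` (AR(1),
`r0 = 0.6` or `0.8`), optionally times `0.5` when one observation is under
control and the other under intervention (a proxy for cluster-varying
intervention effects). The 50% discount composes multiplicatively with the
AR decay; the composition is order-free, which is why no ordering convention
is needed.

### Emrich-Piedmonte generation

Each cluster's outcome vector is `1{Z > z(1-p)}` for a zero-mean unit
multivariate normal `Z`. For every pair of observations the latent normal
correlation `delta` is solved from

    P(Z1 > z(1-p1), Z2 > z(1-p2); delta) - p1 p2 = phi * sqrt(p1 q1 p2 q2)

by Brent bracketing on `delta` (equation solved to well below 1e-10; the
bivariate orthant probability is evaluated through Owen's T function, ~1e-14
accurate). Feasibility against the Frechet bounds of (p1, p2) is checked
first and an infeasible target is an error naming the feasible interval.
Solved values are cached by `(p1, p2, phi)`: a scenario only contains a
handful of distinct pair classes (occasion pair x condition concordance),
so the grid of 690 scenarios re-uses a few hundred solves in total. The
full-cluster latent matrix is assembled by expanding a 6x6 per-sequence
table, must pass a Cholesky factorisation (positive definiteness is never
silently repaired — all simulated parameter ranges are PD, so failure means
a configuration bug), and the factor is cached per sequence when cluster
sizes are constant.

### Cluster sizes

With CV = 0 each cluster contributes `m/6` observations per occasion
(`m` in {24, 60, 300}). With CV = 0.4 the *cluster total* is drawn from a
negative binomial left-truncated at 12 (ensuring at least two observations
per occasion after the split) whose base parameters are solved numerically
so the post-truncation total has mean `m` and CV exactly 0.4; the total is
split evenly over occasions with the remainder assigned to occasions chosen
at random. A per-occasion truncated draw cannot meet these targets: with a
floor of 2 and mean 4 per occasion, no negative binomial reaches the
variance a total CV of 0.4 requires once truncated (the truncated mean is
dragged above 5.5 first). Truncation is implemented by inversion of the
conditional CDF — identical in law to redrawing until the floor is met, but
deterministic given the generator state.

## GEE fit

Fisher scoring on `sum_i D_i' V_i^-1 (y_i - mu_i) = 0` with logit link,
`V_i = A_i^(1/2) R(alpha) A_i^(1/2)`. The exchangeable `R^-1` is applied in
closed form, so no n_i x n_i matrix is ever formed, and cluster reductions
run on flat arrays via `np.add.reduceat`; this is what makes ~200,000
replicate fits per study run affordable. `alpha` is re-estimated each
iteration by the moment estimator over distinct within-cluster pairs of
Pearson residuals with denominator `(sum_i n_i(n_i-1)/2 - p)`, divided by
the Pearson dispersion `phi = X^2/(N-p)` (the `p` subtraction is a
standard small-sample convention; the alternative without it differs at
O(p/N) and is immaterial at these sizes). `alpha` is clipped into the range
where the exchangeable matrix is invertible for the largest cluster.

Convergence requires `max|delta beta| < 1e-6` within 50 iterations;
divergence (non-finite or runaway coefficients, singular information) sets
`converged = False`, never raises — study runners count failures. These caps
make separation detectable: an all-zero period cell sends that period's
cell-mean toward -inf at a roughly constant step per iteration and is caught
by the iteration cap. The scale is estimated rather than fixed at 1 (a flag
fixes it); the sandwich itself is scale-invariant.

The model matrix uses cell-means period coding (one indicator per trial
period, no intercept) plus the treatment indicator, so `p = periods + 1` and
the last coefficient is the marginal log odds ratio directly. Point
estimates and all leverage-based corrections are invariant to switching to
intercept-plus-dummies coding; the FG diagonal adjustment is not exactly
invariant, but the difference was measured below one percentage point of
relative SE error even at six clusters.

## Sandwich corrections

All corrections are computed from one converged fit; none refits. The
leverage corrections are reduced to p x p algebra with the Woodbury
identity `D_i'V_i^-1(I - H_i)^-1 r_i = (I - Q_i)^-1 g_i`, `Q_i = W_i M`
(verified to 1e-12 against the direct n x n formulas), so MD, KC-approx and
FG cost a few p x p solves per cluster. Exact KC needs the square root of
the generally non-symmetric `(I - H_i)`, taken per cluster via the Schur
method; its condition number is recorded in the diagnostics because the
instability of exact KC under an exchangeable working correlation is a
property of the estimator that users should see, not one to repair
silently. A numerically clean computation largely avoids that instability
(in the screening grid here, exact KC under exchangeable working
overcorrects by more than 10% in about 1 of 64 scenarios); implementations
that invert ill-conditioned n x n blocks directly can inflate the
exchangeable-working column of the leverage-based corrections, so grid
means from such implementations may sit a few percentage points above the
ones computed here while the independence column agrees.

MBN constants are isolated in one place: `kappa = (N-1)/(N-p) * C/(C-1)`,
`delta = min(0.5, p/(C-p))`, `phi_r = max(1, kappa * tr(M * meat)/p)`, and
the estimate is `kappa * LZ + delta * phi_r * M`. The FG boundary defaults
to `b = 0.75` and is configurable; at `b = 0` FG reduces to LZ exactly, and
in balanced singleton-cluster toys FG, KC and KC-approx coincide (closed
forms used as test oracles). MW is the scalar `C/(C-p)` rescaling and is
undefined for `C <= p` (reported as a correction failure, as is any
singular `(I - H_i)`; failures are tallied separately from fit
non-convergence).

## Degrees of freedom

Design-based: `C-P = C - (T+1)`, `CP-P = C*T - (T+1)`,
`CP-C-P = C*T - C - T`, floored at 1. Estimated:

* Fay-Graubard: project each cluster's bias-adjusted contribution onto the
  treatment contrast, `a_i = A_i M l`, and moment-match against the
  model-implied covariance `Cov(g_i, g_j) = delta_ij W_i - W_i M W_j`
  (the second term accounts for residuals being taken at the estimated
  coefficients): `df = (sum w_ii)^2 / sum w_ij^2`. In balanced toys this is
  exactly `C - p`; over the screening grid it averages ~13.5 (3 sequences)
  and ~13.0 (6 sequences) with spread coming mostly from redrawn cluster
  sizes in CV = 0.4 scenarios.
* Pan-Wall: Satterthwaite on the per-cluster variance contributions
  `s_i = (g_i' M l)^2`, with `Var(sum s_i)` estimated by `C` times their
  sample variance, capped at 1000 when the spread degenerates. The
  estimator is known to be extremely variable with few clusters —
  reproducing that spread is intended behaviour.

Intervals are `estimate +/- t_{df,0.975} * se`; `df = inf` selects the
normal distribution. The two-sided p-value and the interval are consistent
by construction (`p < 0.05` iff the interval excludes zero), so power and
coverage computed from the same records cannot disagree.

## Study design, metrics and problem sizes

Phase one crosses ICC {0.01, 0.1} x 4 correlation structures x {3, 6}
sequences x cluster size {24, 60} x CV {0, 0.4} at 18 clusters
(64 scenarios); phase two adds ICC 0.05 and clusters {6, ..., 54}
(672 scenarios) plus 18 restricted cluster-size-300 scenarios (exchangeable
structure, CV 0, clusters {12, 24, 42}) — 690 in all. Per scenario x method
the runner reports convergence, standardized bias
`mean(est - true)/SD(est)`, relative SE error `mean(SE)/SD(est) - 1`,
coverage and power, each with Monte-Carlo standard errors, computed over the
replicates where the fit converged and the correction succeeded. Every
simulated dataset is analysed by all requested methods, so method contrasts
are paired.

Seeding: each scenario derives a `SeedSequence` from (root seed, CRC-32 of
its stable scenario id) and spawns one substream per replicate. Results are
therefore independent of execution order, worker count and subsetting; the
same root seed reproduces byte-identical datasets.

The acceptance script runs 1000 replicates per scenario — the full-scale
study's count, affordable because of the closed-form exchangeable inverse
and pair-class caching (~15 minutes for its three grids on one CPU). The
test suite uses 200-250 replicates per scenario, which resolves grid means
to a few tenths of a percentage point.

## Known limitations

* Cohort (repeated-individual) designs, baseline all-control periods and
  incomplete designs are out of scope; the design builder emits only the
  no-baseline staircase (a generic staircase for other sequence counts
  exists behind a flag but is untested against published designs).
* Working correlations beyond independence/exchangeable are not provided.
* The synthetic generator matches marginals and pairwise correlations
  exactly but, like any latent-threshold construction, fixes higher-order
  dependence implicitly; real trials may also have confounding between
  cluster size and outcome, calendar-time shocks, and missingness, none of
  which are emulated. Passing tests therefore demonstrate correctness of
  the estimators under the stated dependence model, not robustness to
  features outside it.
* The Pan-Wall degrees of freedom convention used by older reference
  implementations could not be fully reconstructed; the implemented
  estimator follows the moment-matching definition stated above and
  reproduces the documented qualitative instability, but not the printed
  means of every published table.
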