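# Methods

This note documents the models implemented in `dsrt`, the estimation and
scoring machinery, the synthetic-data generators, and the numerical and design
choices that were genuinely open.

## Models

### Continuous signed-residual-time (SRT) model

A timed item response with binary accuracy `X`, response time `T`, and a
shared item deadline `d` is scored `S = (2X − 1)(d − T)`: the residual time to
the deadline, added for correct and subtracted for incorrect responses.  With
`a = α(θ − δ)` (discrimination α > 0, difficulty δ), the joint density of
(X, T) given ability θ is the truncated exponential family

    f(x, t | θ) = a · exp((2x − 1)(d − t) a) / (exp(d·a) − exp(−d·a)),

which integrates to one over x ∈ {0, 1}, t ∈ [0, d].  The normalizer follows
from integrating the kernel exp(s·a) over s ∈ [−d, d]; it implies the
two-parameter-logistic accuracy margin `P(X = 1 | θ) = logistic(d·a)`, which
the package verifies by numerical integration.  At θ = δ the density
degenerates to the uniform `1/(2d)` (handled as an analytic limit).  Sampling
uses the inverse CDF of S in a form that stays finite for large `d·a`.

### Discretized SRT models

Dichotomizing T at half the deadline (fast iff `t < d/2`; a response at
exactly `d/2` counts as slow) and crossing with accuracy yields the ordered
four-category score 0 = fast incorrect, 1 = slow incorrect, 2 = slow correct,
3 = fast correct — the ordering implied by the continuous scoring rule, with
equal average score spacing when the split is at half deadline.  The family of
category-probability models, all softmax (adjacent-category logistic) forms
with `β_0 ≡ 0`:

| tag      | logits for category s                          | per-item params |
|----------|------------------------------------------------|-----------------|
| coomans  | `s(θ − δ_i)`                                   | 1               |
| pcm      | `sθ + β_is`                                    | 3               |
| srt1d    | `s·α_i·θ + β_is`                               | 4               |
| nrm      | `a_is·θ + β_is` (free category slopes)         | 6               |
| srt2d    | `s·α_i1·θ1 + 1{s∈{0,3}}·α_i2·θ2 + β_is`        | 5               |

`srt2d` is a two-dimensional nominal response model with scoring vectors
`c1 = [0,1,2,3]` (ability) and `c2 = [1,0,0,1]` (speed): θ2 raises the
probability of the fast categories jointly, absorbing person differences in
the tendency to respond fast that ability cannot explain.  Each reduction in
the chain nominal → srt2d → srt1d → pcm → coomans is asserted numerically in
the test suite.

Two comparison models operate on the (accuracy, fast-indicator) split of the
same four cells: the hierarchical model (`hm`, a 2PL for accuracy on θ1 and a
2PL for the fast indicator on θ2, 4 parameters per item + ρ) and the IRTree
model (`irtree`, a 2PL speed branch followed by branch-specific accuracy 2PLs,
6 parameters per item + ρ).  The product of the two 2PLs in `hm` is itself a
four-category softmax with additive logits, so it shares the nominal-model
estimation path; the IRTree's branch-specific normalizers break that linearity
and it carries its own probability and M-step code.

Latent identification throughout: means 0 and variances 1, free correlation
ρ in the two-dimensional models.

### Three-bin discretization

For a three-way equal split of [0, d] the package assigns six ordered scores
(fast incorrect … fast correct) with ability scoring vector `[0,…,5]`.  The
speed scoring vector for this case is not canonically determined; the default
is the symmetric loading `[2,1,0,0,1,2]` (the fastest categories load most on
speed, mirroring the two-bin indicator), and it is user-overridable through
`fit_mml(..., scoring_speed=...)`.

## Estimation

Marginal maximum likelihood via EM.  The E-step evaluates person posteriors
over a fixed Gauss–Hermite grid (product grid in two dimensions).  The latent
correlation enters through the quadrature *weights*: the product-normal
weights are multiplied by the ratio of the correlated to the independent
bivariate-normal density and renormalized.  With fixed nodes, the M-step for ρ
is a decoupled one-dimensional bounded search over the expected complete-data
log-likelihood of the weights, while each item's parameters solve a small
Newton problem (batched across items, three Newton steps per M-step with
step-halving so the EM ascent property is preserved).  Slopes constrained
positive are log-reparameterized; logits and log-slopes are clipped at
generous bounds (±30; log-slope in [−8, 4]) purely as numerical safeguards.
All softmax evaluations subtract the maximum logit.

Starting values: slopes 1, intercepts at observed category log-odds (with 0.5
smoothing for the start only), ρ = 0.  Convergence: relative log-likelihood
change below 1e-6 or 500 iterations; non-convergence is flagged on the result,
never raised.  Missing entries are skipped in the within-person product (a
dummy zero-log-probability category); persons or items with no observations,
and items with empty categories, raise errors naming the offender.

Default quadrature is 21 nodes per dimension.  Accuracy was validated against
brute-force dense-grid integration (relative error below 1e-6 at 3 items, and
~1e-9 in one dimension).

EAP scoring integrates over the *fitted* population distribution (including
the estimated ρ) and reports posterior means and SDs per dimension; persons
with no observed responses are flagged and given the prior (mean 0, SD 1).
EAP reliability is `var(EAP) / (var(EAP) + mean(PSD²))`, the standard
model-based form; the reference study does not print a formula, and this is
the conventional choice.

## Synthetic-data generators

The generators emulate a timed low-stakes testing setting: bivariate-normal
(ability, speed) persons, items from the benchmark design — the five
intercept sets {[0,0,0], [1.5,1.5,0], [−1.5,−1.5,0], [0,1.5,1.5],
[0,−1.5,−1.5]} tiled K/5 times, ability slope 0.5, speed slope 0 (null) or 1 —
with N = 1000 persons unless stated otherwise.  Latents are drawn once per
condition and held fixed across replications (the per-person
average-estimate plots presuppose fixed persons); a redrawn-per-replication
mode is available.  The fixed draw is standardized to exact sample moments
(mean 0, SD 1, exact ρ): the fitted models identify the latent variance as 1,
so a fixed draw whose sample SD deviates from 1 would convert that sampling
error into apparent estimation bias for every person — at K = 40 a draw with
SD 1.06 raises the average absolute bias by more than 50%.  Standardizing
removes this nuisance artifact and makes the recovery summaries stable across
master seeds.  Seeding derives child seeds as
`SeedSequence((master, condition, replication))`, so any replication is
re-runnable in isolation and results are independent of worker count.

What the generators deliberately do not emulate: adaptive item selection,
within-person learning or fatigue, non-normal latents, and informative
missingness (only MCAR masking is provided).  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated model, not robustness to the delivery mechanisms of operational
adaptive-practice data.

## Replication study

The study harness crosses the null and speed-difference conditions with
K ∈ {20, 40} and ρ ∈ {0, .2, .5} (the tabulated grid), fits the requested
models to each replicated data set, EAP-scores ability, and aggregates:

- average absolute bias: per person, the mean over replications of
  (estimate − truth), then the absolute value averaged over persons;
- variance: per-person variance of the estimates over replications (ddof 0,
  so MSE_p = bias_p² + var_p holds exactly);
- MSE: squared error averaged over persons and replications;
- EAP reliability, averaged over replications.

The default replication count is 100 (scaled down from the reference 1000)
and is recorded in all outputs; the reproduction script runs the cheap null
K = 40 condition (one 1-D fit per replication) at 400 replications.  Study numerics: 21 Gauss–Hermite nodes for
one-dimensional fits, 15 nodes per dimension for the two-dimensional-latent
models, and a 21-node-per-dimension grid for EAP scoring.  These sizes come
from an accuracy sweep: coarser fit/scoring grids visibly inflate the
across-replication variance of the 2-D EAP estimates, while 15/21 nodes
reproduce the dense-grid results.

Monte-Carlo error accounting, reported for every cell:

- a jackknife-over-replications SE for bias/variance/MSE and the SE of the
  mean for reliability;
- a person-sampling SE (SD over persons of the per-person summary, divided by
  √N; for reliability a delta-method SE, `rel(1 − rel)·√(2/(N − 1))`).  The
  aggregates depend on the realized draw of 1000 latents, so any two studies
  with independent person draws differ by this much even at infinite
  replications — comparisons against external reference values combine the
  two sources for *both* sides (`ModelSummary.comparison_se`);
- a closed-form estimate of the upward inflation of the average-absolute-bias
  statistic at finite replications (`E|N(b, s)| − |b|` with plug-in per-person
  noise SDs): at 100 replications this is ≈0.004 on the bias scale and should
  be kept in mind when comparing against large-replication reference values.

## Positive-manifold diagnostic

The first eigenvalue of the pairwise-complete inter-item correlation matrix
of the fast/slow indicators (or raw RTs) measures the positive manifold that
unidimensional SRT models cannot generate.  Its predictive distribution under
a fitted model is approximated by a parametric bootstrap at the MML point
estimates — simulating data sets with the same persons, items, and
missingness template and recomputing the statistic (500 replicates by
default, 2.5th/97.5th percentile interval).  A posterior-predictive version
would additionally propagate parameter uncertainty; at the study's sample
sizes the plug-in interval is calibrated to ≈95% coverage under the
generating model (checked by simulation), and misfit appears as the observed
statistic falling above the interval.  Pairwise-complete correlations require
a minimum overlap per item pair (default 30); pairs below the threshold, and
zero-variance items, raise errors naming the offender, and non-PSD pairwise
matrices trigger a warning.

## Known limitations

- No continuous-RT two-dimensional extension (dichotomization is what makes
  the multidimensional polytomous toolbox applicable).
- No standard errors for item parameters (point estimation + EAP scoring
  only); model comparison is by AIC/BIC.
- The EM ascent is to a local optimum; the study's likelihoods are well
  behaved, but pathological data sets can in principle converge elsewhere.
- The bootstrap check fixes parameters at their estimates and mildly
  understates predictive uncertainty relative to a full posterior-predictive
  check.
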