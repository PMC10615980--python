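# Methods

## The measurement problem

In rated performance assessments (essays, presentations, interviews), a
score says as much about the rater as about the examinee. Beyond a rater
being globally severe or lenient, severity changes *within* a rating
session spread over hours or days — rater severity drift. Treating a
rater's per-period severities as unrelated parameters wastes the strong
temporal dependence that real raters exhibit: most raters are stable, and
those that drift tend to move gradually.

## Model

Data are ordinal scores `u_jrt ∈ {1..K}` given by rater `r` to examinee
`j` during rating period `t` (a period is a session or day within which a
rater's severity is treated as constant; single-item setting). The
probability of score `k` follows an adjacent-category (partial-credit
style) many-facet Rasch kernel

    P_jrtk ∝ exp Σ_{m≤k} D (θ_j − β_rt − d_rm),        D = 1.7,

with examinee ability `θ_j`, time-specific rater severity `β_rt`, and
rater-specific step parameters `d_rm` capturing category usage (central
tendency, range restriction). Identification: `d_r1 = 0` and
`Σ_{m≥2} d_rm = 0`. The hierarchical prior couples severities over time:

    θ_j ~ N(0,1)
    β_r1 ~ N(0,1)
    β_rt | β_r,t−1 ~ N(β_r,t−1, σ_r),  t > 1
    σ_r ~ LogNormal(μ_σ, 1)
    d_rm ~ N(0,1)  (on the free coordinates, see below)

`σ_r` is the rater's drift scale — near zero for stable raters, large for
drifters — and the log-mean hyperparameter `μ_σ` encodes how common drift
is believed to be (default −2: drift is the exception; values near 0 admit
strong drift; values above 0 are discouraged since severities live on the
N(0,1) ability scale). The log-scale prior SD is fixed at 1.

Four variants share this kernel:

| variant              | steps        | severity prior       |
|----------------------|--------------|----------------------|
| `proposed`           | `d_rm`       | first-order walk     |
| `proposed_no_markov` | `d_rm`       | i.i.d. N(0,1)        |
| `baseline`           | shared `d_m` | i.i.d. N(0,1)        |
| `baseline_markov`    | shared `d_m` | first-order walk     |

With all step rows equal, the rater-specific model reproduces the shared
step model exactly (nesting tested).

`β_rt` carries no sum-to-zero anchoring; the scale is identified through
the N(0,1) priors on `θ` and `β_r1`. Users should not expect anchored
severity scales.

### Step-parameter prior under the constraints

The stated `d_rm ~ N(0,1)` does not say how the prior interacts with the
two identification constraints. We place independent N(0,1) densities on
the K−2 free coordinates `d_r2..d_r,K−1` and define `d_r1 = 0`,
`d_rK = −Σ free` deterministically — the way such constraints are usually
coded for gradient-based samplers, keeping the sampling space
unconstrained. A consequence worth knowing: the implied marginal variance
of the forced last step is K−2, so simulated truths occasionally contain
an extreme top step, and recovery RMSE for the step family is sensitive
to this convention (ability, severity and drift-scale recovery are not).

## Posterior computation

No gradient-based sampling backend is assumed; the package ships its own
No-U-Turn sampler:

- dynamic trajectory doubling with slice sampling across the trajectory,
  maximum tree depth 10, divergence declared when the Hamiltonian error
  exceeds 1000 (the divergent subtree is rejected and the transition
  counted, never raised as an error);
- dual-averaging step-size adaptation towards a target acceptance
  statistic of 0.98 (a deliberately high target that keeps divergences
  rare in the funnel-prone drift-scale geometry);
- diagonal mass-matrix estimation in doubling warmup windows (75-iteration
  initial buffer, 25-iteration base window, 50-iteration terminal buffer),
  with regularised variance estimates and a step-size re-search after
  each metric update;
- `σ_r` sampled as `log σ_r` with the Jacobian included, so the sampled
  density equals the natural-parameter posterior plus `Σ_r log σ_r`;
- chains initialised at independent jittered prior draws, chain seeds
  derived deterministically from the master seed.

Defaults: 3 chains, draws retained from iteration 2000 to 5000 (2000
warmup + 3000 kept, 9000 total). The jitted
chain loop and the hand-derived gradient are verified against an
independent, readable implementation of the same log posterior (1e−6
agreement at random parameter points) and against central finite
differences.

The density kernel processes observations in a canonical order (sorted by
examinee, rater, time), which makes the sampled chains — and therefore
every downstream estimate — exactly invariant to the row order of the
input file.

Point estimates are EAP (posterior means pooled over chains); step
estimates are averaged on the free coordinates and then constrained, so
they satisfy the identification constraints exactly; drift scales are
averaged on the σ scale.

## Diagnostics

Split-chain R-hat and autocorrelation-based ESS are computed per scalar
parameter (arviz, `method="split"` / `method="mean"`). Chains with zero
within-chain variance but distinct levels report `R-hat = inf`; constant
chains report `ESS = 0`. Thresholds R-hat < 1.1 and ESS > 400 are
reported as pass/fail flags, never hard failures. Divergent transitions
are counted over retained (post-warmup) transitions and reported as a
count and fraction.

## Model comparison

WAIC is reported on the deviance scale, `−2(lppd − p_waic)`, with
log-sum-exp-stabilised lppd and the n−1 sample variance in the penalty.
WBIC runs a dedicated sampling pass on the tempered posterior
(likelihood raised to `1/log n`) and reports the tempered expectation of
the negative log likelihood in nats. The two criteria are therefore on
different scales by construction; both are "lower is better". A testing
hook forces the temperature to 1, where WBIC collapses to the ordinary
posterior mean deviance/2 identity.

## Synthetic studies

The generator emulates a longitudinal essay-rating session:

- abilities and first-period severities standard normal; severities then
  follow the per-rater walk; free step coordinates standard normal;
- drift scales from a 60/40 mixture of LogNormal(−3,1) (stable) and
  LogNormal(−1,1) (drifting); exactly `floor(0.6 R)` raters receive the
  stable component and the component labels are randomly permuted over
  raters (the floor-then-permute rule is our tie-break for fractional
  counts);
- each rater scores each assigned examinee once, with the workload split
  into contiguous near-equal blocks over the T periods in randomised
  order ("a quarter of the essays each day") — so more periods mean less
  data per severity parameter, which is what makes the chain prior
  valuable;
- designs: fully crossed, or a systematic link design assigning each
  examinee `n` cyclically consecutive raters (`n = 2, 3`), which keeps
  the examinee–rater graph connected so all raters share one scale
  (cyclic-consecutive construction; connectivity is property-tested).

What the generator does **not** emulate: real raters' non-Gaussian and
scripted drift patterns (monotone or alternating severity instructions),
halo effects and rater–examinee interactions, missingness that is
informative rather than by design, and multi-item tests. Passing recovery
tests therefore show that the estimator recovers parameters *under the
model's own generative assumptions and these designs*; they do not
certify behaviour under misspecified drift.

Intentionally scripted drifting raters (monotone/alternating) are left as
an extension hook: generate a truth, overwrite its `beta` rows, and pass
it to `simulate_scores`.

## Recovery studies

RMSE pools all entities of a parameter family within a replication
(`sqrt(mean((est − true)^2))`), then averages across replications; bias is
the signed mean error. The step family is scored on entries `m ≥ 2`
(`d_r1` is fixed). Data seeds derive from the master seed independently
of the fitted variant, so ablation comparisons are paired by replication.
Failed fits are excluded and counted, never silently dropped. The paired
t-test compares per-condition mean RMSEs across the condition grid
(two-sided, scipy), flagging the degenerate zero-variance case.

The package's own test and verification budget runs the study at reduced
scale: condition (J=100, R=5, T=3), 10 replications, 3 chains ×
(1000 warmup + 1000 draws), for the crossed and link designs, with the
published 50-replication table values matched within 3 Monte-Carlo
standard errors of the replication spread. The full 12-condition ×
50-replication grid is available through the same API/CLI and is an
overnight computation.

## Numerical choices

- All category probabilities in log space with log-sum-exp normalisation;
  normalisation verified to 1e−12 over random parameters.
- K = 2 is the degenerate step case: an empty free-coordinate vector and
  steps fixed at (0, 0).
- Scores are strictly validated on input (out-of-range is an error, not a
  clamp); at most one observation per (examinee, rater, time).
- Seeds: every stochastic component (truth draw, design, scores, chains)
  derives from one master seed via `numpy.random.SeedSequence` spawning;
  reruns are bit-identical.

## Known limitations

- Single-item setting only; no item, item-time or item-rater facets.
- No maximum-likelihood estimation of the non-Bayesian model; estimates
  approach it only asymptotically through the Bayesian fit.
- Step-family recovery depends on the truth convention for the
  constrained step (see above).
- WAIC/WBIC scale conventions are the package's own documented choices;
  comparisons are meaningful within a convention, not across packages.
- The per-rater drift scale is weakly identified when T is small (three
  periods give two increments per rater); its posterior then leans on the
  prior, which is the intended behaviour of `μ_σ` but means point
  estimates of `σ_r` should be read qualitatively.
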