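# Methods

## The decision model

A trial is modelled as a one-dimensional diffusion: evidence `x(t)`
starts at `x(0) = z·a`, drifts at constant rate `v` with unit noise
coefficient (the scaling convention; the data constrain only ratios to
the noise), and is absorbed at collapsing thresholds `±a·e^{−τt}`.
Hitting the upper threshold produces an *unfriendly* choice, the lower a
*friendly* one; the response time adds a non-decision latency `Ter`.
The exponential collapse models urgency induced by the 2.3 s response
deadline. A trial whose accumulator survives to the deadline (net of
`Ter`) is a miss; misses are excluded from fitting, so the likelihood
conditions on nothing — it scores observed (choice, RT) pairs against
the defective first-passage densities, and the undecided mass is simply
never scored.

Condition effects enter linearly. With mask indicator `C` and emotion
fraction `k` (raw percent / 100, so the six analyzable levels are ±0.10,
±0.40, ±0.60):

    v   = vc0 + C·vc_mask + k·(v_slope0 + C·v_slope_mask)
    Ter = Ter0 + C·Ter_mask
    z   = z0  + C·z_mask

`a` and `τ` are shared between masked and unmasked conditions. The
emotion regressor uses the fraction scale because the group-mean
slope (≈5.7) then yields physically plausible drifts (|v| ≤ 3.6);
the raw integer labels are kept in data files. The starting point is
stored as a signed fraction of the *initial* threshold (`|z| < 1`,
positive toward unfriendly); the collapse moves the thresholds, not the
start.

The four-model family pins mask-bias terms to zero: `null`
(`vc_mask = z_mask = 0`, 8 free parameters), `reduced_vc` (9),
`reduced_z` (9), `full_vc_z` (10). Across-trial variability parameters
(`sz`, `st0`, `sv`) are fixed at zero and are out of scope.

## Numerical engine

`solve_fptd` forward-integrates the Fokker–Planck equation on a fixed
spatial grid spanning `[−a, a]` with a Crank–Nicolson scheme
(unconditionally stable; the advective cell Péclet number stays far
below 2 at the relevant drifts). Design choices that matter:

* **Grid.** The cell count is set by `dx` interpreted per unit
  threshold (`N = 2/dx`, spacing `h = 2a/N`), so the discretization does
  not jump as `a` varies during fitting — cell-count jumps otherwise
  texture the likelihood surface with micro-ridges that trap
  derivative-free optimizers. Defaults: `dt = 5 ms`, `dx = 5·10⁻³`
  (N = 400), `t_max = 2.3 s`.
* **Initial condition.** The point mass at `z·a` is split linearly over
  its two neighbouring nodes; a start within one cell of a boundary is
  an error.
* **Rannacher startup.** The first output step runs as four fully
  implicit quarter-steps. Crank–Nicolson barely damps the
  delta-function's checkerboard mode (amplification → −1 at large
  Fourier number); undamped, that mode survives long enough to be
  harvested by the collapsing bound as spurious signed absorbed mass.
* **Collapse handling.** Nodes outside the current bound are absorbing;
  mass they still hold when the bound sweeps past is harvested into that
  step's absorbed mass on their side. Because the bound generally falls
  *between* node layers, each step solves both bracketing Dirichlet
  windows and blends them by the bound's fractional cell position —
  without this the likelihood is discontinuous in `τ` and `a` with
  steps of tens of log-likelihood units at realistic trial counts.
* **Flux split and conservation.** The mass lost through the Dirichlet
  edges in a step is attributed to the two boundaries in proportion to
  the discrete outgoing fluxes (clamped at zero) and rescaled so that
  absorbed + undecided mass is conserved exactly; residual negative
  per-step masses (below 10⁻⁸ in all tested regimes) are clipped into
  the undecided remainder.
* **Likelihood floor.** Densities are floored at 10⁻¹⁰ s⁻¹; RTs at or
  below `Ter` or beyond the solver horizon score the floor rather than
  −∞.

Two independent oracles validate the solver: the classical eigenfunction
series for constant bounds (sup-norm agreement within 2 % of the peak
density plus a 5·10⁻³ absolute transient term), and closed forms for
absorption probability and zero-drift mean first-passage time. A
Euler–Maruyama path sampler (1 ms steps) with a Brownian-bridge
within-step crossing correction — without it absorption is biased late
by O(√dt), visible as a ~0.03 KS distance — provides a third,
stochastic cross-check: at 10⁵ draws the per-choice KS distance to the
refined-grid (dt = 1 ms, dx = 2·10⁻³) solver distribution stays below
0.025.

## Fitting

Per participant, the log-likelihood sums the log first-passage density
interpolated at `rt − Ter` over the 12 analyzable mask-by-emotion cells
(fillers and misses excluded); repeated RTs are collapsed to unique
values with multiplicities.

The surface is smooth but has a strongly correlated, nearly flat valley
coupling `(vc0, z0)`, `(vc_mask, z_mask)` and `(a, τ)`. The search is a
deterministic staged cascade, seeded only through a small jitter of its
starting point:

1. **Informed start.** Empirical-logit slope and bias per condition
   (choice logit ≈ `2a·v` for roughly constant bounds) give drift
   starts; `Ter` starts just below the 1 % RT quantile; `a = 1.1`,
   `τ = 1`, `z` terms at 0.
2. **Prestage** (`dt = 20 ms`, `dx = 0.04`): full-space Nelder–Mead,
   then cycles of 2-d/4-d block searches over the correlated pairs
   ((vc0, z0), (vc_mask, z_mask), (a, τ), (Ter0, Ter_mask), the bias
   quadruple) alternating with full-space Nelder–Mead, until the cycle
   gain drops below `cycle_tol`.
3. **Consolidation** (`dt = 10 ms`, `dx = 0.01`): the same block/full
   cycles, at most twice. This grid already locates the full-resolution
   arg-max to within ≈0.005 on every parameter.
4. **Polish** (default grid): one short full-space Nelder–Mead; the
   reported log-likelihood, AIC and BIC are on this grid.

An evolutionary global stage (differential evolution) was tried and
rejected: at budgets compatible with per-participant fitting it
frequently stalled far from the optimum or in the mirrored basin where
the starting-point and drift-criterion biases swap roles, while the
informed block-coordinate cascade reaches the optimum reliably in under
a minute at 24,000 trials. When several family members are fitted
(`fit_all_models`), models are fitted simplest-first and every fitted
submodel seeds an extra polish start of its supermodels, which enforces
the nested log-likelihood ordering by construction.

Box constraints bracket plausible values by wide margins: `a ∈ (0.3,
5)`, `τ ∈ (0, 10)`, `Ter0 ∈ (0.1, 1.0) s`, `Ter_mask ∈ (−0.2, 0.2) s`,
drift criteria ∈ (−5, 5), slopes ∈ (−20, 20), `z` terms ∈ (−0.9, 0.9).
Parameter vectors violating the model space (e.g. `|z0 + z_mask| ≥ 1`)
score a large penalty. A fit is flagged converged when the
consolidation cycles met their tolerance or the final polish satisfied
Nelder–Mead's criteria; only converged fits enter cohort summaries.

Model selection computes AIC `= 2k − 2logL` and BIC
`= k·ln(n) − 2logL` with `n` the participant's analyzable trial count,
takes the per-participant arg-min per criterion (ties to the fewer-
parameter model), and reports cohort means and winner percentages.

## Synthetic data

The generator is the study-design stand-in, not a convenience fixture.
A session is 8 blocks of 76 trials, each block a seeded random
alternation of 6 repeats of every main mask-by-emotion cell plus one of
each filler cell (±20 %, generated but excluded from fitting), with
fixation jitter uniform on 600–1200 ms (it affects only the timeline,
not RTs). Choices and RTs come from Euler–Maruyama simulation (1 ms
default step, bridge-corrected) of the same process the solver
describes; trials with no crossing before `2.3 s − Ter` are misses. At
the default generating parameters misses are rare (< 1 %), so the
generator never exercises heavy miss-rate regimes. Cohorts draw each
participant's true parameters independently from normal distributions
whose means and SDs default to the group-level full-model estimates,
rejection-truncated to the valid region (`a, τ, Ter0 > 0`,
`Ter0 + Ter_mask ≥ 0`, `|z|` < 1 in both conditions).

What the generator does *not* emulate: across-trial parameter
variability, sequential effects (post-error slowing, block fatigue),
fast guesses and fixation-period responses, lapses, and any asymmetry
between the two counterbalanced response mappings. Passing recovery
tests therefore demonstrates that the estimation machinery is correct
and well-conditioned at the study's design and effect sizes — not that
the model family is adequate for real behavior.

## Descriptive layer

RT preprocessing drops misses and flags log-RTs beyond 3 SD of their
mask-by-emotion cell mean (≈0.27 % per cell under a log-normal; the
removal fraction is reported, not asserted). The psychometric function
is fitted per participant and per condition (separate fits, since bias
and sensitivity are reported per condition) by binomial GLM on the
per-level counts, fillers included; the deviance against the saturated
per-level model, with df = levels − 2, drives exclusion at the χ²
95th percentile — so ~5 % of participants whose choices truly follow
the logistic are excluded by construction. Diffusion-generated cohorts
are flagged at a higher rate: the choice function of a collapsing-bound
diffusion with a starting-point offset is not exactly logistic in the
emotion fraction, and at ~300 trials per condition even small
lack-of-fit is detectable. The flag is reported per participant and the
pipeline honours it. Complete separation returns a capped slope (100 logit
units per unit fraction) with a flag instead of failing. Cohort
summaries use Wilcoxon signed-rank tests (one-sample for bias, paired
for masked-vs-unmasked sensitivity). The repeated-measures ANOVA on
condition medians is out of scope; the medians that would feed it are
produced.

## Validation experiments and problem sizes

* Engine: conservation to 10⁻³, oracle agreement, sampler–solver KS at
  10⁵ draws (tolerances above).
* Parameter recovery: simulate-and-refit at the group-mean truth with
  2,000 trials per cell and 10 replicate seeds in the acceptance script
  (5 replicates in the test suite); for every parameter, truth must lie
  within 3 recovery standard errors of the replicate mean, where the
  recovery standard error is the standard deviation of the recovered
  values across replicates (the sampling error of a single recovery),
  and the signs of `z_mask` (+) and `vc_mask` (−) — the headline
  dissociation — must be recovered in every converged replicate. At
  this precision the estimates of `a`, `τ` and `Ter0` carry small
  systematic discretization offsets (≈1 %, ≈2 % and ≈2 ms
  respectively), well inside the recovery scatter.
* Psychometric recovery: 10⁴ Bernoulli draws at the reported
  sensitivities; slopes within ±5 %.

These sizes keep the full suite and the acceptance run within desk-
scale single-core budgets (minutes, not hours) while leaving the
Monte-Carlo error well inside the stated tolerances.

## Known limitations

* The likelihood is flat in `a` and `τ` near the optimum at realistic
  trial counts (profile curvature implies a standard error of ≈0.04 on
  `a` at 24,000 trials); their point estimates scatter accordingly, and
  at 608 trials per participant individual `a`/`τ` estimates should be
  interpreted with care.
* The coarse-to-fine cascade reports the log-likelihood after a short
  full-resolution polish; residual suboptimality is below one
  log-likelihood unit in benchmarks, shared across family members, and
  therefore largely cancels in AIC/BIC differences.
* Misses are excluded rather than modelled; under parameter regimes
  with substantial undecided mass the likelihood is defective.
* The deadline and design constants (608/96/48/32/8×76, 2.3 s) are
  hard-wired as the experiment's constants; the generator is not a
  general experiment builder.
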