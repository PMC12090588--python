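# Methods

## Model and assumptions

The package treats a two-arm binomial trial with an elicited joint prior.
The control-arm response probability `p_C` has a `Beta(α, β)` prior; the
treatment effect is the log odds ratio `θ = logit(p_E) − logit(p_C)` with a
`Normal(μ, σ)` prior, assumed independent of `p_C`.  Eliciting `(p_C, θ)`
rather than `(p_C, p_E)` is what makes the independence assumption tenable:
experts' beliefs about a relative effect are largely decoupled from their
beliefs about the control rate.  The experimental-arm probability
`p_E = expit(logit(p_C) + θ)` then inherits a derived marginal prior with no
closed form.

## Quantile fitting

Experts state a few quantiles of each quantity (default levels 0.25, 0.5,
0.75, configurable — common practice in Sheffield-style elicitation).  Beta
fitting minimises the sum of squared differences between the stated
quantiles and the beta quantile function, over `log(α), log(β)` with bounds
`α, β ∈ [1e-3, 1e4]`, multi-start from method-of-moments initial values, and
objective tolerance 1e-10.  Least squares on quantiles (not on CDF values)
was chosen because it weights the statements the expert actually made.  The
Normal fit is exact: the Normal quantile function is linear in `(μ, σ)`, so
the least-squares solution is the regression of stated values on
standard-normal quantiles.  Degenerate judgements (repeated quantile values
at distinct levels) are rejected rather than fitted as point masses.

Mathematical aggregation uses the linear opinion pool — an equal-weight (or
fixed-weight) mixture of the fitted densities.  Behavioural consensus, when
a group reaches one, is simply supplied as a final judgement set and fitted
like any other; the pool is the programmatic fallback.

## Derived experimental marginal

For each evaluation point `q` the marginal density is

    f(q) = ∫ φ((t − μ)/σ)/σ · f_Beta(p(t)) · p(t)(1 − p(t)) dt,
    p(t) = expit(logit(q) − t),

the pushforward integral rewritten in `θ`, computed with Gauss–Hermite
nodes centred on the Normal prior (default 512 nodes).  This form is exact
in the `σ → 0` limit (where the marginal collapses onto the control beta)
and remains accurate for diffuse priors because the Hermite rule resolves
smooth integrands many σ wide.  The evaluation grid (default 256 points)
sits at quantiles of a moment-matched beta with geometrically refined tail
levels down to 1e-8, so mass near 0 and 1 — where the Jacobian `1/(q(1−q))`
is large — is resolved; the grid density is renormalised by its trapezoid
integral (raw integrals are within ~1e-4 of 1 and recorded in the grid
metadata).  Across the test lattice (α, β ∈ {1,…,20}, μ ∈ {−1,0,1},
σ ∈ {0.25,…,2}) the grid CDF agrees with 1e5-draw Monte-Carlo pushforwards
within Kolmogorov–Smirnov distance 0.01.

Moment matching (`k = m(1−m)/v − 1`, `α = mk`, `β = (1−m)k`) turns a grid
into a beta summary.  It was preferred to KL minimisation because it is
closed-form, reproducible, and consistent with the effective-sample-size
convention below.  `solve_log_or_prior` inverts the construction: given the
two arms' beta summaries it solves the two moment equations for `(μ, σ)` by
quadrature and a root find — useful because published consensus summaries
typically report the arm betas but not the log-OR hyperparameters.

## Effective sample size

For a beta prior the ESS is the plain sum `α + β`.  The alternative
convention `α + β − 2` (information beyond a uniform prior) is deliberately
not used; the sum is the convention under which the consensus summaries
(15.7 and 13.1, totalling 28.8) are self-consistent with their means.
Conjugate updating adds exactly `n` to the ESS.

## Endpoint classification

SUN anterior-chamber cell grades form six ordinal levels
`0 < 0.5+ < 1+ < 2+ < 3+ < 4+`, with 0.5+ a full step.  Original endpoint:
drop of ≥ 2 steps or reaching 0.  Revised endpoint: additionally any
decrease reaching 0.5+.  Patients must enter with grade > 0; one grade per
patient (a worse-eye convention, if needed, is the data provider's choice).
The revised responder set strictly contains the original one on all 30
eligible grade pairs.

## Posterior computation

The posterior over `(p_C, θ)` is computed on a deterministic 256×256 tensor
grid: `p_C` at quantiles of the conjugate control-arm update (which brackets
the true marginal), `θ` uniform over a range combining the prior (±8σ) with
a precision-weighted pairing of prior and continuity-corrected likelihood
estimate, always containing 0 as a grid node so `P(θ > 0)` needs no
interpolation.  Trapezoid rule throughout; no MCMC dependency, so results
are reproducible to quadrature error (validated against brute-force
prior-sampling oracles to within 0.01 on `P(θ > 0)` and 0.005 on posterior
means).  The control marginal is summarised by a moment-matched beta and
the experimental marginal returned as a density grid.  Credible intervals
come from grid-CDF inversion.

The final-analysis decision rule — declare superiority if posterior
`P(θ > 0) ≥ 0.95` — is the package's design choice (configurable); the
run-in data are excluded from the randomised-stage analysis by default.

## Operating characteristics

Each replicate simulates the run-in responder count, applies the 3-of-10
gate, then (conditional on proceeding) draws both randomised arms and
applies the posterior rule; stopped trials count as non-declarations.  The
declare decision is a deterministic function of the responder-count pair, so
it is memoised per pair — 2000 replicates run in seconds with no change to
any distribution.  Identical seeds give bit-identical results, and the
binomial draws do not depend on the prior, so informative-versus-uniform
comparisons at the same seed are exactly paired.

## Synthetic data

The expert generator perturbs the true distribution's quantiles with
multiplicative log-normal jitter (additive for log-OR values, which can be
near zero), re-sorts and clips response rates to (0.001, 0.999); noise 0
reproduces the exact quantiles.  Defaults emulate the study conditions:
9 experts, quartile elicitation, seed 20231010.  The trial generator draws
baseline grades from a severity mix (default 0.4/0.3/0.2/0.1 over grades
1+–4+, reflecting that mild disease is common) and constructs the week-12
grade so the marginal responder probability equals the arm's true rate
exactly, for either endpoint.  What the generators do not emulate: real
experts' systematic biases and dependence, longitudinal visit schedules,
bilateral eyes, dropout — so passing tests demonstrate correctness of the
machinery under the stated model, not robustness to those features of real
data.

## Problem sizes and numerical defaults

Default grids: 256 marginal evaluation points, 512 Hermite nodes, 256×256
posterior grid; operating characteristics use 2000 replicates (Monte-Carlo
standard error ≈ 0.011 at a rate of 0.5).  Property tests use 1e5-draw
Monte-Carlo oracles; posterior oracle checks use 1e6 draws.  These sizes
make the full test suite and the reproduction script run in well under a
minute each while keeping every tolerance comfortably met.

## Known limitations

- Independence of `p_C` and `θ` is assumed, never tested against data.
- The beta summary of the derived marginal is a moment approximation; its
  tails are slightly lighter than the true pushforward's.
- Expert weights in the pool are fixed; no performance-based weighting.
- No interim analyses beyond the single run-in gate, no dropout handling,
  no safety endpoints.
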