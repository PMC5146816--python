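# Methods

## Generative model

One replicate holds `n` independent subjects. The SNP genotype `S_i` is
the minor-allele count, drawn Binomial(2, q) — the additive coding under
Hardy-Weinberg equilibrium, giving genotype frequencies
((1−q)², 2q(1−q), q²). Treatment `x_i` (when an arm is configured) is
Bernoulli(p); the allocation probability defaults to 0.5 (a balanced
two-arm trial) and is user-overridable.

Latent event times are Weibull in the **rate convention**: survivor
function `S(t) = exp(−b_i t^a)`, hazard `h_i(t) = a b_i t^(a−1)`, with

    b_i = d0 · exp(β_s S_i + β_x x_i + β_γ S_i x_i).

This convention is load-bearing: it is the only parameterization under
which `b_i` is both the "scale-like" parameter that covariates multiply
and the betas are exactly log hazard ratios at every shape `a`. The
common alternative (mean-scale, `S(t) = exp(−(t/λ)^a)`) would flip the
effect signs. Sampling is by inverse transform,
`t = (−log U / b)^(1/a)`, `U ~ Uniform(0,1)`.

Shape semantics are the standard ones: `a = 1` constant hazard
(exponential times, proportional hazards shared with the Cox model),
`a > 1` increasing hazard, `a < 1` decreasing.

Drop-out times (scenarios 2 and 4) are exponential with **mean**
`censor_scale` — deliberately the opposite convention from event times,
so that a smaller scale means earlier drop-out and more censoring, which
is the natural control knob for a study planner. Both conventions are
stated in the config docstrings.

Recruitment times (scenarios 3 and 4) are discrete uniform on the
integers `{0, …, ⌊R⌋}` — staggered entry in whole time units (e.g.
months) — with a continuous-uniform option behind a flag, default off.

### Observation rule

All latent times are anchored at each subject's own study entry. With
horizon `H_i = Z` (scenarios 1–2) or `Z − r_i` (3–4) and drop-out
`C_i = c_i` (2, 4) or `+∞` (1, 3):

    observed_i = min(t_i, C_i, H_i),   event_i = [t_i ≤ min(C_i, H_i)].

Entry-anchoring (rather than calendar-time anchoring with a later
subtraction of `r_i`) guarantees non-negative observed times and makes
the recruitment scenarios exactly "shrink the horizon" designs.
Boundary ties (`t = Z`, `r = R`) count as events at the horizon. The
constraint `R < Z` is enforced because `R ≥ Z` would permit subjects
with zero or negative follow-up.

## Fitters

Both fitters are Newton-Raphson with step-halving (the step is halved
until the objective does not decrease), convergence when the score
max-norm drops below 1e−8 (or the relative log-likelihood change falls
below 1e−10 once the score is already below 1e−6), and a 50-iteration
cap. "Converged" is only reported when the score max-norm at the final
iterate is below 1e−6, so a converged fit always sits at a stationary
point. Divergence — monotone likelihood from perfect separation, or a
shape blow-up when all event times coincide — is detected as
`|β| > 20` on the log-hazard scale (or `|log a| > 10`) and reported as
`converged=False` with the final iterate, never raised.

**Cox.** Breslow tie handling by default (Efron selectable); with the
continuous simulated times, event-time ties have probability zero and
the two coincide, as the tests assert. Standard errors come from the
inverse observed information of the partial likelihood; tests are
two-sided Wald. The risk-set sums are suffix cumulative sums over the
time-sorted arrays, vectorized over tie groups, which keeps one fit at
n=500 around 2 ms.

**Weibull.** Full likelihood under right-censoring,

    ℓ = Σ_i [ e_i (log a + (a−1) log t_i + η_i) − e^{η_i} t_i^a ],

with `η_i = intercept + Σ β_k z_ik` and `a = e^{log a}` so the shape is
unconstrained during optimization; the shape's standard error is
delta-method (`SE(â) = â · SE(log â)`). Gradient and Hessian are
analytic and verified against central finite differences to 1e−5
relative error in the test suite. Initialization: shape from a
`log(−log S)` versus `log t` regression on the crude (censoring-blind)
survival at event times, falling back to 1.0 when degenerate; intercept
from the exponential closed form `log(events / Σ t^a)`; betas at 0.
A subject censored at time 0 contributes nothing (S(0)=1) and is masked;
an event at time 0 is a data error. The model is fit as proportional
hazards — not AFT — so β̂ estimates exactly the estimand the simulator
injects; an AFT reporting transform (−β/a) is available but off by
default, and a `fixed_shape` option gives exponential regression.

A covariate column that is constant in the sample (monomorphic SNP draw,
single-arm treatment draw) or linearly dependent on earlier columns is
flagged *inestimable* and dropped from the design; the replicate still
fits the remaining columns. A dataset with zero events raises `FitError`.

## Power engine

Replicate `j` uses the child RNG stream `SeedSequence(seed, spawn_key=(j,))`,
so replicates are independent, order-insensitive, and individually
reproducible (convergence warnings log the replicate index and master
seed for standalone re-runs). Power for a term is
`#{p < φ among evaluable replicates} / #evaluable`; the interaction
p-value comes from the same joint fit, not a separate model. The
Monte-Carlo standard error is binomial, `sqrt(p̂(1−p̂)/m)`.

Non-converged or SNP-inestimable replicates follow one of two policies:
`exclude` (default) removes them from the denominator and reports their
count — estimating power conditional on an informative, analysable
replicate — while `nonsignificant` keeps them as failures to reject,
which is conservative. Both are exposed because neither choice dominates:
exclusion can flatter power when divergence correlates with large
effects; counting-as-nonsignificant punishes designs whose small samples
often yield monomorphic draws.

Histogram summaries of β̂_s and −log10 p use Freedman-Diaconis bins
(numpy's `fd` rule), deterministic given the data; a degenerate sample
occupies a single bin. They are emitted as data tables rather than
images.

The significance threshold is validated to (0, 1]: φ = 1 is degenerate
but well-defined (every replicate rejects) and kept reachable as an
identity check.

## What the simulator does and does not emulate

It emulates the design features that drive power in pharmacogenetic
time-to-event studies: allele frequency, effect sizes on the log-hazard
scale, treatment balance, interaction, drop-out intensity, staggered
recruitment, and an administrative horizon. It does **not** model LD or
multi-SNP haplotypes, covariates beyond one SNP and one binary arm,
non-Weibull baseline hazards, informative censoring (drop-out is
independent of event risk and covariates), left truncation, or
competing risks. Passing tests therefore certify the engine's arithmetic
and its calibration under this generative family — not that a real study
with, say, informative drop-out will achieve the computed power.

## Validation strategy and problem sizes

The suite validates statistically rather than against published
end-to-end numbers, at these sizes (chosen to pin each property with
adequate Monte-Carlo resolution):

- type-I error at the null over 2000 replicates of n=500, judged against
  the exact-binomial 99% interval around 0.05, for both models;
- simulated power versus the asymptotic Wald power
  `Φ(√(E·2q(1−q))·|β| − z_{1−φ/2})` (E = expected events) at effect
  sizes spanning power 0.35–0.85, 2000 replicates each, within ±0.04;
- fitter equivalence with brute-force/grid/golden-section and
  multi-start Nelder-Mead maximization of independently coded
  likelihoods, to |Δβ| < 1e−4 on 20 random replicates;
- parameter recovery (a=1.5, d0=0.1, β_s=0.4, n=2000, Z=4.5 giving ~30%
  censoring at MAF 0.3) over 200 replicates: mean β̂ within 0.05, mean â
  within 0.1;
- the omitted-interaction bias: SNP-only analysis of data carrying
  β_s=0.4, β_x=0.3, β_γ=0.2 centres β̂_s near 0.4 + β_γ·E[x] ≈ 0.5,
  while the joint model stays unbiased — asserted directionally at
  3 MC-SE;
- exhaustive min-rule checks of all four observation scenarios, and
  exact closed forms (exponential MLE, inverse-transform quantiles,
  HWE frequencies).

lifelines serves as an independent cross-check oracle for both fitters
(its Weibull AFT estimates are mapped to the PH scale via
β_PH = −a·β_AFT); it is never the implementation.

## Known limitations

- No sample-size inversion (solving for n at target power); loop over
  `run_power_study` to bracket it.
- Replicates are fitted serially; the child-seed contract permits
  parallel execution, but none is built in.
- The Efron tie path is implemented with a per-group loop and is slower
  than Breslow; with continuous simulated times it is only needed for
  imported data containing genuine event-time ties.
- Interaction power at realistic pharmacogenetic effect sizes is low at
  the cohort sizes that power main effects; the engine reports it
  honestly rather than warning about it.
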