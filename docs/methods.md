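# Methods

## Model

An MPT model has K category systems (trees); system k has J_k mutually
exclusive categories, and a person's counts per system follow a multinomial
whose category probabilities are sums of branch probabilities

P(B_kji | θ) = ∏_s θ_s^{a_skji} (1 − θ_s)^{b_skji},

with non-negative integer exponents counting parameter occurrences along
the branch.  Jointly the counts are product-multinomial across systems.
Multinomial coefficients are included in all reported log-likelihoods so
that values, AIC and BIC are comparable across software; they cancel in
gradients and LR statistics.

In the hierarchical (latent-trait) extension, R ≤ S process parameters are
random: on the link scale (probit by default, logit optional) person t has

b_t ~ MVN(μ_t, Σ),  μ_t = μ + Γ X_t,   θ_st = link⁻¹(b_st),

while the remaining S − R fixed parameters have θ_st = link⁻¹(β_s + γ_s X_t).
For identification, intercepts of random parameters are pinned at zero (the
mean enters through μ); when all parameters are random, β vanishes
entirely.  Structural zeros in Γ/γ exclude a covariate from a parameter.
Covariates are mean-centered by default, so μ describes a participant with
average covariate values.

## Marginal likelihood and integration

The marginal log-likelihood sums, over persons, the log of an R-dimensional
integral of the conditional likelihood against the MVN density.  Every back
end is anchored at the per-person posterior mode b̂_t (maximizer of the
joint log-density l_t(b)) and curvature Ω̂_t = (−∇²l_t(b̂_t))⁻¹:

* **Laplace**: log L_t ≈ (R/2)log 2π + ½log|Ω̂_t| + l_t(b̂_t).  Exact for a
  Gaussian integrand (a person with zero counts), and identical — by
  construction and by test — to AGHQ with one node.
* **AGHQ**: a tensor-product Gauss–Hermite rule with M nodes per dimension
  (Mᴿ node vectors per person), affinely transformed by b̂_t and
  chol(Ω̂_t)·√2, with the e^{‖z‖²} weight correction; accumulated by
  log-sum-exp.  A budget guard refuses Mᴿ > 10⁶ nodes per person and points
  to QMC.
* **QMC**: the first M Halton points (prime bases, zero point skipped),
  mapped through the normal quantile and the same per-person affine map.
  Because the points then sample N(b̂_t, Ω̂_t) rather than the random-effect
  distribution, the ratio of the MVN(μ_t, Σ) density to that proposal is
  applied as an importance weight — plain "scaling" without the weight
  would target the wrong measure.  Halton generation is deterministic, so
  estimation has no random seed of its own.

Modes are found by a batched modified-Newton iteration on the analytic
b-gradient: the Hessian (finite differences of the analytic gradient, step
1e-5) is spectrally clipped at 1e-4 so the step remains an ascent direction
even where the joint density is not concave — plain Newton with a ridge
stalls on real simulated persons.  Inner tolerance: gradient sup-norm
≤ 1e-8, at most 100 iterations; non-converged persons are flagged and
reported.  Curvatures come from the same finite-difference Hessian, which
keeps arbitrary EQN models supported without hand-coded second derivatives.

## Scores and optimization

The analytic gradient of the joint log-density is implemented for every
free parameter: the multinomial part via the chain rule through branch and
category probabilities and the link derivative; the Gaussian part in closed
form, with Σ parameterized by its log-Cholesky factor (log on the
diagonal), which keeps Σ positive definite during unconstrained
optimization.  The whole score is validated against central finite
differences (relative error < 1e-5) across model structures with fixed
parameters and covariates.

The marginal gradient is the quadrature-weighted average of these scores at
the person's nodes — exactly the gradient of the fixed-node objective.  The
classical two-step scheme (full parameter pass between mode refreshes)
proved unstable: with stale modes the fixed-node objective can be inflated
almost arbitrarily far from where the modes were computed.  The optimizer
therefore **profiles the modes out**: every BFGS objective evaluation
refreshes the modes (warm-started), so mode and parameter updates
interleave at every iteration.  A final polish alternates short (≤5-step)
fixed-mode BFGS passes with mode refreshes, accepting a pass only if the
profiled log-likelihood improves; the fixed point of that alternation has
zero marginal gradient at self-consistent modes.

Starting values: link-transformed estimates from an aggregate-data
fixed-effects fit (cheap and stable) for μ and β; Σ = 0.3·I; covariate
weights 0.  R = 0 (no random parameters) degenerates gracefully: the
"integral" is a single point and the fit reduces to fixed-effects ML, which
matches an independent direct simplex optimization to 1e-5.

**Convergence** of a fit means an admissible solution: finite estimates,
positive-definite Σ, and every standard error defined and positive.
Boundary solutions (Σ̂ nearly singular, which happens at small N) typically
produce a non-invertible information matrix and are therefore counted as
failures, matching how convergence is scored in the simulation study.  The
final scaled marginal gradient norm is reported as a diagnostic message
when above 1e-4; with dense quadrature the optimum satisfies the
first-order condition sharply, while coarse quadrature leaves a small
alternation gap.

## Standard errors and intervals

The observed information is computed either by central finite differences
of the analytic marginal gradient (default) or from the exact
second-derivative expressions with quadrature-approximated inner integrals
(per-node Hessians by finite differences of the analytic scores); the two
agree to well under 2% and both hold the quadrature fixed at the final
modes.  An information matrix whose smallest eigenvalue is below 1e-8 of
its largest is treated as singular: standard errors are undefined and the
fit is flagged (this is how a structurally non-identified model presents).

Wald intervals are formed on the estimation scale of each quantity: means,
β, γ, Γ on the link scale; variances and covariances on their natural scale
via the delta method from the log-Cholesky covariance.  The reference study
does not state the scale of its coverage intervals; this choice is the
package's own and is exposed through the reported tables.

## Simulator and simulation harness

`simulate_dataset` draws b_t ~ MVN on the link scale, maps to θ_t, and
draws per-system multinomial counts; it emulates between-person parameter
heterogeneity and the product-multinomial sampling of category frequencies.
It does **not** emulate trial-level dependencies, item effects, non-normal
random effects, or response times — so passing tests demonstrate correct
behavior under the model's own assumptions, not robustness to their
violation.

The default population is the pair-clustering model with probability-scale
means (0.50, 0.40, 0.25, 0.15) and the stated link-scale covariance (its
non-zero covariances 0.08/0.04/0.03/0.07).  Means are interpreted on the
probability scale because variances of 0.50 are impossible for probabilities
with these means, and a probit mean of Φ⁻¹(0.5) = 0 would make relative
bias undefined; the generating link (unstated in the reference) defaults to
probit, following the latent-trait tradition, and is configurable.  The
80/20 split of responses across the two trees is implemented as the exact
per-cell totals 20/5, 60/15, 100/25.

The study harness reports, per design cell and parameter group (means μ;
variances σ²_b; covariances σ_bb): relative bias — means compared on the
probability scale, (co)variances on the link scale, zero-truth entries
excluded; CI coverage over converged replications; and the convergence
rate.  Per-replication seeds derive deterministically from the master seed,
and every cell carries Monte Carlo uncertainty bands (±2·SD/√reps for bias,
binomial bands for coverage) so comparisons against large reference studies
remain meaningful at reduced replication counts.

## Problem sizes used in the checked experiments

The acceptance suite runs scaled-down versions of the reference design,
chosen as fixed design points of this package: the AGHQ-3, T=75, N=125 cell
at 50 replications (bias and mean-group coverage), AGHQ-4 at 30
replications (variance-group coverage), AGHQ-5 with N=75 at 14 replications
(mean-group coverage), and a T=300, AGHQ-4 recovery cell at 10
replications.  `scripts/acceptance.py` uses the same cells at 30/20/10/5
replications.  At these sizes the Monte Carlo bands are wide; the checks
verify band coverage of the reference values, not point equality.

## Numerical choices and limitations

* Probabilities from the links are clamped to [1e-12, 1−1e-12]; category
  probabilities are floored at 1e-300 before logs; branch probabilities are
  always evaluated in log space, so large exponents cannot underflow.
* The log-Cholesky diagonal is clipped at ±12 during optimization to keep
  line-search excursions finite; the bound is far outside any plausible
  random-effect scale.
* The probit forward/inverse roundtrip is limited by float64 tail precision
  to ≈1e-8 near |η| = 6.
* LR tests assume the caller has verified nesting; only df > 0 and the
  log-likelihood ordering are checked.  The BIC sample size is the total
  number of recorded responses across persons and systems.
* Laplace is fast but known-fragile for these models (frequent undefined
  standard errors at small N); it is retained as a baseline and as the
  AGHQ(1) anchor, with AGHQ recommended as the default and QMC for large R.
* QMC fits converge less sharply than AGHQ at equal budgets (the
  approximation is more sensitive to the mode anchor), mirroring its lower
  convergence rates in the reference study.
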