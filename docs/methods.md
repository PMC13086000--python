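# Methods

## Model

`nuts4pno` estimates the four-parameter normal ogive (4PNO) item response
model for dichotomous data. Examinee *i* answers item *j* correctly with
probability

    P_ij = g_j + (1 − s_j − g_j) · Φ(α_j θ_i − β_j),

where θ_i is a latent ability, α_j > 0 an item slope, β_j a threshold on the
probit scale, g_j ∈ (0,1) the lower asymptote (guessing in achievement
testing, false endorsement in self-report scales) and s_j ∈ (0,1) the upper
asymptote shortfall (slipping, or under-reporting driven by social
desirability). Setting s ≡ 0 gives the 3PNO and g ≡ s ≡ 0 the 2PNO; the
constrained parameters are held at exactly zero and excluded from sampling,
so free item-parameter counts are 2J / 3J / 4J.

Sampling operates on the unconstrained scale (θ, α* = ln α, β, γ = logit g,
ς = logit s) with independent normal priors there. **Prior variances are
variances, not standard deviations.** Defaults (the educational
configuration): α* ~ N(0, 0.5), β ~ N(0, 2), γ, ς ~ N(−1.39, 0.5) — the
asymptote priors centre near invlogit(−1.39) ≈ 0.20 — and θ ~ N(0, 1). The
psychological configuration relaxes the asymptote priors to
γ, ς ~ N(−1.61, 0.8) (centre ≈ 0.17). Probabilities are clamped to
[1e−12, 1 − 1e−12] before any logarithm or division, because the likelihood
and the score divide by P(1 − P).

## Samplers

Both samplers are block-wise No-U-Turn samplers: each sweep updates every
ability as an independent 1-D block given the items, then every item's
(α*, β, γ, ς) as a 2–4-D block given the abilities. A transition draws a
fresh standard-normal momentum (identity mass matrix, never adapted), sets a
log-scale slice level u₀ = ξ₀ − x with x ~ Exp(1), where ξ = log posterior −
½‖r‖², and grows a trajectory by recursive doubling in random directions.
Growth stops at a U-turn of the trajectory span against either frontier
momentum, at the depth cap (default 10 doublings), or when a leaf's energy
error exceeds the divergence threshold (ξ₁ ≤ u₀ − Δmax, default Δmax = 100 —
deliberately the smaller bound this lineage of implementations uses, and
configurable). The proposal is the standard progressive draw: within a
merged subtree the second half's proposal replaces the first's with
probability n′/(n + n′) over slice-acceptable leaves, and across doublings
the new subtree's proposal is accepted with probability min(1, n_b/n_a).

**Step sizes.** Each block carries a scalar step size (the per-coordinate
step-size vector is that scalar times a vector of ones). It is initialized
by the doubling/halving search: starting at ε = 1 with a single fresh
momentum, the one-step acceptance ratio Ω fixes a direction
ρ = 2·[Ω > 0.5] − 1 and ε is scaled by 2^ρ while Ω^ρ > 2^(−ρ). The direction
is frozen after the first probe: re-deciding it each pass oscillates forever
once Ω crosses ½ (with Ω just below ½ the rule halves, the next probe's Ω
exceeds ½ and doubles back). The search is capped at 50 scalings. During
the warm-up half of the run the step size follows dual averaging toward
acceptance statistic 0.8: with k the adaptation step, H ← (1 − η_a)H +
η_a(0.8 − λ_c), ε ← exp(ι − (√k/0.05)·H), ln ε̄ ← (1 − η_b) ln ε̄ + η_b ln ε,
where η_a = (k + 10)⁻¹, η_b = k^(−0.75), ι = ln(10 ε₀) and λ_c is the
whole-transition ratio of accumulated acceptance statistics λ_a/λ_b. After
warm-up ε is frozen at ε̄. A variant using k/0.05 instead of √k/0.05 is kept
behind `sqrt_k_scaling=False` for comparison; the √k form is the standard
dual-averaging scheme this design follows.

**MMNUTS.** The mixture formulation introduces z_ij ~ Bernoulli(P*_ij), the
indicator that examinee i knows item j; given z, the response is
Bernoulli(1 − s_j) or Bernoulli(g_j). MMNUTS replaces the observed-data
score with the expected complete-data score evaluated at the posterior
responsibility z^E = y(1−s)P*/P + (1−y)sP*/(1−P). Because z^E is the exact
conditional expectation, the expected score equals the observed-data score
(Fisher identity) — verified in the tests to 1e−10 relative at random
points — so NUTS and MMNUTS target the same posterior and differ only in
the arithmetic route to the gradient. z^E is refreshed at every gradient
evaluation inside the leapfrog loop; freezing it (e.g. per iteration) turns
the gradient into an approximation of the posterior score, so the frozen
variant is exposed only at the library level (the `z_e` argument of the
mixture gradient functions) for fidelity experiments, never in fits.

**Two implementations.** `nuts4pno.nuts` is the readable reference engine
(pure NumPy, any log-density callback); `nuts4pno._engine` is the
numba-compiled specialization that `fit` uses, required to run full-size
designs (I = 2500–5000, K = 2000, several chains) in minutes on one core.
They share the algorithm but not an RNG stream, so the test suite
cross-checks them statistically: posterior means from both agree within
Monte-Carlo error on a shared small dataset, and the reference engine's
trees are checked leaf-for-leaf against an explicit iterative-doubling
oracle on shared streams.

## Estimation workflow

Initial values come from classical test theory: per item the correct rate
(→ threshold via −Φ⁻¹), the item-total Pearson correlation (→ log-slope via
ln max(0.3, 2r)), the bottom-27%-group correct rate (→ γ via logit) and the
top-27%-group error rate (→ ς via logit); per examinee the mean score rate
(→ θ via Φ⁻¹). Rates are clipped to [0.01, 0.99] and correlations to
[0.05, 0.99]; an item with zero response variance falls back to the prior
means with a warning. All chains share these centers and differ by
unit-SD normal jitter, which the between-chain convergence diagnostic
needs. The 27% extreme-group convention and the exact center mappings are
package choices (config-overridable); only the three-step outline —
CTT statistics, probit transform, unit-SD jitter — is fixed by design.

Runs default to 4 chains of K = 2000 iterations with the first half
discarded as warm-up. Convergence is declared when the Gelman–Rubin
potential scale reduction factor √(((n−1)/n·W + B/n)/W) — computed on the
natural-scale draws (α, g, s), matching how estimates are reported — is
below 1.1 for every item parameter. Point estimates and posterior SDs are
means and SDs of the pooled post-warm-up draws; ability summaries are
accumulated by running moments rather than stored draws.

Model comparison uses a marginal log-likelihood: items fixed at their
posterior means, abilities integrated over their N(0, 1) prior by
61-point Gauss–Hermite quadrature with a log-sum-exp inner sum. AIC =
−2LL + 2p and BIC = −2LL + p ln I use the free item-parameter count
p ∈ {2J, 3J, 4J} (abilities are integrated out, so they are not counted);
LR tests between nested fits report 2ΔLL with df the parameter difference.
Because the likelihood is a plug-in at posterior means rather than a
maximum, a larger model is not guaranteed a larger value when its
posterior is diffuse; this mirrors how such tables behave in practice and
is worth remembering when reading close calls.

## Synthetic data

The educational scenario draws J = 20 items with α ~ U(0.5, 3),
β ~ N(0, 1), g, s ~ U(0.05, 0.35); abilities are N(0, 1) and responses
Bernoulli from the response surface. The psychological scenario (J = 23)
matches reported moment summaries on the traditional metric (discrimination,
difficulty = β/α, guessing, slipping) using normals truncated to the
reported ranges, with a Gaussian copula giving g and s their negative
dependence (−0.308). The reported SDs sit slightly above the maximum SD a
range-truncated normal attains at the reported means (reported ranges are
sample extremes, not distribution supports), so the generator matches means
exactly and SDs as closely as the family allows, and rejects targets whose
SD would miss by more than half. An explicit true-parameter table can be
supplied instead of either generator.

The recovery harness fixes one truth draw per experiment, redraws abilities
and responses each replication, fits the 4PNO, keeps replications whose
item R-hats all fall below 1.1, and reports per-parameter bias, RMSE and
PSD (the mean of per-replication posterior SDs — chains are never pooled
into a single SD before averaging).

What the generators do not emulate: local dependence between items, ability
distributions other than N(0, 1), missing responses (rejected at load
time), and polytomous data beyond the never/else dichotomization. Passing
recovery tests therefore demonstrate correctness of the estimator under the
model's own assumptions, not robustness to their violation.

## Problem sizes and expected behavior

The full reference design (100 replications × 4 chains × K = 2000 at
I = 2500–5000) is a cluster-scale computation. The packaged tests and the
acceptance script run the same pipeline at the largest single-workstation
sizes: one full-settings educational replication (J = 20, I = 2500,
4 chains, K = 2000) for convergence and truth-correlation checks, and a
five-replication contrast of I = 2500 vs 5000 at reduced chain counts for
the sample-size ordering of RMSEs.

At these sizes the threshold β is the best-identified item parameter
(truth-estimate correlation ≈ 0.98 at I = 2500). The slope α is the
weakest: with both asymptotes free its posterior is heavy-tailed (posterior
SDs up to ~2 for extreme items), and jointly estimated abilities attenuate
it, giving truth correlations around 0.65–0.88 at I = 2500 that improve
with I. This is a property of the joint 4PNO posterior, not of the
sampler: the same engine recovers 2PNO slopes with correlation 0.99, and
conditioning on the true abilities re-centers the 4PNO item posteriors on
the truth. It matches the model's reputation of needing 5000+ examinees
for stable slope/asymptote recovery.

## Numerical choices

- Probability floor 1e−12 on P and P* before logs and divisions.
- Transform round-trips (natural ↔ unconstrained) are exact to 1e−12
  relative and tested.
- Non-finite log densities inside a trajectory mark the state divergent
  (ξ = −∞) instead of raising; divergence is tracked separately from
  U-turn stops, and a fit aborts if more than half of the retained item
  transitions diverge.
- Ties in the proposal swap (n + n′ = 0) keep the first subtree's
  proposal; the uniform is still drawn so RNG streams stay aligned across
  implementations.
- Gauss–Hermite order 61 is fixed; against a 10⁶-draw Monte-Carlo oracle
  it agrees to ~1e−4 on small cases.
- Step-size search caps at 50 doublings/halvings; the reference engine
  raises on a pathological target, the compiled engine returns the last ε.

## Known limitations

- Slope recovery at I = 2500 is attenuation-limited (see above); results
  for α and the asymptotes should be read with their posterior SDs.
- The marginal likelihood is a plug-in at posterior means, not a maximized
  or fully marginal quantity; LR statistics can be negative for
  weakly-identified nested pairs.
- No missing-data mechanism, no polytomous links, no multidimensional θ.
- The compiled engine's RNG (numba's internal generator) is seeded per
  chain and reproducible, but its streams are not interchangeable with
  numpy `Generator` streams, so reference-vs-compiled comparisons are
  statistical, not bitwise.
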