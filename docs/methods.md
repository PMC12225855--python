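# Methods

## Model and observation scheme

Households occupy one of four ordered food-insecurity states (1 food
secure, 2 mild, 3 moderate, 4 severe), derived from the FIES raw score by
the discrete cut-offs 0 / 1–3 / 4–7 / 8.  The latent trajectory is a
time-homogeneous continuous-time Markov chain with generator Λ whose 12
off-diagonal entries λ_ij (month⁻¹) are all permitted to be positive:
direct jumps that skip a severity level are allowed, and every state is
transient.  Covariates enter through transition-specific proportional
intensities λ_ij(z) = λ_ij·exp(β_ijᵀz), with z six binary indicators and
0 always the reference category (male head, head under 40, rural, not
employed, no assistance, income not reduced).

Observations are panel snapshots: the state is seen only at visit times,
never the jump times.  The likelihood contribution of a consecutive pair
(x₀ at t₀, x₁ at t₁) is therefore the matrix-exponential entry
`expm((t₁−t₀)·Λ(z₀))[x₀,x₁]`.  When covariates change between visits the
interval uses the value recorded at its **left** endpoint — the standard
panel-model convention; the data format accepts time-varying covariate
rows, so other conventions can be emulated upstream.  Exactly observed
transition times are deliberately unsupported: the survey design never
produces them.

## Estimation

The working parameters are unconstrained: log λ_ij and raw β.  The
log-likelihood is maximized by L-BFGS-B inside a generous box
(log-rates in [−40, 8]) that exists only to keep line-search trial points
out of floating-point overflow; no plausible estimate is near the box.

Intervals are grouped by (covariate pattern, interval length), so one
matrix exponential serves all pairs in a group.  The gradient is exact:
the derivative of the grouped log-likelihood with respect to the
generator is obtained from the Fréchet derivative of the matrix
exponential in adjoint form (one operation per group, independent of the
number of parameters), then chained to the working parameters.  A
spectral fast path evaluates all groups in batch via the
eigendecomposition of each pattern's generator, with divided-difference
handling of near-coincident eigenvalues (midpoint-exponential
substitution below a 1e-10 relative gap); if any eigenbasis has condition
number above 1e8 the implementation falls back to scaling-and-squaring
`expm`/`expm_frechet` per group.  Unit tests verify the analytic gradient
against central finite differences.

The covariance of the estimates is the inverse observed information,
differenced centrally from the analytic gradient (step 1e-5 relative).
Transitions with essentially no supporting events — in this model the
rare direct jumps 1→4 and 2→4 — leave directions of numerically zero
curvature, so the information matrix is inverted through an
eigenvalue-floored pseudo-inverse: eigenvalues below 1e-10 of the largest
are floored there, giving those directions an honestly enormous variance;
a genuinely indefinite information (minimum eigenvalue below −1e-6 of the
largest) flags the fit as not converged.  All intervals are 95% Wald:
log-scale (multiplicatively symmetric) for baseline rates, exp(β) hazard
ratios for covariates, delta method for hazards at arbitrary covariate
settings.  No multiplicity adjustment is applied.

Initialization is by crude rates — observed i→j consecutive-pair counts
divided by total observed time with left state i, floored at 1e-4 — with
β starting at zero.

## Candidate structures and selection

Five predefined covariate placements, all on the full 12-rate baseline:
null; all six covariates on the forward-adjacent transitions 1→2, 2→3,
3→4; on the backward-adjacent (recovery) transitions; on both adjacent
sets; and on all six forward transitions.  Selection is by minimum AIC =
−2·loglik + 2·df among converged fits, tie-broken lexicographically by
label (and logged).  Structures are also expressible as JSON for custom
placements.

## Derived quantities

- Mean sojourn time: −1/λ_ii, infinite when a state has no exit.
- Total length of stay: L_j = ∫₀ᵀ P(t)[start,j] dt by 64-node
  Gauss–Legendre quadrature on [0,T] (validated against a fine-grid
  Riemann oracle to 1e-6; the integrand is entire, so 64 nodes are far
  beyond sufficient at T = 12 months).  Occupancy summaries default to
  T = 12 months from start state 1.
- Expected visits: e_j = Σ_{i≠j} L_i·λ_ij, the expected number of entries
  into j during (0,T]; the initial occupancy of the start state is not
  counted as a visit.  Verified against exact-path simulation.
- Covariate settings for prediction: zero (baseline), sample means
  (fractional values allowed), a risk-increasing profile (female head,
  under 40, rural, not employed, no assistance, income reduced) and its
  complement.
- Prevalence goodness of fit: at each grid time the risk set is the
  subjects whose follow-up spans it; the observed state is the last
  observation carried forward (the plotted survey comparison defines no
  interpolation, and LOCF is the natural panel choice), the expected
  distribution averages P(t−t_first; z)[x_first,·] over the risk set.
- Piecewise time-inhomogeneous probabilities: epoch-wise constant
  parameters composed by ordered matrix products.  An additive
  time-varying form λ_ij(t,z) = λ_ij(t) + β_ij(t)ᵀz was considered and
  rejected because it can produce negative intensities; the multiplicative
  piecewise-constant construction is the standard alternative and keeps
  every epoch a valid generator.

## Synthetic survey generator

The generator reproduces the design the analysis assumes: five rounds at
months 0, 0.7667, 3.4667, 4.3667, 11.3667; 3,300 households; monotone
attrition parameterized by conditional continuation probabilities
calibrated so marginal per-round completion matches 3107/3058/2770/2704/
1982 out of 3,300; time-constant Bernoulli covariates; latent paths by
exact (Gillespie) simulation under Λ(z); optional FIES item emission that
draws a raw score uniformly within the state's band and scatters it over
random items, so re-scoring recovers the emitting state exactly.

Reference dynamics (`default_true_parameters`) use the published baseline
intensity estimates with covariate coefficients equal to the logs of the
published hazard ratios on the forward-adjacent transitions.  Covariate
prevalences are not published for this cohort; the defaults (female head
0.25, age ≥ 40 0.50, urban 0.45, employed 0.55, assisted 0.12, income
reduced 0.45) were fixed once as plausible values for an Ethiopian
phone-survey panel and are simulation knobs, not reproduction claims.
The same applies to the initial state distribution (0.42, 0.25, 0.26,
0.07), shaped like observed first-visit margins.

What the generator does **not** emulate: survey weights and the sampling
frame, regional stratification, non-monotone return patterns (real
panels show households skipping and re-entering rounds; completions here
are prefixes), within-round interview-timing variation, and time-varying
covariates in the default design (per-round overrides are accepted).
Passing tests therefore demonstrate correctness of the estimator under
the model's own assumptions, not robustness to these real-data features.

## Problem sizes used by the test suite

Statistical checks run at sizes chosen to make sampling noise small
relative to the tested tolerances while keeping the suite quick:
parameter recovery and Wald coverage use panels of 2,000 subjects (20
replicates for coverage); model-selection recovery uses 1,500 subjects
over 5 replicates; Monte-Carlo validation of the visit functional uses
50,000 exact paths with a sample-standard-error band; prevalence
self-consistency uses the recovery panel with a 3-percentage-point bound.

## Known limitations

- Time-homogeneity within epochs; no duration dependence inside a state.
- No misclassification (hidden-Markov) layer over the observed states,
  no random effects/frailty: all heterogeneity is through the six
  observed covariates.
- Rare transitions (1→4, 2→4 at realistic rates) are weakly identified
  at survey scale; the package reports this through very wide intervals
  rather than failing, and the floored pseudo-inverse makes that
  behaviour explicit rather than an inversion artifact.
- The crude initializer treats consecutive-pair counts as direct
  transitions; it is only a starting point and deliberately floored away
  from zero.
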