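# Methods

## Functional response with prey depletion

A closed arena with no prey replacement violates the constant-density
assumption of the Holling disc equation, so expected consumption over a
trial of length *T* is taken from the random predator equation
*Nₑ = N₀(1 − e^{−a(T − h Nₑ)})*, solved in closed form on the principal
branch of the Lambert W function. All rates are per day; a 72 h trial is
*T* = 3. Attack rate *a* (arena⁻¹ day⁻¹) and handling time *h* (days per
prey) are meaningless without their time unit, and every I/O schema carries
durations in days so fits cannot silently mix scales.

Lambert W is implemented in-house (Halley iteration; series start near the
branch point x = −1/e; a log-scale fixed point for arguments too large for
`exp`) so the solver can be validated against independent oracles — a
Newton iteration, a brute-force fixed-point solver of the implicit
equation, and SciPy's `lambertw` — rather than being its own referee.
Guaranteed absolute residual is 1e−10 on x ∈ [−1/e, 10] (internal
tolerance 1e−12); for very large arguments only a ~1e−13 relative residual
is representable in double precision. The a = 0 and h = 0 limits are
evaluated analytically, never as 0/0 limits of the W expression.

### Likelihood and fitting

The published analyses this mirrors report integer consumed counts and
maximum-likelihood estimates but not the likelihood itself; this package
adopts the standard choice for depletion designs, *C* ~ Binomial(*N₀*,
*Nₑ*/*N₀*) per trial, with the consumption probability clamped to
[1e−12, 1 − 1e−12] so the objective stays finite everywhere. The negative
log-likelihood is minimised by Nelder–Mead over (log a, log h), which
enforces positivity without constraints; default starts are a = 0.4,
h = 0.01 (the order of magnitude of published hawkfish estimates), with
five deterministically jittered restarts on failure.

Handling time is weakly identified when prey densities are low: at
densities ≤ 6 the likelihood often decreases monotonically toward h = 0.
The h = 0 sub-model (one-parameter exponential-depletion fit) is therefore
fitted alongside, kept when it matches or beats the interior optimum (ties
break toward the simpler model), and boundary estimates are *flagged*
(`h_at_boundary_`), never treated as convergence failures — on the
20-trial layout they are the expected outcome. All-zero consumption data
are handled as an explicit degenerate case: the likelihood supremum sits
at a = 0 (any parameter pair with vanishing expected consumption is
equivalent), so the fit returns a = 0 with the boundary flag set.

### Intervals and the comparison rule

The default 95% interval is the likelihood profile at the χ²(1) cutoff
(profiled nll within 1.921 of the minimum), with sides that run into a
parameter boundary reported as censored rather than extrapolated; a
nonparametric trial-resampling percentile bootstrap (≥ 200 replicates,
seeded) is available as a cross-check. Two size classes are fitted
independently and their parameters declared *distinguishable* only when
the closed 95% intervals do not intersect — a deliberately conservative
decision rule; interval overlap does not prove equality.

Simulation checks at 10× the 20-trial layout (200 trials, truth a = 0.4,
h = 0.02): median relative bias of â ≈ 2% and profile-CI coverage ≈ 95%
over 200 replicates.

## Bayesian co-occurrence model

Prey presence is zero-inflated and the field question is about risk
avoidance, so presence/absence is modelled rather than abundance. Per
species, presence on a head is Bernoulli with logit equal to the
coefficient of the head's predator category (cell-means coding: one
coefficient per level, so predictions are a direct inverse-logit of the
draws). Species are fitted independently — per-species predictions are the
output of interest and no cross-species covariance structure is specified.
The residual variance of a binary response is unidentifiable and fixed at
1; the model uses the direct Bernoulli-logit likelihood, so coefficients
are on the plain logit scale (no latent-variable rescaling convention).

Small surveys routinely contain completely separated levels (a category
whose outcomes are all 0), where the unpenalised MLE is infinite.
Independent Cauchy(0, 2.5) priors — the conventional weakly informative
scale — keep the posterior proper; the prior scale is configurable, and
shrinkage of a separated category's predicted probability toward 0.5 is
monotone in decreasing scale (verified over scales 10, 2.5, 1, 0.5).

Sampling is componentwise random-walk Metropolis. Because the cell-means
likelihood factorises by category, each coefficient's update needs only
that category's (successes, trials) sufficient statistics, making long
chains cheap. Proposal scales adapt every 50 iterations during burn-in
toward ~0.3 acceptance and are frozen afterwards, preserving detailed
balance for all retained draws. The retained-draw count is exactly
⌊(iterations − burn-in)/thin⌋. The reference configuration
(3,000,000 / 100,000 / 1000 → 2900 draws) matches the field-study scale;
the default desk configuration is 20,000 / 2,000 / 10 (1800 draws), which
recovers known presence probabilities at n = 600 to within ±0.05.
Correctness of the sampler is checked against deterministic quadrature of
the posterior on a tiny problem. Diagnostics report autocorrelation-based
ESS (ArviZ), a Geweke first-10%-vs-last-50% z-score with ESS-adjusted
standard errors, and the acceptance rate; constant chains are flagged
degenerate instead of yielding spurious statistics.

## Synthetic data

The generators define the study conditions the tests exercise.

* **Feeding assay**: two size classes × densities {2, 4, 6} over T = 3
  days, 20 trials. The source account of the assay gives two conflicting
  replicate layouts; both ship (`tabulated`, the labelled set-up, is the
  default; `narrative` is the in-text version) and both total 20 trials.
  `binomial` mode draws counts from the fitter's exact likelihood (so
  recovery tests isolate the estimator); `mechanistic` mode is an
  event-driven renewal process — exponential search at rate a·(prey
  remaining), then a handling period per capture, horizon T, no
  replacement — whose mean the random predator equation approximates
  (exactly for h = 0, within ~5% on the design grid). Handling is a fixed
  h per capture, matching the total-handling-time accounting behind the
  equation; exponential handling is an option for robustness studies.
* **Survey**: 67 heads, category probabilities (0.473, 0.333, 0.194) —
  the reported frequencies, which do not all correspond to integer counts
  of 67; the generator targets the percentages. Default presence
  probabilities are (0.40, 0.10, 0.10) for chromis and (0.55, 0.15, 0.15)
  for dascyllus: predator-free heads are favoured, small and large
  predators have identical effects, and the implied marginal presence
  (~0.24 and ~0.34) matches the reported 16/67 and 23/67 occupied heads.
  Species names are opaque labels. Coral-head dimensions are carried
  through I/O but never modelled.

What the generators deliberately omit — observation error in visual size
classification, spatial/transect autocorrelation, prey schooling and
refuge behaviour, and predator individuality — bounds what passing tests
show: they certify the estimators against their own assumed data-generating
processes (plus the mechanistic robustness check), not against every
failure mode of field data.

## Numerical and design choices

* Optimisation on the log scale with an explicit boundary sub-model, not
  penalties; ties toward the simpler model.
* Profile root-finding by bracket expansion + Brent on each side;
  non-identifiable (flat) profiles raise rather than return fiction.
* All simulators and samplers are pure functions of (spec, seed); fits are
  deterministic given data and options, so CLI outputs are byte-identical
  under a repeated (seed, config, version) triple, which every output file
  records in its header.
* Desk-scale problem sizes used in the shipped checks: 200 recovery
  replicates at 10× the assay layout; 1e5 mechanistic replicates for the
  pure-death mean; n = 600 survey for Bayesian recovery; 1800–5500
  retained draws per chain. These keep the full suite under a minute while
  leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Type III / flexible-exponent responses, predator interference and
  Bayesian functional-response fitting are out of scope.
* The binomial likelihood is this package's interpretation of the
  published MLE workflow; a quasi-likelihood treatment of overdispersed
  consumption is not offered.
* The interval-overlap rule is conservative relative to a formal test of
  parameter equality.
* Attack-rate/handling-time estimates are unit-bound; published point
  estimates whose units are unstated cannot be recomputed, only emulated.
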