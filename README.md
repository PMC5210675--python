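# coralpred

Tools for asking whether a mesopredator's body size changes its effect on
prey, the way it is asked in coral-reef field studies: a laboratory
functional-response analysis and a Bayesian presence/absence co-occurrence
analysis, plus synthetic-data generators that emulate both study designs
with known ground truth.

## Who this is for

Ecologists analysing closed-arena feeding trials (prey depleted, not
replaced) and small presence/absence surveys with a categorical predator
variable — and anyone who wants a tested, reproducible reference
implementation of the two statistical workhorses involved.

## The models

**Functional response.** Over a trial of length *T* with initial prey
*N₀*, the number eaten *Nₑ* under a Holling Type II response with attack
rate *a* and handling time *h* satisfies the random predator equation

    Nₑ = N₀ (1 − exp(−a (T − h Nₑ)))

solved in closed form with the Lambert W function,
*Nₑ = N₀ − W(a h N₀ e^{−a(T − h N₀)})/(a h)*. Consumed counts are modelled
as Binomial(*N₀*, *Nₑ*/*N₀*) and (*a*, *h*) estimated by maximum likelihood
(`RogersFunctionalResponse`, a scikit-learn-style estimator), with profile
or bootstrap 95% CIs. Two predator size classes are fitted independently
and their attack rates declared distinguishable only if the 95% intervals
do not overlap.

**Co-occurrence.** Prey presence on a coral head is Bernoulli with
logit(p) equal to a coefficient for the head's predator category
(none / small / large; cell-means coding), with independent
Cauchy(0, 2.5) priors that keep the posterior proper under complete
separation. `CooccurrenceMCMC` samples by adaptive random-walk Metropolis
and reports posterior median presence probabilities with 95% credible
intervals per species and category, plus ESS/Geweke diagnostics.

## Worked example

```python
from coralpred import (FRParams, assay_design, simulate_experiment,
                       fit_size_classes, reference_survey_spec,
                       simulate_survey, mcmc_fit, CoocConfig,
                       predictions_table)

# 20-trial feeding assay, truth: a_small=0.418, a_large=0.243, h ~ 0
design = assay_design("tabulated")
truth = {"small": FRParams(a=0.418, h=1e-4), "large": FRParams(a=0.243, h=1e-4)}
trials = simulate_experiment(design, truth, mode="binomial", seed=7)
res = fit_size_classes(trials)
for cls, fit in res["fits"].items():
    iv = fit.intervals["a"]
    print(f"{cls}: a = {fit.params_hat.a:.3f} "
          f"(95% CI {iv.lower:.3f}-{iv.upper:.3f}), h at boundary: {fit.h_at_boundary}")
print("attack-rate verdict:", res["attack_rate_verdict"])
```

prints

```
small: a = 1.302 (95% CI 0.303-2980.958), h at boundary: False
large: a = 0.187 (95% CI 0.099-0.391), h at boundary: True
attack-rate verdict: indistinguishable
```

Twenty trials at densities 2–6 are too few to pin down handling time: the
large-class fit lands on the *h* = 0 boundary (flagged, not failed) and the
small-class likelihood has a long *a*–*h* ridge, hence the huge upper CI —
exactly the behaviour this design produces in practice, which is why the
comparison rests on attack rates. The verdict says the two classes cannot
be told apart at these sample sizes.

```python
# 67-head survey, prey commoner on predator-free heads
survey = simulate_survey(reference_survey_spec(seed=7))
chains = mcmc_fit(survey, CoocConfig(seed=1))
print(predictions_table(chains).round(3).to_string(index=False))
```

prints

```
  species category  point  lower  upper  data_absent_level
  chromis     none  0.442  0.281  0.604              False
  chromis    small  0.094  0.016  0.248              False
  chromis    large  0.091  0.006  0.312              False
dascyllus     none  0.562  0.391  0.720              False
dascyllus    small  0.184  0.067  0.367              False
dascyllus    large  0.172  0.037  0.426              False
```

Presence probability is highest with no predator, and the small/large
credible intervals overlap heavily — the predator's effect, not its size,
carries the signal.

The same pipeline is available from the shell:

```sh
coralpred report --seed 7 --out-dir out/   # both analyses + figures
coralpred compare-fr --lower1 0.254 --upper1 0.983 --lower2 0.164 --upper2 0.502
```

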