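# dielmeta

Phylogenetic multilevel meta-analysis of **diel pollination differences** —
does plant reproductive success differ when only daytime or only
night-time pollinators have access to flowers?

Pollinator-exclusion experiments bag flowers during one diel period, so
reproduction (fruit set, fruit mass, seed set, seed mass or pollen
deposition) can be compared between *day* and *night* pollination, and
against *open* (never bagged) and *closed* (always bagged) controls.
`dielmeta` turns the treatment-level summaries of such experiments
(mean, SD, n per arm) into a complete meta-analytic pipeline for
ecologists synthesising this literature:

- **Effect sizes.** Hedges' g (standardised mean difference with the
  small-sample correction J = 1 − 3/(4(n₁+n₂−2)−1)) with sampling
  variance vᵢ = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)), for four comparisons:
  night vs. day, day vs. open, night vs. open and open vs. closed (the
  plant's pollination dependency). Fruit-set counts get theoretical
  binomial SDs; remaining missing SDs are regression-imputed from n,
  mean and treatment within each outcome metric.
- **Covariates.** Photoperiod from the CBM daylength model (latitude ×
  day of year), a *diel exposure quotient* correcting for imbalanced
  exclusion times, plus user-supplied daily temperature range and
  elevation.
- **Models.** A hand-rolled REML engine for multilevel meta-analysis with
  known sampling variances and five crossed random effects — study,
  outcome metric, phylogenetic species effect (covariance from a dated
  tree under Brownian motion), non-phylogenetic species effect, and an
  observation-level effect:

  V = Σₖ σ²ₖ Zₖ Aₖ Zₖ′ + diag(vᵢ)

  maximising the restricted likelihood
  −½[log|V| + log|X′V⁻¹X| + y′Py]. Because every Zₖ is a group
  indicator, V is diagonal-plus-low-rank and the engine works entirely
  through the Woodbury identity with analytic gradients — fits with
  k ≈ 1200 effects take about a second, which is what makes the
  simulation-based calibration suite affordable.
- **Inference.** Multilevel I² heterogeneity decomposition, omnibus QM
  (Wald) moderator tests with Benjamini–Yekutieli adjustment, marginal
  R², marginal means, species-level BLUP predictions, and Pagel's λ on
  those predictions.
- **Diagnostics.** Funnel data, a multilevel Egger regression (SMD on its
  SE inside the full random structure) and a time-lag test.
- **Synthetic data.** A generator that emulates the whole input schema
  (arms, counts, missing-SD pattern, traits, environments, tree) from
  known ground-truth parameters, so the entire pipeline and all recovery
  experiments run offline.

## Worked example

```bash
python analysis/01_simulate_dataset.py
python analysis/02_effect_sizes.py
python analysis/03_overall_models.py
python analysis/04_moderator_models.py
python analysis/05_publication_bias.py
```

`03_overall_models.py` prints, for the simulated study set (120 studies,
130 species, ground truth: overall SMD 0, exposure-quotient slope −0.1,
σ² = 0.2/0.02/0.05/0.5/0.3 for study/metric/phylo/non-phylo/observation):

```
night_vs_day: SMD +0.098 (z = 0.30, k = 360), total I^2 = 88%
  lambda = 0.000 (p = 1.000); 25/115 species with CI excluding 0
day_vs_open: SMD -1.046 (z = -2.21, k = 302), total I^2 = 66%
  lambda = 0.515 (p = 0.000); 109/109 species with CI excluding 0
...
open_vs_closed: SMD +1.937 (z = 15.09, k = 193), total I^2 = 87%
```

Read: the overall night-vs-day difference is indistinguishable from zero
(as simulated); ~88% of the variance in those effect sizes is
heterogeneity rather than sampling noise, most of it from the
non-phylogenetic species effect; the phylogenetic signal in the
species-level predictions is absent (λ = 0 — the true phylogenetic share
was small); a minority of species still show individually significant
diel differences, as expected under a large species-level variance; and
plants strongly depend on pollinators overall (open vs. closed SMD ≈ +1.9).
`04_moderator_models.py` then finds pollination dependency as the one
moderator surviving Benjamini–Yekutieli adjustment — dependency is built
into the generator's open/closed arms, so this is the expected positive
control.

Library use in a few lines:

```python
from dielmeta import (SyntheticConfig, simulate_effects, RandomEffect,
                      reml_fit, i2_multilevel)
import numpy as np

eff, truth = simulate_effects(SyntheticConfig(seed=1))
X = np.column_stack([np.ones(len(eff)), eff["exposure_quotient"]])
fit = reml_fit(eff["yi"], eff["vi"], X,
               [RandomEffect("study", eff["study_id"]),
                RandomEffect("metric", eff["metric"]),
                RandomEffect("species_phylo", eff["species"], truth["corr"].to_frame()),
                RandomEffect("species_nonphylo", eff["species"]),
                RandomEffect("obs", eff["obs_id"])],
               coef_names=["intercept", "quotient"])
print(fit.coef)            # estimates, SEs, z, p, 95% CIs
print(fit.sigma2)          # the five variance components
print(i2_multilevel(fit))  # total I^2 and per-component shares
```

Real datasets enter through `dielmeta.pipeline.run_pipeline(config, outdir)`
with a YAML/dict config pointing at a treatment CSV, trait CSV, covariate
CSV and Newick tree (see `docs/methods.md` for the schemas and every
tunable default).

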