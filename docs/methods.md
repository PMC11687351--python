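# Methods

## The problem and the model

Pollinator-exclusion experiments measure plant reproductive success when
flowers are accessible to pollinators only by day, only by night, always
(open) or never (closed). Synthesising that literature poses three linked
statistical problems: (i) converting heterogeneous treatment summaries
into comparable effect sizes, (ii) modelling a deeply hierarchical
dependence structure — several effect sizes per study, several outcome
metrics, and species that share evolutionary history — and (iii) asking
which environmental conditions and floral traits explain between-species
differences.

For each study × species × outcome-metric group, effect sizes are
Hedges' g: the mean difference between a focal and a reference arm
divided by the pooled SD, times the small-sample correction
J = 1 − 3/(4(n₁+n₂−2)−1), with sampling variance
vᵢ = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)) (the g-based quadratic term; the
uncorrected-d alternative differs at O(1/n²)). Sign conventions are fixed
in code: night vs. day positive when night pollination wins; day/night
vs. open negative when a single diel period underperforms full access;
open vs. closed (pollination dependency) positive when animal visitation
matters. Effects with |g| > 10 are set aside as extreme values before
modelling (the boundary itself is kept).

The core model for one comparison's k effects is

    y = Xβ + Σₖ Zₖuₖ + e,   uₖ ~ N(0, σ²ₖAₖ),   e ~ N(0, diag(vᵢ)),

with five random components: study, outcome metric, a phylogenetic
species effect (A = Brownian correlation from a dated ultrametric tree:
shared root-to-MRCA depth divided by tree height, root edge excluded, the
ape `vcv` convention), a non-phylogenetic species effect (A = I), and an
observation-level effect. X always carries an intercept and the diel
exposure quotient (below). Estimation is REML; the restricted
log-likelihood includes the conventional +½log|X′X| constant so values
are directly comparable with the standard meta-analytic software. Wald
z statistics and normal-based 95% CIs (no small-sample t adjustment) are
the significance convention throughout.

## Numerics

V is never formed densely. Components with one level per observation are
folded into the diagonal D = diag(vᵢ) + σ²_obs; every other component is
a low-rank block Zₖ Lₖ (Lₖ the Cholesky factor of Aₖ), so
V = D + ŨŨ′ and all solves and log-determinants go through the Woodbury
identity / matrix determinant lemma. Because the Zₖ are one-hot
indicators, the inner q × q Gram matrix is assembled from weighted
cross-tabulations in O(k) per block pair, and the REML gradient

    ∂ℓ/∂σ²ₖ = −½[tr(P Cₖ) − (Py)′Cₖ(Py)],  Cₖ = ZₖAₖZₖ′

reduces to q-dimensional algebra. Optimisation is L-BFGS-B on log σ²
(bounds keep σ² in [1e−12, 1e8]) with analytic gradients, three
deterministic starts (a moment-based split of the excess variance, ×10
and ×0.1), early-stopped when two starts agree to 1e−8; estimates below
1e−10 are reported as exactly 0. The engine is verified against dense
brute-force likelihood evaluation (1e−8) and against `metafor::rma.mv`
(including a phylogenetic R matrix) in the test suite; a fit with
k ≈ 1200 and five components takes ~1 s on one core, which sets the
budget for the calibration experiments.

Downstream quantities:

- **Multilevel I²** uses the typical sampling variance
  ṽ = (k−1)Σwᵢ / ((Σwᵢ)² − Σwᵢ²), wᵢ = 1/vᵢ; per-component shares
  σ²ₖ/(Σσ² + ṽ) sum to the total by construction.
- **QM** is the Wald chi-square on the moderator coefficients (all
  non-intercept, non-quotient columns); QE is the fixed-effects residual
  chi-square with weights 1/vᵢ.
- **Marginal R²** = var(Xβ̂)/(var(Xβ̂) + Σσ²ₖ), clamped to [0, 1]
  (sample variance over observations, ddof 1).
- **Marginal means** for categorical moderators use cell-means coding
  with every other column (in practice the exposure quotient) held at its
  observed mean.
- **Species predictions** are l′β̂ + BLUP(phylo) + BLUP(non-phylo), with
  BLUPs σ²ₖAₖZₖ′V⁻¹(y − Xβ̂) and l the observed design mean. The SE is
  the conditional prediction-error variance
  var(t) − c′V⁻¹c + (l − X′V⁻¹c)′(X′V⁻¹X)⁻¹(l − X′V⁻¹c), i.e. it
  accounts for the estimation of β; the marginal alternative was
  considered and rejected as it ignores the shrinkage already present in
  the BLUP.
- **Pagel's λ** is estimated on the species predictions by bounded
  scalar ML on [0, 1] (xatol 1e−6), with the GLS mean and σ² profiled at
  each λ; λR + (1−λ)I is the working correlation. The LRT p-value
  against λ = 0 is halved (χ²₁ boundary mixture), with p = 1 at LR = 0
  and for flat likelihoods (star trees). Numerically singular
  correlations at λ → 1 (effectively identical tips) are treated as
  unattainable rather than fatal.
- **Benjamini–Yekutieli** adjustment of the moderator-family QM p-values
  is applied once per comparison type, matching how the model families
  are reported.

## Covariates and imputation

- **Daylength** follows the CBM photoperiod model; the horizon
  coefficient p defaults to 0.8333° (sunrise/sunset with refraction,
  the convention of the common daylength implementations) and is
  configurable, with p = 0 giving the sun-centre definition. Polar
  day/night fall out of clamping.
- **Experiment timing**: day of year of the midpoint between the 15th of
  the start and end months (month-arithmetic midpoint; an odd month span
  takes the day-midpoint between the two adjacent month-15ths), wrapping
  across the year boundary.
- **Diel exposure quotient**: day/night exposure hours for the
  night-vs-day comparison, period/24 h for the open comparisons, 1 for
  open vs. closed. Stated exposure hours pass through; missing ones are
  imputed from daylength (day + night = 24 exactly). The quotient enters
  the fixed part uncentred.
- **Missing SDs**: within each outcome metric, SD is regressed on n,
  mean and treatment; seed set uses the full factorial
  n × mean × treatment (11 model df with three treatment levels), the
  sparser metrics additive terms. Predictions are floored at
  max(0.01 × arm mean, 1e−8); fruit-set count arms instead get the
  theoretical per-flower binomial SD sqrt(p(1−p)) with n = number of
  flowers, using the continuity-corrected p = (x+0.5)/(n+1) for the SD
  only when x ∈ {0, n} so pooled SDs stay positive.
- **Study year**: a missing year is the publication year minus the mean
  publication lag of the complete rows, rounded half-up.
- **Daily temperature range and elevation** are consumed from a
  per-study covariate CSV; raster extraction is upstream preprocessing,
  not part of this package.

## Trait handling and moderator models

Trait recodes (capitulum → open flowers; blue → purple; brown → yellow;
missing anthesis time → "both"; the non-photosynthetic holoparasite
*Mitrastemon yamamotoi* excluded) are table-driven and logged.
Collinearity screening reports Pearson r (continuous pairs), Cramér's V
(nominal pairs) and one-way R² (mixed pairs) with a configurable 0.7
flag threshold; flower width/length/style length form the expected
correlated cluster in synthetic data, and style length is the retained
size measure. Moderators are tested one at a time (linear and quadratic
variants for continuous ones) because their mutual dependence makes
multi-predictor models uninterpretable here; the metric moderator drops
the metric random term (the "reduced" preset). Quantitative trait gaps
are left missing (complete-case per model).

## The synthetic-data generator

The generator emulates the structure of this literature: ~120 studies ×
~130 species on a pure-birth tree (height 1), 1–3 experiment groups per
study, a metric mix dominated by fruit set (56%) and seed set (35%),
group sizes 10–40, day/night arms always present, open arms in 84% and
closed arms in 65% of groups, binomial fruit-set counts, ~3% missing SDs
on continuous arms, and study-level geography/seasons that drive
daylength and the exposure quotient. Ground truth defaults to no overall
diel difference (β₀ = 0), a modest negative exposure-imbalance slope
(−0.1), and variance components (0.2, 0.02, 0.05, 0.5, 0.3) for
study/metric/phylo/non-phylo/observation — i.e. heterogeneity dominated
by the non-phylogenetic species effect with small phylogenetic
structure, the regime the exclusion-experiment literature appears to
occupy. A master seed spawns one stream per table, so outputs are
byte-identical across runs and adding a table never perturbs existing
draws.

Two generator levels serve different purposes. The *effect-level*
simulator draws yᵢ ~ N(Xβ + ΣZu, vᵢ) with vᵢ known and independent of
the random effects — model-exact, used for the sharp recovery and
calibration experiments. The *arm-level* simulator generates Gaussian
sample means and χ²-distributed sample SDs (and logit-shifted binomial
counts for fruit set, clipped to [0.02, 0.98] with clips counted) so the
computed Hedges' g is centred on the group's true SMD; it exercises the
full input schema but induces the target SMD only approximately for
binomial outcomes, so integration tests use it qualitatively. Passing
recovery tests therefore demonstrate correctness of the estimator under
the stated model, not robustness to real-data pathologies (digitisation
error, non-normal outcomes, correlated sampling errors within studies),
which the generator deliberately does not simulate.

## Publication-bias diagnostics

The Egger-type test refits the full multilevel model with sqrt(vᵢ) as an
uncentred moderator and reports the intercept (the effect at SE → 0):
a significantly nonzero intercept flags small-study asymmetry. Its
calibration null is therefore a zero overall effect, and sign-symmetric
suppression of small studies is invisible to it by construction — the
power experiments use one-directional selection (small studies published
only when significantly positive), the classic funnel-asymmetry
mechanism. The time-lag test adds mean-centred publication year and
reports the slope.

## Problem sizes and runtime choices

The calibration suite runs at the scale the estimator is meant for:
100 replicates of k ≈ 1200 effects / 130 species / 120 studies for
parameter recovery (~3 min), 1000 replicates of k = 400 for Wald-test
type-I error (~30 s, using a study + observation structure; the
five-component structure is covered by the recovery experiment), and
200 replicates per λ scenario. Grid-search brute-force comparisons use
k ≤ 12 fixtures where dense evaluation is exact and cheap.

## Known limitations

- The phylogenetic/non-phylogenetic species split is weakly identified
  when the phylogenetic share is small: its REML split shows a small
  finite-sample transfer toward the phylogenetic component (their sum is
  recovered without bias). This is a property of the estimator, shared
  with the reference R implementation, not of this implementation.
- Sampling variances are treated as known; no robust (sandwich) or
  cluster-bootstrap alternatives are provided.
- The λ p-value convention (boundary-halved LRT) is one of several in
  use; the unhalved value is recoverable by doubling.
- No selection-model or trim-and-fill bias corrections — diagnostics
  only.
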