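# Methods

This note documents the statistical models implemented in `tubertrace`,
the defaults chosen where the underlying methods admit variants, what
the synthetic-data generator does and does not emulate, and known
limitations.

## Presence, and the vertical/horizontal classification

Presence is a pre-normalization concept: a taxon is *present* in a design
cell (generation × compartment × cultivar × field) if it has at least
`min_count` raw reads in at least `min_prevalence` samples of that cell.
The defaults (1 read, 1 sample) are the weakest rule under which reported
taxon counts are plain set sizes; raising either threshold shrinks every
presence set monotonically.

Two baselines define "vertically transferred" at generation *g* with
present set `A_g` and seed set `A_0`:

- `seed_baseline`: vertical = `A_g ∩ A_0` — used for per-generation
  vertical/horizontal percentages (denominator `|A_g|`);
- `chain`: vertical = `A_g ∩ A_{g−1} ∩ … ∩ A_0` — presence in every
  prior generation, used for "transferred across all generations"
  statements and for the stage-flow (Sankey) tables, where each stage's
  retention percentage is relative to the previously retained set.

Both modes agree at the first transition and partition `A_g` exactly.
Seed tubers predate the field trials and carry the explicit field level
`"(none)"`; when a context names a field, the seed baseline is the
no-field seed cell of the same cultivar and compartment (one seed lot
feeds every field), and a generation grown at a single field (the
daughter stage) backs any field's chain. Reported percentages are kept
exact and additionally rounded half-away-from-zero to integers for
presentation.

## CSS normalization

Cumulative sum scaling divides each sample's counts by the sum of its
counts up to a quantile of the sample's *nonzero* count distribution,
then rescales by a global constant so magnitudes stay comparable to
counts. The exact conventions here, chosen so the operation is
deterministic and oracle-testable:

- quantile of the nonzero counts with the nearest-rank (≤) rule: the
  value at 1-based index `ceil(q·m)` of the sorted nonzero vector of
  length `m`; default `q = 0.5`;
- scaling factor `s_j` = sum of counts ≤ that quantile value;
- global rescale `R` = median of the `s_j` (or fixed 1000).

An adaptive mode picks the smallest quantile at which the median
relative change of `s_j` between successive quantile levels exceeds an
instability threshold (default 0.1). CSS implementations differ in these
details; results here may differ from any particular reference
implementation. Because no published quantile is canonical, downstream
analyses expose both CSS-then-proportion and plain-proportion inputs
(`transform="css"` / `"proportion"` in the heritability screen; CSS is
the default since normalization is applied globally before downstream
statistics).

## Transfer-probability model

The unit of observation is the context: one row per compartment ×
cultivar × field × transition, with `trials` = taxa present at the
baseline generation (chained) and `successes` = those retained at the
next generation. The model is a binomial logit GLM fitted by IRLS
(convergence when the largest coefficient change drops below 1e−8,
at most 100 iterations). Choices:

- **Fixed effects + optional sandwich, not a random-intercept GLMM.**
  Field-level dependence is handled by cluster-robust (HC0-style)
  standard errors clustered on field rather than by integrating a random
  intercept; this keeps the estimator closed-form and exactly testable,
  and matches settings where field variation is negligible. Note the
  sandwich collapses to zero in a saturated model (residuals vanish), so
  robust and model-based covariances are *not* interchangeable there;
  robust SEs are validated against an independent GLM implementation
  instead.
- **Wald χ² with sum-to-zero (Type-III) contrasts**, so term tests do
  not depend on the reference level. Treatment coding is available
  (`coding="treatment"`); the term χ² is invariant to the choice.
- **Marginal probabilities** per factor level: the linear predictor is
  averaged over the levels of the other factors (balanced average),
  inverse-logit transformed, with 95% CIs computed on the logit scale by
  the delta method and mapped through the inverse logit — bounds stay in
  [0, 1].
- **Overdispersion** via a quasi-binomial Pearson dispersion scalar
  (`quasi=True`) instead of an observation-level random effect.
- **Separation**: if any fitted probability is pinned at 0/1 the ML fit
  aborts with advice to use `bias_reduced_fit`, a Firth-type
  penalized-likelihood fit (Jeffreys-prior score adjustment,
  `U* = Xᵀ(y − mμ + h(½ − μ))` with `h` the leverages of `W^{1/2}X`),
  which always returns finite coefficients and approaches the ML fit at
  o(1/n) on well-behaved data.

Paired vertical-vs-horizontal count comparisons use the Wilcoxon
signed-rank test: zeros dropped, exact two-sided p by full sign
enumeration when the effective n ≤ 12 with tie-free absolute
differences, otherwise the normal approximation with tie and continuity
corrections. Multiplicity is controlled with Benjamini–Hochberg
(step-up, `adj_(i) = min_{j≥i} p_(j)·m/j`, capped at 1).

## Broad-sense heritability

Per taxon, within one cultivar–compartment cell (fields pooled, since
generation is the model's only grouping factor), abundances are taken to
relative scale, transformed as `log10(x + 10⁻⁶)` (an absence maps to
−6), and fitted with the one-way random-effects model
`y_ijk = μ + G_i + ε_ijk`. H² = VG/(VG+VE) is the intraclass
correlation of generation.

**Estimation.** REML, profiled to one dimension in the ratio
λ = VG/VE on [0, 10⁶]. The profiled criterion is
`(N−1)·log Q(λ) + Σ log(1+λn_i) + log Σ w_i` with `w_i = n_i/(1+λn_i)`
and `Q` the weighted residual sum of squares; its analytic derivative
has a single sign change, so the optimum is found by bisection on the
derivative (accurate to machine precision, beyond the √ε limit of a
value-only search) and truncated at the boundary VG = 0. On balanced
layouts with an interior optimum the solution coincides exactly with the
ANOVA method-of-moments estimator `VG = (MSB − MSW)/n₀`, `VE = MSW`,
which serves as an independent oracle. Degenerate inputs: zero total
variance → VG = VE = 0, H² = 0 (with a warning); zero within-group
variance → VE = 0, H² = 1.

**Significance.** B = 999 (default) uniform random permutations of the
full generation-label vector, unstratified; H² recomputed per
permutation; `p = (1 + #{H²_perm ≥ H²_obs})/(1 + B)`, ties counted as
extreme (conservative, p > 0 guaranteed). Comparisons use a 1e−9
tolerance so permutations equivalent to the observed labelling are not
lost to floating-point noise. An exhaustive mode enumerates all N!
label orders for small layouts and returns the exact null proportion.
BH adjustment is applied across the taxa of a screen.

**Bias with few generations.** With only three generation levels the
between-group mean square has 2 degrees of freedom, so H² estimates are
noisy and their *median* sits below the truth at moderate H² (≈0.21 at
a true 0.3 with 10 replicates per generation); recovery claims should be
read against that inherent small-k behaviour, which the estimator shares
with any one-way variance-component fit.

## Community statistics

- Alpha diversity: richness (taxa with value > 0), Shannon `H = −Σ p ln p`
  (natural log; documented because conventions differ), Pielou
  `J = H/ln(richness)` (undefined for single-taxon samples).
- Bray–Curtis `d = Σ|x−y| / Σ(x+y)`, computed on CSS-normalized values
  for community comparisons.
- PERMANOVA: Gower-centred squared dissimilarities, sequential (Type-I)
  sums of squares in model-formula order via projection matrices — so
  multi-term models and interactions partition SS exactly additively —
  pseudo-F against the residual, and p-values from raw-data permutations
  of the samples, `(1 + extreme)/(1 + B)` with B = 999 by default and an
  exhaustive option for small N.
- Kruskal–Wallis with tie correction, and Dunn's pairwise z from pooled
  rank means with tie correction, BH-adjusted across pairs (applied
  whenever more than one pair is tested).

## The synthetic-data generator

The generator emulates the processed data of a three-generation seed
tuber trial, with defaults set to the emulated design: 2 cultivars, 10
replicate tubers per cell, seed founder pools of 120 (flesh) and 200
(peel) taxa per cultivar (≈320 founder taxa, the scale of a seed tuber
community), per-transition retention 0.20 (flesh) and 0.15 (peel) —
mean founder retention ≈18% per transition, higher in flesh —
horizontal pools that grow across generations and dominate in peel
(250/500 at the daughter stage; 400/1200 per field at the granddaughter
stage, plus a 1500-taxon tare-soil pool sharing 40% of the peel pool),
daughter tubers grown at the first field only and granddaughters at two
fields. Abundances: founder baselines log10-normal (mean −3, sd 1);
retained non-null taxa get a per-(taxon, generation) offset with
variance `vg = 0.4` shared by every sample of that generation and a
per-sample residual with variance `ve = 0.4` (true H² = 0.5); a 35%
null fraction has VG = 0. Reads: per-sample lognormal library size
(mean 30,000, σ = 0.3) and gamma–Poisson counts with dispersion 0.1.

Because generation offsets are shared across cultivars' samples, fields
and replicates, the one-way random-effects model *is* the generating
model, making parameter recovery a meaningful check. The detection
guarantee (every taxon marked present gets ≥1 read in each sample of its
cells; on by default, switchable off) separates classification logic
from stochastic detection: with it on, presence/absence classification
agrees with the truth ledger for 100% of taxa; with it off, low-abundance
taxa drop out and classification inherits detection noise.

What the generator does **not** emulate: taxonomy and phylogeny,
chimeras and sequencing error, compositional correlations between taxa
(abundances are independent given the design), per-sample renormalization
effects shared across taxa (which slightly inflate apparent
between-generation variance in the full pipeline), cultivar-shared
founder taxa, and the exact field layout of a real trial. Tests passing
on this generator therefore validate the *arithmetic and estimators*,
not robustness to real-data artefacts such as contamination or index
hopping.

## Reproducibility

Every stochastic routine takes an explicit seed or `numpy` Generator.
The CLI derives per-module streams from a single run seed by hashing the
module name (CRC32, keeping seeds below 2³¹), so stages are reproducible
independently; `full-analysis` writes a JSON manifest with input
parameters, the seed and SHA-256 checksums of every output, and two runs
with the same configuration and seed produce identical checksums.

## Problem sizes used in the test suite

Checks that need replication use deliberately modest sizes — 500
simulated taxa for recovery/calibration, B = 199 permutations for
calibration runs (999 remains the analysis default), N = 6 samples for
exhaustive PERMANOVA enumeration, 200 random matrices for the CSS
oracle — chosen to give stable rates (binomial SEs of a few tenths of a
percent) while keeping the suite quick to run.
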