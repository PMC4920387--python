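# Methods

This note documents the statistical conventions the package implements, in
enough detail to reproduce every number it prints.

## Study design

The experiment has 96 plots in 8 blocks of 12. Each block holds the same 12
sown compositions: 4 monocultures (one pool's species), 4 two-species
mixtures and 2 four-species mixtures per block, drawn from two fixed pools
of 4 species each (one grass-dominated, one forb-dominated; species are
additionally classed by growth stature, small vs tall). Shade is applied to
whole blocks (4 of 8 shaded); fertilization is applied to half the plots
within every block (6 of 12). Every composition therefore appears once in
each of the four environments (shade × fertilization). Monoculture
reference yields are taken from the matching environment, averaging
replicates when more than one monoculture of a species exists there.

## Overyielding metrics

For a mixture with observed species yields `Y_i`, monoculture references
`M_i` and sown proportions `q_i` (equal, `1/S`, throughout the design):

- Relative yield `RY_i = Y_i / M_i`; relative yield total `RYT = Σ RY_i`.
- Non-transgressive overyielding `D_mean = (Y_O − M̄) / M̄` with
  `Y_O = Σ Y_i` and `M̄ = mean(M_i)`.
- Transgressive overyielding `D_max = (Y_O − max M_i) / max M_i`.

`D_mean` and `RYT` are linked exactly under equal sown proportions by
`D_mean − (RYT − 1) = S · cov(RY, M) / M̄` (population covariance), so
`D_mean = RYT − 1` only when relative yields are uncorrelated with
monoculture yields (for example uniform `RY` or equal monocultures). The
package treats the two statistics as distinct and reports both.

## Tripartite partition of the net diversity effect

With `ΔRY_i = RY_i − q_i` and population (divide-by-S) covariances:

- Net effect `NE = Y_O − Σ q_i M_i`
- Trait-independent complementarity `TICE = S · mean(ΔRY) · M̄`
- Dominance `DE = S · cov(M, RY/RYT − q)`
- Trait-dependent complementarity `TDCE = S · cov(M, RY − RY/RYT)`

These satisfy `NE = TICE + TDCE + DE` identically. The two-part additive
partition (complementarity `CE = TICE`, selection `SE = TDCE + DE`) is also
reported and doubles as an internal consistency check. Mixtures whose
monoculture reference is zero for any sown species are excluded and logged
with a reason; percent gains are reported with the ratio-of-means
convention by default (`100 · mean(component) / mean(expected biomass)`).

## Community-level inference

The community model regresses log total biomass on shade, fertilization,
log richness, functional-group composition and growth-stature composition
plus their two- and three-way interactions with the environment terms, with
block and sown composition as random terms. Fitting is a sequential
(type-I) decomposition: random terms define error strata, each fixed term's
expected mean square is matched to a non-negative combination of stratum
mean squares (non-negative least squares on the variance-component
coefficients), and denominator degrees of freedom follow Satterthwaite's
approximation. With block as the only random term this reproduces the
classical split-plot analysis exactly (shade tested against the
between-block stratum with 1 and 6 df). In the full model the composition
random term crosses blocks, so the block stratum is not a pure whole-plot
error and the matched denominator legitimately differs from the naive
block-means F.

Kenward–Roger denominator degrees of freedom are not implemented and
requesting them raises `NotImplementedError`; the supported alternatives
are Satterthwaite (default) and design-based permutation.

### Permutation tests

The permutation method re-randomizes a term's assignment within its design
orbit and recomputes the term's F statistic. For shade the orbit is the
C(8,4) = 70 ways of shading 4 of 8 blocks; it is enumerated exhaustively
and the p-value is `#{F* ≥ F} / 70` (the identity assignment included), so
attainable p-values are multiples of 1/70. For fertilization the orbit
(within-block half assignments) is sampled, and the p-value is
`(1 + #{F* ≥ F}) / (1 + n_perm)`. Terms not listed in `perm_terms` keep
their Satterthwaite stratum-F p-values, annotated as such.

### One-sample tests

`test_mean_against` is a two-sided one-sample t test (optionally on block
means). When the sample variance is exactly zero, the test reports `t = 0,
p = 1` if the mean equals the reference ("exact equality") and `t = ∞` with
an undefined (NaN) p otherwise; both cases carry an explanatory note.

## Trait composition and multimodel inference

Community-weighted means (CWM) weight environment-specific trait values by
sown-species biomass shares; functional diversity is Rao's quadratic
entropy `Q = Σ_ij p_i p_j d_ij` with absolute trait distance by default
(range-scaled Gower optionally). Right-skewed traits are log-transformed
before CWM/FD computation. The predictor matrix holds CWM and FD for each
of six traits (12 predictors); rows with undefined predictors (e.g. zero
functional diversity in single-group, single-stature mixtures) are excluded
and logged.

Model selection fits all predictor subsets up to `max_terms` terms (default
3) by maximum likelihood with a random block intercept, ranks them by AIC
(AICc optional) and retains models within `delta_max` (default 4) of the
best. Akaike weights are `exp(−Δ/2)` renormalized over the retained set.
Model-averaged coefficients substitute zero when a predictor is absent from
a retained model; a predictor's relative importance is the summed retained
weight of models containing it. Because importance is conditional on
retention, a lucky predictor can score high in a single noise-only fit —
importance ranks are meaningful, absolute values under the null are not.

## Synthetic data generator

Defaults are the study conditions. Monoculture means are
`base_biomass ± stature_effect ± fg_effect` (450 ± 120 ± 30 g m⁻²), times
0.76 under shade and 1.36 under fertilization. True mixture relative yields
are

```
ry_i = 1/S + δ_c + δ_d (μ_i − μ̄) / (S μ̄) + δ_t rank01_i
```

with `δ_c = complementarity = 0.08` (uniform gain, pure TICE),
`δ_d = dominance = 2.0` (zero-sum shift toward productive species, pure
DE) and `δ_t = trait_dependence = 0.02` (rank-based non-zero-sum gain,
TDCE); `rank01` is the 0–1 scaled monoculture-biomass rank. Noise is
moment-exact: species shares are Dirichlet with concentration set so an
equal-share species' share CV equals `noise_sd` (0.26), scaled by the true
RYT and by a mean-one lognormal whole-plot factor, so every partition
component is unbiased by construction. Configs that would drive any true
relative yield negative are rejected. The generator returns the biomass
table, the design, an environment-specific trait table and the exact true
partition per mixture.

## Pipeline

`run_pipeline` reads (or simulates) the biomass/design/trait tables,
validates them, and writes the partition table, percent-gain summaries,
community- and mixture-level ANOVA tables, the trait-composition table with
exclusion log, collinearity screen, model-averaging results for net effect,
TICE and dominance, a markdown report and the fully resolved configuration.
Reruns with the same configuration are byte-identical. CSV i/o is lossless
for doubles (shortest-repr writing, round-trip parsing).
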