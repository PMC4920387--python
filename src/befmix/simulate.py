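"""Synthetic biomass and trait data for the factorial diversity experiment.

The generator produces data under a known ground truth so that every stage
of the analysis pipeline can be checked end to end:

* monoculture biomass: a species baseline (additive stature and
  functional-group offsets around a grassland mean) times multiplicative
  environment responses -- shading reduces biomass to about 76 %,
  fertilization raises it to about 136 % of the control, with an optional
  shade x fertilization interaction -- times mean-one lognormal noise;
* mixture biomass: the realized monoculture biomass of each species in the
  same environment times a noisy relative yield.  The constructed (true)
  relative yields add three levers to the neutral expectation 1/S:

      ry_i = 1/S  +  delta_c
                  +  delta_d (mu_i - mean mu)/(S mean mu)
                  +  delta_t rank_i

  with rank_i the (0..1)-scaled monoculture-biomass rank.  ``delta_c``
  lifts every species' relative yield by the same amount
  (trait-independent complementarity: with delta_c = 0.1, mean M = 150 and
  S = 2 the true TICE is S * delta_c * mean M = 30), ``delta_d`` shifts
  mixture shares toward high-biomass species while summing to zero across
  the mixture (dominance: gain at the others' expense), and ``delta_t``
  lets high-biomass species gain without a compensating loss elsewhere
  (trait-dependent complementarity).

Mixture noise is constructed so that the first moments of every functional
the tripartite partition uses are exact: noisy relative yields are a
Dirichlet draw of the mixture *shares* (whose mean equals the true shares
ry_i / RYT exactly) times the true RYT times an independent mean-one
lognormal total-biomass factor.  Since estimated relative yields are built
from the same realized monoculture references used in the analysis, all
four components -- net effect, trait-independent and trait-dependent
complementarity, and dominance -- are unbiased by construction rather than
only up to a share-nonlinearity bias.  The Dirichlet concentration is
derived from ``noise_sd`` (an equal-share species' share-noise coefficient
of variation equals ``noise_sd``), so the noise level is governed by a
single parameter throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    ENVIRONMENTS,
    Environment,
    PlotRecord,
    SpeciesInfo,
    build_design,
    default_species_pool,
)
from .errors import GeneratorError
from .partition import MixtureObservation, tripartite_partition
from .traits import TRAITS

__all__ = [
    "GeneratorConfig",
    "SyntheticExperiment",
    "species_base_biomass",
    "expected_monoculture",
    "true_relative_yields",
    "true_partition",
    "generate_experiment",
    "default_trait_table",
    "generate_mmi_dataset",
]

_MAX_SEED = 2**31


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters; the defaults are the study conditions."""

    base_biomass: float = 450.0  # g m^-2, grand mean of species baselines
    stature_effect: float = 120.0  # tall +, small -
    fg_effect: float = 30.0  # grass +, forb -
    shade_mult: float = 0.76  # biomass ratio shaded / unshaded
    fert_mult: float = 1.36  # biomass ratio fertilized / unfertilized
    interaction_mult: float = 1.0  # extra multiplier when shaded AND fertilized
    noise_sd: float = 0.26  # lognormal sigma (log scale), mean-one noise
    complementarity: float = 0.08  # delta_c: uniform additive relative-yield gain
    dominance: float = 2.0  # delta_d: zero-sum shift toward productive species
    trait_dependence: float = 0.02  # delta_t: non-zero-sum rank-based gain
    dropout_rate: float = 0.0  # P(a sown mixture species dies, biomass 0)

    def validate(self) -> None:
        if self.base_biomass <= 0:
            raise GeneratorError("base_biomass must be positive")
        if self.stature_effect + self.fg_effect >= self.base_biomass:
            raise GeneratorError("offsets exceed base biomass; negative baselines")
        for name in ("shade_mult", "fert_mult", "interaction_mult"):
            if getattr(self, name) <= 0:
                raise GeneratorError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be non-negative")
        if self.dominance < 0 or self.trait_dependence < 0:
            raise GeneratorError("dominance and trait_dependence must be >= 0")
        if self.complementarity <= -0.25:
            raise GeneratorError(
                "complementarity <= -0.25 drives four-species relative yields negative"
            )
        # the exact positivity bound on dominance depends on the realized
        # monoculture spread; true_relative_yields enforces it per mixture
        if not 0 <= self.dropout_rate < 1:
            raise GeneratorError("dropout_rate must be in [0, 1)")


def species_base_biomass(
    species: list[SpeciesInfo], config: GeneratorConfig
) -> dict[str, float]:
    """Baseline monoculture biomass per species (unshaded, unfertilized)."""
    out = {}
    for s in species:
        base = config.base_biomass
        base += config.stature_effect if s.stature == "tall" else -config.stature_effect
        base += config.fg_effect if s.functional_group == "grass" else -config.fg_effect
        out[s.species_id] = base
    return out


def expected_monoculture(
    config: GeneratorConfig, baseline: float, environment: Environment
) -> float:
    """Expected monoculture biomass mu of one species in one environment."""
    mu = baseline
    if environment.shade:
        mu *= config.shade_mult
    if environment.fertilized:
        mu *= config.fert_mult
    if environment.shade and environment.fertilized:
        mu *= config.interaction_mult
    return mu


def true_relative_yields(config: GeneratorConfig, mus: np.ndarray) -> np.ndarray:
    """Constructed relative yields for a mixture with expected monocultures mus."""
    mus = np.asarray(mus, dtype=float)
    s = len(mus)
    ranks = np.argsort(np.argsort(mus)).astype(float)
    rank01 = ranks / (s - 1) if s > 1 else ranks
    ry = (
        1.0 / s
        + config.complementarity
        + config.dominance * (mus - mus.mean()) / (s * mus.mean())
        + config.trait_dependence * rank01
    )
    if np.any(ry < 0):
        raise GeneratorError(
            "constructed relative yields went negative; lower dominance or "
            "raise complementarity for this monoculture spread"
        )
    return ry


@dataclass
class SyntheticExperiment:
    """A generated experiment: design, biomass table and the ground truth."""

    design: list[PlotRecord]
    species: list[SpeciesInfo]
    table: pd.DataFrame  # plot_id, species_id, biomass (annual, g m^-2)
    config: GeneratorConfig
    truth: pd.DataFrame = field(repr=False)  # per-mixture true components
    trait_table: pd.DataFrame = field(repr=False, default=None)


def true_partition(
    config: GeneratorConfig,
    design: list[PlotRecord],
    species: list[SpeciesInfo],
) -> pd.DataFrame:
    """Noise-free partition components per mixture plot (the ground truth)."""
    base = species_base_biomass(species, config)
    rows = []
    for plot in sorted(design, key=lambda p: p.plot_id):
        if plot.richness == 1:
            continue
        mus = np.array(
            [expected_monoculture(config, base[s], plot.environment) for s in plot.sown_species]
        )
        ry = true_relative_yields(config, mus)
        obs = MixtureObservation(
            species=plot.sown_species,
            mixture_biomass=tuple(mus * ry),
            monoculture_biomass=tuple(mus),
        )
        res = tripartite_partition(obs)
        rows.append(
            {
                "plot_id": plot.plot_id,
                "composition": plot.composition,
                "richness": plot.richness,
                "environment": plot.environment.label,
                "net_effect": res.net_effect,
                "tice": res.tice,
                "tdce": res.tdce,
                "dominance": res.dominance,
                "ryt": res.ryt,
            }
        )
    return pd.DataFrame(rows)


def _mean_one_noise(rng, sd: float, size) -> np.ndarray:
    """Lognormal noise with exact unit mean: exp(N(-sd^2/2, sd^2))."""
    if sd == 0:
        return np.ones(size if size is not None else ())
    return np.exp(rng.normal(-0.5 * sd * sd, sd, size))


def generate_experiment(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    species: list[SpeciesInfo] | None = None,
    design: list[PlotRecord] | None = None,
) -> SyntheticExperiment:
    """Generate a full synthetic experiment under ``config`` (defaults: study).

    All randomness (design randomization, biomass noise, dropout) derives
    from ``seed``.  A pre-built design can be supplied to hold the layout
    fixed across replicates.
    """
    config = config or GeneratorConfig()
    config.validate()
    species = species or default_species_pool()
    rng = np.random.default_rng(seed)
    if design is None:
        design = build_design(species, seed=int(rng.integers(_MAX_SEED)))
    base = species_base_biomass(species, config)

    # realized monoculture biomass per species x environment: these are the
    # reference values the analysis will see, and the building blocks of the
    # mixtures (one monoculture plot per species x environment in the design)
    realized: dict[tuple[str, str], float] = {}
    for plot in sorted(design, key=lambda p: p.plot_id):
        if plot.richness != 1:
            continue
        sp = plot.sown_species[0]
        mu = expected_monoculture(config, base[sp], plot.environment)
        realized[(sp, plot.environment.label)] = mu * float(
            _mean_one_noise(rng, config.noise_sd, None)
        )

    rows = []
    for plot in sorted(design, key=lambda p: p.plot_id):
        env = plot.environment.label
        if plot.richness == 1:
            sp = plot.sown_species[0]
            rows.append({"plot_id": plot.plot_id, "species_id": sp, "biomass": realized[(sp, env)]})
            continue
        mus = np.array(
            [expected_monoculture(config, base[s], plot.environment) for s in plot.sown_species]
        )
        ry = true_relative_yields(config, mus)
        ryt = ry.sum()
        shares = ry / ryt
        if config.noise_sd > 0:
            # concentration such that an equal-share species' share CV equals
            # noise_sd: (S-1)/(kappa+1) = noise_sd^2
            kappa = (len(ry) - 1) / config.noise_sd**2 - 1.0
            shares = rng.dirichlet(shares * kappa)
        total_noise = float(_mean_one_noise(rng, config.noise_sd, None))
        noisy_ry = shares * ryt * total_noise
        for sp, r in zip(plot.sown_species, noisy_ry):
            biomass = realized[(sp, env)] * r
            if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                biomass = 0.0
            rows.append({"plot_id": plot.plot_id, "species_id": sp, "biomass": biomass})

    return SyntheticExperiment(
        design=design,
        species=species,
        table=pd.DataFrame(rows),
        config=config,
        truth=true_partition(config, design, species),
        trait_table=default_trait_table(species, seed=int(rng.integers(_MAX_SEED))),
    )


# ---------------------------------------------------------------------------
# synthetic traits

#: trait baselines (units as in the trait module) and multiplicative
#: modifiers for functional group, stature and the two treatments; the
#: qualitative directions follow common grassland trait syndromes (shade
#: raises specific leaf area, fertilization raises nitrogen concentrations,
#: grasses have higher specific root length, tall species are taller and
#: root deeper).
_TRAIT_RULES = {
    # trait: (baseline, grass_mult, tall_mult, shade_mult, fert_mult)
    "SLA": (22.0, 0.85, 1.05, 1.30, 1.05),
    "SRL": (120.0, 1.40, 0.90, 1.05, 0.90),
    "LNC": (20.0, 0.85, 0.95, 1.10, 1.25),
    "RNC": (10.0, 0.90, 1.00, 1.05, 1.20),
    "Hmax": (45.0, 1.05, 1.60, 1.15, 1.20),
    "WMD": (9.0, 0.90, 1.35, 0.95, 1.05),
}


def default_trait_table(
    species: list[SpeciesInfo] | None = None, seed: int = 0, jitter_sd: float = 0.08
) -> pd.DataFrame:
    """Per species x environment trait values (long format, all positive).

    Deterministic syndrome rules plus a small per-species lognormal jitter
    (driven by ``seed``) so that species of the same functional type still
    differ in every trait.
    """
    species = species or default_species_pool()
    rng = np.random.default_rng(seed)
    jitter = {
        (s.species_id, trait): float(np.exp(rng.normal(0, jitter_sd)))
        for s in species
        for trait in TRAITS
    }
    rows = []
    for s in species:
        for env in ENVIRONMENTS:
            for trait in TRAITS:
                base, g_mult, t_mult, s_mult, f_mult = _TRAIT_RULES[trait]
                v = base * jitter[(s.species_id, trait)]
                if s.functional_group == "grass":
                    v *= g_mult
                if s.stature == "tall":
                    v *= t_mult
                if env.shade:
                    v *= s_mult
                if env.fertilized:
                    v *= f_mult
                rows.append(
                    {
                        "species_id": s.species_id,
                        "environment": env.label,
                        "trait": trait,
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic datasets for multimodel inference

def generate_trait_response(
    predictors: pd.DataFrame,
    blocks,
    coefs: dict[str, float],
    block_sd: float = 0.3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Synthetic response over a predictor matrix with known coefficients.

    ``coefs`` maps predictor column names to effect sizes on the
    z-standardized predictor scale; remaining predictors get a true
    coefficient of zero.  A Gaussian random block intercept and residual
    noise are added.  Returns (response, true coefficient vector).
    """
    unknown = [c for c in coefs if c not in predictors.columns]
    if unknown:
        raise GeneratorError(f"coefficients for unknown predictors: {unknown}")
    rng = np.random.default_rng(seed)
    blocks = np.asarray(blocks)
    if len(blocks) != len(predictors):
        raise GeneratorError("blocks must align with the predictor rows")
    y = np.zeros(len(predictors))
    for name, coef in coefs.items():
        col = predictors[name].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            raise GeneratorError(f"predictor {name!r} is constant; cannot standardize")
        y += coef * (col - col.mean()) / sd
    levels, codes = np.unique(blocks, return_inverse=True)
    y += rng.normal(0, block_sd, len(levels))[codes]
    y += rng.normal(0, noise_sd, len(y))
    truth = pd.Series(
        {c: float(coefs.get(c, 0.0)) for c in predictors.columns}, name="true_coef"
    )
    return pd.Series(y, index=predictors.index, name="response"), truth


def generate_mmi_dataset(
    n: int = 62,
    n_predictors: int = 12,
    active: tuple[int, ...] = (0,),
    effect_size: float = 0.8,
    block_sd: float = 0.3,
    noise_sd: float = 0.5,
    n_blocks: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Predictor matrix plus a response driven by the ``active`` predictors.

    Predictors are independent standard normals (columns ``x01``..); the
    response adds a random block intercept and Gaussian noise.  With
    ``active=()`` the response is pure noise (the null case).
    """
    if n_predictors < 1 or n < 8:
        raise GeneratorError("need at least 1 predictor and 8 observations")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, n_predictors))
    cols = [f"x{i + 1:02d}" for i in range(n_predictors)]
    frame = pd.DataFrame(x, columns=cols)
    blocks = rng.integers(1, n_blocks + 1, size=n)
    frame["block"] = blocks
    y = np.zeros(n)
    for a in active:
        if not 0 <= a < n_predictors:
            raise GeneratorError(f"active predictor index {a} out of range")
        y += effect_size * x[:, a]
    y += rng.normal(0, block_sd, n_blocks)[blocks - 1]
    y += rng.normal(0, noise_sd, n)
    frame["response"] = y
    return frame
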