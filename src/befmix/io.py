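"""CSV schemas, pipeline configuration and the end-to-end pipeline driver.

All tables are plain UTF-8 CSV with '.' decimal separator and documented
headers.  Schemas:

biomass table   plot_id, species_id, biomass           (annual, g m^-2)
                -- or plot_id, species_id, biomass_spring, biomass_summer,
                in which case annual biomass is the sum of both harvests
design table    plot_id, block, shade, fertilized, sown_species
                (sown_species '+'-joined, canonical sorted order)
trait table     species_id, environment, trait, value  (long format)

Every pipeline run writes the resolved configuration next to its outputs
and logs every row exclusion (zero monoculture reference, missing species,
log-of-zero predictor) with the plot id, since those decisions change N.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova as anova_mod
from .design import (
    Environment,
    PlotRecord,
    default_species_pool,
    design_to_frame,
    validate_design,
    validate_table,
)
from .errors import ConfigError, SchemaError, TableValidationError
from .mmi import all_subsets_mmi, model_average
from .partition import partition_table, percent_gain_summary
from .simulate import GeneratorConfig, generate_experiment
from .traits import build_predictor_matrix, collinearity_screen, trait_composition_table

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_biomass_table",
    "read_design_table",
    "read_trait_table",
    "write_table",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# readers / writers

def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_biomass_table(path) -> pd.DataFrame:
    """Read a per-plot, per-species biomass CSV (annual or two harvests)."""
    frame = pd.read_csv(path, dtype={"plot_id": str, "species_id": str}, float_precision="round_trip")
    _require_columns(frame, ["plot_id", "species_id"], path)
    if "biomass" in frame.columns:
        cols = ["biomass"]
    elif {"biomass_spring", "biomass_summer"} <= set(frame.columns):
        cols = ["biomass_spring", "biomass_summer"]
    else:
        raise SchemaError(
            f"{path}: need either a 'biomass' column or both "
            "'biomass_spring' and 'biomass_summer'"
        )
    for col in cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[numeric.isna() & frame[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise SchemaError(
                f"{path}: non-numeric {col} value(s) at line(s) {lines}"
            )
        frame[col] = numeric
    if cols != ["biomass"]:
        frame["biomass"] = frame["biomass_spring"] + frame["biomass_summer"]
        frame = frame.drop(columns=["biomass_spring", "biomass_summer"])
    return frame[["plot_id", "species_id", "biomass"]]


def read_design_table(path, species=None, validate: bool = True) -> list[PlotRecord]:
    """Read a design CSV into plot records (optionally validating invariants)."""
    frame = pd.read_csv(path, dtype={"plot_id": str, "sown_species": str}, float_precision="round_trip")
    _require_columns(
        frame, ["plot_id", "block", "shade", "fertilized", "sown_species"], path
    )
    records = []
    for row in frame.itertuples():
        records.append(
            PlotRecord(
                plot_id=row.plot_id,
                block=int(row.block),
                sown_species=tuple(sorted(str(row.sown_species).split("+"))),
                environment=Environment(
                    shade=bool(row.shade), fertilized=bool(row.fertilized)
                ),
            )
        )
    if validate:
        validate_design(records, species or default_species_pool())
    return records


def read_trait_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"species_id": str, "environment": str, "trait": str}, float_precision="round_trip")
    _require_columns(frame, ["species_id", "environment", "trait", "value"], path)
    frame["value"] = pd.to_numeric(frame["value"], errors="raise")
    return frame


def design_table_frame(design: list[PlotRecord]) -> pd.DataFrame:
    """Design in the on-disk schema (sown_species joined with '+')."""
    frame = design_to_frame(design)
    frame["sown_species"] = [p.composition for p in sorted(design, key=lambda p: p.plot_id)]
    frame = frame.sort_values("plot_id").reset_index(drop=True)
    return frame[["plot_id", "block", "shade", "fertilized", "sown_species"]]


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a CSV losslessly (full float precision round trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; unknown keys in a file are rejected."""

    output_dir: str = "befmix-out"
    seed: int = 0
    simulate: bool = False  # generate inputs instead of reading them
    biomass_path: str | None = None
    design_path: str | None = None
    trait_path: str | None = None
    df_method: str = "satterthwaite"  # or "permutation"
    n_perm: int = 499
    delta_max: float = 4.0
    max_terms: int = 3
    use_aicc: bool = False
    standardize_predictors: bool = True
    percent_convention: str = "ratio-of-means"
    distance: str = "absolute"  # trait distance convention ("absolute"|"gower")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {unknown}")
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        if self.df_method not in ("satterthwaite", "permutation"):
            raise ConfigError(f"df_method must be satterthwaite|permutation, got {self.df_method!r}")
        if self.percent_convention not in ("ratio-of-means", "mean-of-ratios"):
            raise ConfigError(f"unknown percent_convention {self.percent_convention!r}")
        if self.distance not in ("absolute", "gower"):
            raise ConfigError(f"unknown distance {self.distance!r}")
        if self.max_terms < 1 or self.delta_max <= 0 or self.n_perm < 1:
            raise ConfigError("max_terms, delta_max and n_perm must be positive")
        if not self.simulate and not (self.biomass_path and self.design_path):
            raise ConfigError("need biomass_path and design_path unless simulate: true")

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# the pipeline

_MMI_RESPONSES = ("net_effect", "tice", "dominance")


@dataclass
class PipelineResult:
    """In-memory bundle of everything a pipeline run produced."""

    config: PipelineConfig
    partition: pd.DataFrame
    percent_gains: pd.DataFrame
    anova_biomass: pd.DataFrame
    anova_net_effect: pd.DataFrame
    composition: pd.DataFrame | None
    averaged_models: dict[str, pd.DataFrame] = field(default_factory=dict)
    exclusions: pd.DataFrame | None = None
    report: str = ""


def _one_sample_line(name: str, values, reference: float) -> str:
    test = anova_mod.test_mean_against(values, reference)
    return (
        f"- {name}: mean {test.mean:.3f} vs {reference:g} "
        f"(t = {test.t:.2f}, df = {test.df}, p = {test.p:.4g}, n = {test.n})"
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; writes all tables plus report.md to output_dir.

    Deterministic given config (all randomness flows through config.seed).
    Partial outputs are left in place if a later stage raises.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")
    species = default_species_pool()

    if config.simulate:
        experiment = generate_experiment(GeneratorConfig(), seed=config.seed)
        design, table, trait_table = experiment.design, experiment.table, experiment.trait_table
        write_table(table, out / "biomass.csv")
        write_table(design_table_frame(design), out / "design.csv")
        write_table(trait_table, out / "traits.csv")
        write_table(experiment.truth, out / "truth.csv")
    else:
        design = read_design_table(config.design_path, species)
        table = read_biomass_table(config.biomass_path)
        trait_table = read_trait_table(config.trait_path) if config.trait_path else None

    report = validate_table(table, design)
    if not report.ok:
        raise TableValidationError(f"biomass table fails validation: {report.summary()}")

    # --- overyielding & partition -----------------------------------------
    partition = partition_table(table, design)
    write_table(partition, out / "partition.csv")
    gains = percent_gain_summary(
        partition, grouping="environment", convention=config.percent_convention
    )
    write_table(gains, out / "percent_gains.csv")
    valid = partition[partition["excluded_reason"].isna()]

    # --- sequential ANOVAs ------------------------------------------------
    frame = design_to_frame(design)
    frame = anova_mod.add_composition_factors(frame, species)
    totals = table.groupby("plot_id")["biomass"].sum()
    frame["community_biomass"] = frame["plot_id"].map(totals)
    frame["log_biomass"] = np.log(frame["community_biomass"].where(frame["community_biomass"] > 0))
    fit_biomass = anova_mod.fit_sequential_anova(
        frame, anova_mod.community_model("log_biomass"),
        method=config.df_method, n_perm=config.n_perm, seed=config.seed,
    )
    write_table(fit_biomass.table, out / "anova_log_biomass.csv")

    mix_frame = frame.merge(partition[["plot_id", "net_effect"]], on="plot_id")
    mix_frame = mix_frame[mix_frame["net_effect"].notna()]
    fit_ne = anova_mod.fit_sequential_anova(
        mix_frame, anova_mod.community_model("net_effect"),
        method=config.df_method, n_perm=config.n_perm, seed=config.seed + 1,
    )
    write_table(fit_ne.table, out / "anova_net_effect.csv")

    # --- traits & multimodel inference ------------------------------------
    composition = None
    exclusions = None
    averaged: dict[str, pd.DataFrame] = {}
    screen = None
    if trait_table is not None:
        composition = trait_composition_table(table, design, trait_table, distance=config.distance)
        write_table(composition, out / "trait_composition.csv")
        pm = build_predictor_matrix(composition)
        exclusions = pm.exclusions
        write_table(pm.exclusions, out / "predictor_exclusions.csv")
        screen = collinearity_screen(pm.matrix)
        write_table(screen, out / "collinearity_screen.csv")

        predictors = pm.matrix
        if config.standardize_predictors:
            predictors = (predictors - predictors.mean()) / predictors.std(ddof=0)
        mmi_frame = predictors.join(
            valid.set_index("plot_id")[list(_MMI_RESPONSES)], how="inner"
        )
        mmi_frame = mmi_frame.join(frame.set_index("plot_id")["block"])
        for response in _MMI_RESPONSES:
            mmi = all_subsets_mmi(
                mmi_frame, response, list(pm.matrix.columns),
                group_col="block", max_terms=config.max_terms, use_aicc=config.use_aicc,
            )
            avg = model_average(mmi, delta_threshold=config.delta_max)
            averaged[response] = avg
            write_table(avg, out / f"mmi_{response}.csv")

    # --- report ------------------------------------------------------------
    lines = [
        "# Diversity-effect pipeline report",
        "",
        f"Plots: {len(design)}; mixtures analysed: {len(valid)} of {len(partition)}"
        f" ({int(partition['excluded_reason'].notna().sum())} excluded).",
        "",
        "## Overyielding",
        f"- RYT > 1 (non-transgressive overyielding): {100 * (valid['ryt'] > 1).mean():.1f}% of mixtures",
        f"- D_max > 0 (transgressive overyielding): {100 * (valid['d_max'] > 0).mean():.1f}% of mixtures",
        _one_sample_line("RYT vs 1", valid["ryt"], 1.0),
        _one_sample_line("D_max vs 0", valid["d_max"], 0.0),
        "",
        "## Percent biomass gains by environment "
        f"({config.percent_convention})",
        gains.to_string(index=False),
        "",
        "## Sequential ANOVA: log community biomass "
        f"(df method: {config.df_method})",
        fit_biomass.table.to_string(index=False),
        "",
        "## Sequential ANOVA: net diversity effect",
        fit_ne.table.to_string(index=False),
    ]
    if averaged:
        lines += ["", "## Trait-based multimodel inference (averaged models)"]
        for response, avg in averaged.items():
            lines += [f"### response: {response}", avg.to_string(index=False), ""]
        if exclusions is not None and len(exclusions):
            lines += ["Excluded from trait models:"]
            lines += [f"- {r.plot_id}: {r.reason}" for r in exclusions.itertuples()]
    report_text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(report_text)

    return PipelineResult(
        config=config,
        partition=partition,
        percent_gains=gains,
        anova_biomass=fit_biomass.table,
        anova_net_effect=fit_ne.table,
        composition=composition,
        averaged_models=averaged,
        exclusions=exclusions,
        report=report_text,
    )
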