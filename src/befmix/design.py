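"""Experimental universe of the factorial grass-forb biodiversity experiment.

The design crosses species richness (1, 2, 4) from two independent pools of
four perennial grassland species (2 functional groups x 2 growth statures)
with a 2 x 2 manipulation of light (shading cloth over whole blocks) and
nutrients (NPK fertilization of plots within blocks).  96 plots are arranged
in 8 blocks of 12; each block holds 4 monocultures, 6 two-species mixtures
and 2 four-species mixtures, balanced over pools so that every species
occurs exactly three times per block.  Every species composition meets each
of the four resource environments exactly once (four-species mixtures:
twice).

This module defines the domain types, builds randomized designs satisfying
all of those invariants, resolves monoculture reference biomasses, and
validates observed biomass tables against a design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, MissingReferenceError

__all__ = [
    "SpeciesInfo",
    "Environment",
    "PlotRecord",
    "ValidationReport",
    "ENVIRONMENTS",
    "default_species_pool",
    "build_design",
    "design_to_frame",
    "validate_design",
    "monoculture_reference",
    "monoculture_reference_table",
    "composition_key",
    "validate_table",
]

FUNCTIONAL_GROUPS = ("grass", "forb")
STATURES = ("small", "tall")


@dataclass(frozen=True)
class SpeciesInfo:
    """Identity and functional classification of one species."""

    species_id: str
    pool: str
    functional_group: str
    stature: str

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise DesignError(
                f"unknown functional group {self.functional_group!r} "
                f"for species {self.species_id!r}"
            )
        if self.stature not in STATURES:
            raise DesignError(
                f"unknown stature {self.stature!r} for species {self.species_id!r}"
            )


@dataclass(frozen=True)
class Environment:
    """One of the four resource environments (2 x 2 shade x fertilization)."""

    shade: bool
    fertilized: bool

    @property
    def label(self) -> str:
        return f"F{'+' if self.fertilized else '-'}S{'+' if self.shade else '-'}"

    @classmethod
    def from_label(cls, label: str) -> "Environment":
        try:
            fert, shade = label[1], label[3]
            assert label[0] == "F" and label[2] == "S" and fert in "+-" and shade in "+-"
        except (IndexError, AssertionError):
            raise DesignError(f"unknown environment label {label!r}") from None
        return cls(shade=shade == "+", fertilized=fert == "+")


#: All four environments in canonical order.
ENVIRONMENTS = (
    Environment(shade=False, fertilized=False),
    Environment(shade=True, fertilized=False),
    Environment(shade=False, fertilized=True),
    Environment(shade=True, fertilized=True),
)


@dataclass(frozen=True)
class PlotRecord:
    """One 2 x 2 m experimental plot."""

    plot_id: str
    block: int
    sown_species: tuple[str, ...]
    environment: Environment

    @property
    def richness(self) -> int:
        return len(self.sown_species)

    @property
    def composition(self) -> str:
        return composition_key(self.sown_species)


def composition_key(species_ids) -> str:
    """Canonical label of a sown composition: '+'-joined sorted species ids."""
    return "+".join(sorted(species_ids))


# ---------------------------------------------------------------------------
# default species metadata

_DEFAULT_SPECIES = [
    # species_id, pool, functional group, stature  (classic Arrhenatherion species)
    ("Ant.odo", "A", "grass", "small"),   # Anthoxanthum odoratum
    ("Arr.ela", "A", "grass", "tall"),    # Arrhenatherum elatius
    ("Pla.lan", "A", "forb", "small"),    # Plantago lanceolata
    ("Cen.jac", "A", "forb", "tall"),     # Centaurea jacea
    ("Lol.per", "B", "grass", "small"),   # Lolium perenne
    ("Dac.glo", "B", "grass", "tall"),    # Dactylis glomerata
    ("Pru.vul", "B", "forb", "small"),    # Prunella vulgaris
    ("Kna.arv", "B", "forb", "tall"),     # Knautia arvensis
]


def default_species_pool() -> list[SpeciesInfo]:
    """The default 8-species metadata (two pools x 2 FG x 2 statures)."""
    return [SpeciesInfo(*row) for row in _DEFAULT_SPECIES]


def species_frame(species: list[SpeciesInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.species_id, s.pool, s.functional_group, s.stature) for s in species],
        columns=["species_id", "pool", "functional_group", "stature"],
    )


# ---------------------------------------------------------------------------
# combinatorial block template
#
# Template slots 1-8 stand for blocks; roles 0-3 stand for the four species
# of one pool.  The layout below satisfies, per pool: every role is sown in
# monoculture in 4 slots, every pair occurs as a two-species mixture in 4
# slots, the four-species mixture occurs in every slot, every role occurs
# exactly 3 times per slot, and with slots 1-4 shaded every composition
# splits its replicates 2/2 (four-species: 4/4) across the shade halves.
# The same layout is used for both pools; randomization permutes the
# slot -> block map and the role -> species map under the run seed.

_TMPL_MONO = {
    1: (0, 1), 2: (2, 3), 3: (0, 2), 4: (1, 3),
    5: (0, 3), 6: (1, 2), 7: (0, 1), 8: (2, 3),
}
_TMPL_TWO = {
    1: [(2, 3), (0, 2), (1, 3)],
    2: [(0, 1), (0, 3), (1, 2)],
    3: [(1, 3), (0, 1), (2, 3)],
    4: [(0, 2), (1, 2), (0, 3)],
    5: [(1, 2), (0, 1), (2, 3)],
    6: [(0, 3), (1, 3), (0, 2)],
    7: [(2, 3), (0, 3), (1, 2)],
    8: [(0, 1), (0, 2), (1, 3)],
}
_TMPL_SHADED_SLOTS = frozenset({1, 2, 3, 4})


def _check_pools(species: list[SpeciesInfo]) -> dict[str, list[SpeciesInfo]]:
    pools: dict[str, list[SpeciesInfo]] = {}
    for s in species:
        pools.setdefault(s.pool, []).append(s)
    if len(pools) != 2:
        raise DesignError(f"expected exactly 2 species pools, got {sorted(pools)}")
    for pool, members in pools.items():
        combos = {(s.functional_group, s.stature) for s in members}
        if len(members) != 4 or len(combos) != 4:
            raise DesignError(
                f"pool {pool!r} must contain 4 species covering all "
                f"functional-group x stature combinations"
            )
    return pools


def _sample_balanced_labels(groups, quotas, rng, max_tries=1000):
    """Pick positive items per group under per-block quotas.

    groups : list of (needed_positives, [(item, block), ...])
    quotas : dict block -> number of positives required in that block
    Returns the set of chosen items, sampled by randomized greedy assignment
    with restart on dead ends.  The same procedure is used when building a
    design and when re-randomizing treatment labels for permutation tests,
    so both draw the assignment from an identical distribution.
    """
    blocks = list(quotas)
    for _ in range(max_tries):
        remaining = dict(quotas)
        chosen: set = set()
        order = rng.permutation(len(groups))
        ok = True
        for gi in order:
            needed, items = groups[gi]
            candidates = [(it, b) for it, b in items if remaining.get(b, 0) > 0]
            if len(candidates) < needed:
                ok = False
                break
            # uniform subset via a random permutation prefix
            for k in rng.permutation(len(candidates))[:needed]:
                it, b = candidates[k]
                chosen.add(it)
                remaining[b] -= 1
        if ok and all(v == 0 for v in remaining.values()):
            return chosen
    raise DesignError("could not find a quota-respecting treatment assignment")


def sample_fertilization(plots: pd.DataFrame, rng) -> pd.Series:
    """Draw a fertilization assignment for a design skeleton.

    ``plots`` needs columns block, shade, richness, composition.  Within each
    shade half and richness level, each composition fertilizes half of its
    replicate plots, subject to equal numbers of fertilized plots per block
    and richness level (the design's balancing rule).  Returns a boolean
    Series aligned with ``plots``.
    """
    fert = pd.Series(False, index=plots.index)
    for (_, richness), cell in plots.groupby(["shade", "richness"]):
        n_blocks = cell["block"].nunique()
        per_block = len(cell) // (2 * n_blocks)
        quotas = {b: per_block for b in cell["block"].unique()}
        groups = []
        for _, comp_rows in cell.groupby("composition"):
            needed = len(comp_rows) // 2
            items = list(zip(comp_rows.index, comp_rows["block"]))
            groups.append((needed, items))
        for idx in _sample_balanced_labels(groups, quotas, rng):
            fert.loc[idx] = True
    return fert


def build_design(species: list[SpeciesInfo] | None = None, seed: int = 0) -> list[PlotRecord]:
    """Build a randomized 96-plot design from 8-species metadata.

    Randomization (all driven by ``seed``): which physical blocks are
    shaded, which species plays which template role within its pool, the
    fertilization assignment, and plot order within blocks.
    """
    if species is None:
        species = default_species_pool()
    pools = _check_pools(species)
    rng = np.random.default_rng(seed)

    # physical block for each template slot; slots 1-4 carry the shade cloth
    block_of_slot = {slot: int(b) + 1 for slot, b in zip(range(1, 9), rng.permutation(8))}
    shaded_blocks = {block_of_slot[s] for s in _TMPL_SHADED_SLOTS}

    # species for each (pool, role)
    role_species: dict[tuple[str, int], str] = {}
    for pool in sorted(pools):
        members = sorted(s.species_id for s in pools[pool])
        for role, idx in enumerate(rng.permutation(4)):
            role_species[(pool, role)] = members[idx]

    rows = []
    for slot in range(1, 9):
        block = block_of_slot[slot]
        for pool in sorted(pools):
            comps: list[tuple[int, ...]] = [(r,) for r in _TMPL_MONO[slot]]
            comps += [tuple(p) for p in _TMPL_TWO[slot]]
            comps.append((0, 1, 2, 3))
            for roles in comps:
                sown = tuple(sorted(role_species[(pool, r)] for r in roles))
                rows.append(
                    {
                        "block": block,
                        "pool": pool,
                        "sown": sown,
                        "richness": len(sown),
                        "shade": block in shaded_blocks,
                        "composition": composition_key(sown),
                    }
                )
    skeleton = pd.DataFrame(rows)
    skeleton["fertilized"] = sample_fertilization(skeleton, rng)

    records = []
    for block, block_rows in skeleton.groupby("block"):
        order = rng.permutation(len(block_rows))
        for k, (_, row) in enumerate(block_rows.iloc[order].iterrows()):
            records.append(
                PlotRecord(
                    plot_id=f"P{block:d}-{k + 1:02d}",
                    block=int(block),
                    sown_species=row["sown"],
                    environment=Environment(
                        shade=bool(row["shade"]), fertilized=bool(row["fertilized"])
                    ),
                )
            )
    records.sort(key=lambda r: (r.block, r.plot_id))
    validate_design(records, species)
    return records


def design_to_frame(design: list[PlotRecord]) -> pd.DataFrame:
    """Flat table view of a design (one row per plot)."""
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in design],
            "block": [p.block for p in design],
            "composition": [p.composition for p in design],
            "richness": [p.richness for p in design],
            "shade": [p.environment.shade for p in design],
            "fertilized": [p.environment.fertilized for p in design],
            "environment": [p.environment.label for p in design],
        }
    )


def validate_design(design: list[PlotRecord], species: list[SpeciesInfo]) -> None:
    """Raise :class:`DesignError` unless all design invariants hold."""
    pools = _check_pools(species)
    pool_of = {s.species_id: s.pool for s in species}
    n_env = len(ENVIRONMENTS)

    if len(design) != 96:
        raise DesignError(f"expected 96 plots, got {len(design)}")
    by_block: dict[int, list[PlotRecord]] = {}
    for p in design:
        if len({pool_of.get(s) for s in p.sown_species}) != 1:
            raise DesignError(f"plot {p.plot_id} mixes species pools")
        if p.richness not in (1, 2, 4):
            raise DesignError(f"plot {p.plot_id} has richness {p.richness}")
        by_block.setdefault(p.block, []).append(p)
    if len(by_block) != 8:
        raise DesignError("expected 8 blocks")
    for block, plots in by_block.items():
        counts = {1: 0, 2: 0, 4: 0}
        occurrence: dict[str, int] = {}
        shades = set()
        for p in plots:
            counts[p.richness] += 1
            shades.add(p.environment.shade)
            for s in p.sown_species:
                occurrence[s] = occurrence.get(s, 0) + 1
        if counts != {1: 4, 2: 6, 4: 2}:
            raise DesignError(f"block {block} richness counts {counts} violate 4/6/2")
        if len(shades) != 1:
            raise DesignError(f"block {block} mixes shaded and unshaded plots")
        bad = {s: n for s, n in occurrence.items() if n != 3}
        if bad:
            raise DesignError(f"block {block}: species occurrences != 3: {bad}")
        n_fert = sum(p.environment.fertilized for p in plots)
        if n_fert != 6:
            raise DesignError(f"block {block} has {n_fert} fertilized plots, expected 6")

    # every composition meets every environment once (four-species: twice)
    combos: dict[tuple[str, str], int] = {}
    for p in design:
        combos[(p.composition, p.environment.label)] = (
            combos.get((p.composition, p.environment.label), 0) + 1
        )
    for (comp, env), n in combos.items():
        expected = 2 if comp.count("+") == 3 else 1
        if n != expected:
            raise DesignError(f"composition {comp} occurs {n}x in environment {env}")
    n_comps = len({c for c, _ in combos})
    if n_comps != 22 or len(combos) != 22 * n_env:
        raise DesignError("composition x environment coverage incomplete")


# ---------------------------------------------------------------------------
# monoculture references

def monoculture_reference(
    table: pd.DataFrame,
    design: list[PlotRecord],
    species_id: str,
    environment: Environment | str,
) -> float:
    """Monoculture biomass of ``species_id`` in ``environment`` (g m^-2).

    The monoculture grown in the same resource environment provides the
    expected biomass for that species in mixtures of the same environment.
    With replicated monocultures (a generalization; the reference design has
    exactly one per environment) the arithmetic mean is returned.  A zero
    value is returned as-is; relative yields are then undefined downstream.
    """
    if isinstance(environment, str):
        environment = Environment.from_label(environment)
    plot_ids = [
        p.plot_id
        for p in design
        if p.richness == 1
        and p.sown_species[0] == species_id
        and p.environment == environment
    ]
    if not plot_ids:
        raise MissingReferenceError(
            f"no monoculture of {species_id!r} in environment {environment.label}"
        )
    rows = table[table["plot_id"].isin(plot_ids) & (table["species_id"] == species_id)]
    if rows.empty:
        raise MissingReferenceError(
            f"no biomass rows for monoculture of {species_id!r} "
            f"in environment {environment.label}"
        )
    return float(rows["biomass"].mean())


def monoculture_reference_table(
    table: pd.DataFrame, design: list[PlotRecord]
) -> pd.DataFrame:
    """All monoculture references: columns species_id, environment, biomass."""
    species = sorted({p.sown_species[0] for p in design if p.richness == 1})
    rows = []
    for sp, env in itertools.product(species, ENVIRONMENTS):
        rows.append(
            {
                "species_id": sp,
                "environment": env.label,
                "biomass": monoculture_reference(table, design, sp, env),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table validation

@dataclass
class ValidationReport:
    """Outcome of checking a biomass table against a design."""

    unknown_species: list = field(default_factory=list)
    unknown_plots: list = field(default_factory=list)
    duplicate_rows: list = field(default_factory=list)
    negative_biomass: list = field(default_factory=list)
    non_finite_biomass: list = field(default_factory=list)
    missing_rows: list = field(default_factory=list)  # warnings, not hard

    @property
    def hard_violations(self) -> list:
        return (
            self.unknown_species
            + self.unknown_plots
            + self.duplicate_rows
            + self.negative_biomass
            + self.non_finite_biomass
        )

    @property
    def ok(self) -> bool:
        return not self.hard_violations

    @property
    def empty(self) -> bool:
        return self.ok and not self.missing_rows

    def summary(self) -> str:
        parts = []
        for name in (
            "unknown_species",
            "unknown_plots",
            "duplicate_rows",
            "negative_biomass",
            "non_finite_biomass",
            "missing_rows",
        ):
            values = getattr(self, name)
            if values:
                parts.append(f"{name}: {values}")
        return "; ".join(parts) if parts else "ok"


def validate_table(table: pd.DataFrame, design: list[PlotRecord]) -> ValidationReport:
    """Check a per-plot, per-species biomass table against a design.

    Hard violations (unknown plots or species, duplicates, negative or
    non-finite biomass) must stop a pipeline; plots lacking a row for a sown
    species are reported as warnings (dead species should be explicit
    biomass-0 rows so that richness and sown proportions stay correct).
    """
    report = ValidationReport()
    plots = {p.plot_id: p for p in design}
    known_species = {s for p in design for s in p.sown_species}

    for _, row in table.iterrows():
        if row["species_id"] not in known_species:
            report.unknown_species.append((row["plot_id"], row["species_id"]))
        if row["plot_id"] not in plots:
            report.unknown_plots.append(row["plot_id"])
        elif (
            row["species_id"] in known_species
            and row["species_id"] not in plots[row["plot_id"]].sown_species
        ):
            # a real species reported from a plot where it was not sown
            report.unknown_species.append((row["plot_id"], row["species_id"]))
        b = row["biomass"]
        if not np.isfinite(b):
            report.non_finite_biomass.append((row["plot_id"], row["species_id"]))
        elif b < 0:
            report.negative_biomass.append((row["plot_id"], row["species_id"], float(b)))

    seen = table.groupby(["plot_id", "species_id"]).size()
    report.duplicate_rows.extend(seen[seen > 1].index.tolist())

    present = set(map(tuple, table[["plot_id", "species_id"]].itertuples(index=False)))
    for p in design:
        for s in p.sown_species:
            if (p.plot_id, s) not in present:
                report.missing_rows.append((p.plot_id, s))
    return report
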