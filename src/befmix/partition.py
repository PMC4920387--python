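"""Overyielding metrics and the tripartite partition of net diversity effects.

For a mixture of S species sown at proportions ``q_i`` (default 1/S), with
observed per-species mixture biomass ``Y_i`` and monoculture reference
biomass ``M_i`` from the same resource environment:

* relative yield          RY_i  = Y_i / M_i
* relative yield total    RYT   = sum_i RY_i          (de Wit)
* non-transgressive       D_mean = (Y_O - mean M)/mean M
* transgressive           D_max  = (Y_O - max M)/max M

Under equal sown proportions D_mean and RYT are linked by the exact
relation D_mean - (RYT - 1) = S cov(RY, M) / mean M (population
covariance), so the often-quoted shorthand D_mean = RYT - 1 holds exactly
when relative yields are uncorrelated with monoculture biomass (uniform
relative yields, or equal monocultures) and only approximately otherwise.
* net diversity effect    NE    = Y_O - sum_i q_i M_i

The net effect splits additively into three components (an extension of the
Loreau-Hector additive partition):

* TICE = S * mean(dRY) * mean(M)                     trait-independent
  complementarity (== the Loreau-Hector complementarity effect CE), with
  dRY_i = RY_i - q_i;
* DE   = S * cov(M, RY/RYT - q)                      dominance: high-
  monoculture-biomass species gain mixture share at the expense of others;
* TDCE = S * cov(M, RY - RY/RYT)                     trait-dependent
  complementarity: such species gain relative yield without depressing
  others.

Covariances use the population convention (divide by S); only then does
NE = TICE + TDCE + DE hold as an algebraic identity.  The Loreau-Hector
selection effect SE = S * cov(M, dRY) equals TDCE + DE and serves as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PlotRecord, monoculture_reference_table
from .errors import PartitionUndefinedError, UndefinedRelativeYieldError

__all__ = [
    "MixtureObservation",
    "PartitionResult",
    "relative_yields",
    "relative_yield_total",
    "overyield_mean",
    "overyield_max",
    "corrected_relative_yield",
    "tripartite_partition",
    "additive_partition",
    "partition_table",
    "percent_gain_summary",
]


@dataclass(frozen=True)
class MixtureObservation:
    """Observed mixture biomass plus monoculture references for one plot."""

    species: tuple[str, ...]
    mixture_biomass: tuple[float, ...]  # Y_i, g m^-2
    monoculture_biomass: tuple[float, ...]  # M_i, g m^-2
    sown_proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.species)
        if not (len(self.mixture_biomass) == len(self.monoculture_biomass) == n):
            raise ValueError("species, mixture and monoculture vectors differ in length")
        if self.sown_proportions is not None:
            if len(self.sown_proportions) != n:
                raise ValueError("sown_proportions has wrong length")
            if abs(sum(self.sown_proportions) - 1.0) > 1e-8:
                raise ValueError("sown proportions must sum to 1")

    @property
    def richness(self) -> int:
        return len(self.species)

    @property
    def proportions(self) -> np.ndarray:
        if self.sown_proportions is None:
            return np.full(self.richness, 1.0 / self.richness)
        return np.asarray(self.sown_proportions, dtype=float)


@dataclass(frozen=True)
class PartitionResult:
    """All overyielding metrics and partition components for one mixture."""

    species: tuple[str, ...]
    relative_yield: tuple[float, ...]
    ryt: float
    d_mean: float
    d_max: float
    expected_biomass: float  # Y_E = sum q_i M_i
    observed_biomass: float  # Y_O
    net_effect: float
    tice: float
    tdce: float
    dominance: float
    complementarity: float  # Loreau-Hector CE (= TICE)
    selection: float  # Loreau-Hector SE (= TDCE + DE)


def relative_yields(obs: MixtureObservation) -> np.ndarray:
    """RY_i = Y_i / M_i.  Raises if any monoculture reference is zero."""
    m = np.asarray(obs.monoculture_biomass, dtype=float)
    if np.any(m <= 0):
        dead = [s for s, b in zip(obs.species, m) if b <= 0]
        raise UndefinedRelativeYieldError(
            f"zero/negative monoculture biomass for {dead}; relative yield undefined"
        )
    return np.asarray(obs.mixture_biomass, dtype=float) / m


def relative_yield_total(ry: np.ndarray) -> float:
    """RYT = sum of relative yields; RYT > 1 flags non-transgressive overyielding."""
    ry = np.asarray(ry, dtype=float)
    if ry.size == 0:
        raise ValueError("empty relative-yield vector")
    return float(ry.sum())


def overyield_mean(observed_total: float, mean_monoculture: float) -> float:
    """D_mean = (Y_O - mean M) / mean M.

    Equals RYT - 1 exactly when relative yields are uncorrelated with the
    monoculture biomasses (see the module docstring for the exact link).
    """
    if mean_monoculture <= 0:
        raise ValueError("mean monoculture biomass must be positive")
    return (observed_total - mean_monoculture) / mean_monoculture


def overyield_max(observed_total: float, monoculture_biomass) -> float:
    """D_max = (Y_O - max M) / max M; > 0 flags transgressive overyielding."""
    m = np.asarray(monoculture_biomass, dtype=float)
    if m.size == 0 or m.max() <= 0:
        raise ValueError("maximum monoculture biomass must be positive")
    return float((observed_total - m.max()) / m.max())


def corrected_relative_yield(ry, richness: int):
    """RY corrected for sowing proportion: RY_i * S.

    Values above 1 mean the species performs better in mixture than in its
    monoculture, 1 is neutral, below 1 worse.
    """
    if richness < 1:
        raise ValueError("richness must be >= 1")
    return np.asarray(ry, dtype=float) * richness


def _pop_cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a * b) - np.mean(a) * np.mean(b))


def tripartite_partition(obs: MixtureObservation) -> PartitionResult:
    """Partition the net diversity effect into TICE, TDCE and DE."""
    s = obs.richness
    q = obs.proportions
    m = np.asarray(obs.monoculture_biomass, dtype=float)
    y = np.asarray(obs.mixture_biomass, dtype=float)
    ry = relative_yields(obs)
    ryt = relative_yield_total(ry)
    if ryt <= 0:
        raise PartitionUndefinedError("RYT = 0 (all species dead); partition undefined")

    d_ry = ry - q
    y_o = float(y.sum())
    y_e = float((q * m).sum())
    ne = y_o - y_e

    tice = s * d_ry.mean() * m.mean()
    de = s * _pop_cov(m, ry / ryt - q)
    if np.ptp(q) < 1e-12:
        # With equal sown proportions the alternative argument dRY/RYT
        # differs from RY/RYT - q only by a within-mixture constant, so the
        # covariances must agree (for unequal q they genuinely differ).
        de_alt = s * _pop_cov(m, d_ry / ryt)
        if abs(de - de_alt) > 1e-8 * max(1.0, abs(de)):
            raise AssertionError("dominance-effect covariance arguments disagree")
    tdce = s * _pop_cov(m, ry - ry / ryt)

    ce, se = additive_partition(obs)
    return PartitionResult(
        species=obs.species,
        relative_yield=tuple(ry.tolist()),
        ryt=ryt,
        d_mean=overyield_mean(y_o, float(m.mean())),
        d_max=overyield_max(y_o, m),
        expected_biomass=y_e,
        observed_biomass=y_o,
        net_effect=ne,
        tice=float(tice),
        tdce=float(tdce),
        dominance=float(de),
        complementarity=ce,
        selection=se,
    )


def additive_partition(obs: MixtureObservation) -> tuple[float, float]:
    """Loreau-Hector additive partition: (CE, SE).

    CE = S * mean(dRY) * mean(M) and SE = S * cov(M, dRY); CE equals TICE
    and SE equals TDCE + DE, which makes this an independent oracle for the
    tripartite partition.
    """
    s = obs.richness
    m = np.asarray(obs.monoculture_biomass, dtype=float)
    ry = relative_yields(obs)
    d_ry = ry - obs.proportions
    ce = s * d_ry.mean() * m.mean()
    se = s * _pop_cov(m, d_ry)
    return float(ce), float(se)


# ---------------------------------------------------------------------------
# table-level driver

_TABLE_COLUMNS = [
    "plot_id",
    "block",
    "composition",
    "richness",
    "environment",
    "observed_biomass",
    "expected_biomass",
    "ryt",
    "d_mean",
    "d_max",
    "net_effect",
    "tice",
    "tdce",
    "dominance",
    "complementarity",
    "selection",
    "excluded_reason",
]


def partition_table(
    table: pd.DataFrame,
    design: list[PlotRecord],
    references: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-mixture overyielding and partition metrics for a whole experiment.

    One row per mixture plot (richness > 1), sorted by plot id.  Mixtures
    whose monoculture reference is zero for some species get NA metrics and
    an ``excluded_reason``.  ``references`` (species x environment biomass)
    is derived from the monocultures in ``table`` when not given.
    """
    if references is None:
        references = monoculture_reference_table(table, design)
    ref = {
        (r.species_id, r.environment): r.biomass for r in references.itertuples()
    }
    biomass = {
        (r.plot_id, r.species_id): r.biomass for r in table.itertuples()
    }

    rows = []
    for plot in sorted(design, key=lambda p: p.plot_id):
        if plot.richness == 1:
            continue
        base = {
            "plot_id": plot.plot_id,
            "block": plot.block,
            "composition": plot.composition,
            "richness": plot.richness,
            "environment": plot.environment.label,
        }
        mono = [ref.get((s, plot.environment.label), np.nan) for s in plot.sown_species]
        mixed = [biomass.get((plot.plot_id, s), np.nan) for s in plot.sown_species]
        if any(not np.isfinite(b) for b in mixed):
            rows.append({**base, "excluded_reason": "missing mixture biomass row"})
            continue
        if any(not np.isfinite(b) or b <= 0 for b in mono):
            rows.append({**base, "excluded_reason": "zero or missing monoculture reference"})
            continue
        obs = MixtureObservation(
            species=plot.sown_species,
            mixture_biomass=tuple(mixed),
            monoculture_biomass=tuple(mono),
        )
        try:
            res = tripartite_partition(obs)
        except PartitionUndefinedError as exc:
            rows.append({**base, "excluded_reason": str(exc)})
            continue
        rows.append(
            {
                **base,
                "observed_biomass": res.observed_biomass,
                "expected_biomass": res.expected_biomass,
                "ryt": res.ryt,
                "d_mean": res.d_mean,
                "d_max": res.d_max,
                "net_effect": res.net_effect,
                "tice": res.tice,
                "tdce": res.tdce,
                "dominance": res.dominance,
                "complementarity": res.complementarity,
                "selection": res.selection,
                "excluded_reason": None,
            }
        )
    out = pd.DataFrame(rows)
    return out.reindex(columns=_TABLE_COLUMNS)


_COMPONENTS = ("net_effect", "tice", "tdce", "dominance")


def percent_gain_summary(
    partition: pd.DataFrame,
    grouping: str | list[str] | None = "environment",
    convention: str = "ratio-of-means",
) -> pd.DataFrame:
    """Percent biomass gain attributable to NE, TICE, TDCE and DE per group.

    ``ratio-of-means`` (default): 100 * mean(component) / mean(Y_E), robust
    to mixtures with small expected biomass.  ``mean-of-ratios``: mean of
    per-mixture 100 * component / Y_E.
    """
    if convention not in ("ratio-of-means", "mean-of-ratios"):
        raise ValueError(f"unknown percent-gain convention {convention!r}")
    valid = partition[partition["excluded_reason"].isna()]
    if grouping is None:
        grouped = [("all", valid)]
        index_name = "group"
    else:
        grouped = list(valid.groupby(grouping))
        index_name = grouping if isinstance(grouping, str) else "+".join(grouping)
    rows = []
    for key, sub in grouped:
        row = {"group": key, "n": len(sub)}
        for comp in _COMPONENTS:
            if len(sub) == 0:
                row[f"pct_{comp}"] = np.nan
            elif convention == "ratio-of-means":
                row[f"pct_{comp}"] = 100.0 * sub[comp].mean() / sub["expected_biomass"].mean()
            else:
                row[f"pct_{comp}"] = float(
                    (100.0 * sub[comp] / sub["expected_biomass"]).mean()
                )
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.rename(columns={"group": index_name})
    return out
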