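"""Community-weighted mean traits and single-trait Rao's quadratic entropy.

Six functional traits characterize resource acquisition above and below
ground (SLA: specific leaf area, m2 kg-1; SRL: specific root length, m g-1),
plant stature (Hmax: maximum shoot length, cm; WMD: weighted mean depth of
root biomass, cm) and nitrogen economy (LNC / RNC: leaf / root nitrogen
concentration, mg g-1).  Trait values are resolved per species and per
resource environment, so environment-induced trait plasticity propagates
into the community metrics.

For a community with relative biomass abundances p_i and trait values t_i:

    CWM = sum_i p_i t_i
    FD  = sum_i sum_j p_i p_j d_ij        (Rao's quadratic entropy)

with d_ij a pairwise trait distance; the default is the absolute raw-scale
difference |t_i - t_j| (single-trait Rao's Q), a range-scaled Gower variant
is available and differs only by a positive per-trait scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PlotRecord

__all__ = [
    "TRAITS",
    "LOG_FD_TRAITS",
    "LOG_CWM_TRAITS",
    "abundance_weights",
    "rao_q",
    "cwm",
    "trait_composition_table",
    "build_predictor_matrix",
    "collinearity_screen",
]

TRAITS = ("SLA", "SRL", "LNC", "RNC", "Hmax", "WMD")
#: FD columns are log-transformed for inference for every trait;
#: CWM columns only for the right-skewed root/leaf-nitrogen traits.
LOG_FD_TRAITS = TRAITS
LOG_CWM_TRAITS = ("SRL", "RNC", "LNC")


def abundance_weights(biomass) -> np.ndarray:
    """Relative abundances p_i from species biomass proportions."""
    b = np.asarray(biomass, dtype=float)
    total = b.sum()
    if total <= 0:
        raise ValueError("cannot compute abundance weights: total biomass is zero")
    if np.any(b < 0):
        raise ValueError("negative biomass in abundance weights")
    return b / total


def rao_q(p, t, distance=None) -> float:
    """Rao's quadratic entropy FD = sum_ij p_i p_j d_ij over ordered pairs."""
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    if p.shape != t.shape:
        raise ValueError("abundance and trait vectors differ in length")
    if distance is None:
        d = np.abs(t[:, None] - t[None, :])
    else:
        d = np.array([[distance(a, b) for b in t] for a in t], dtype=float)
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance must be symmetric with zero diagonal")
    return float(p @ d @ p)


def gower_distance_factory(trait_range: float):
    """Range-scaled (Gower) single-trait distance: |dt| / range."""
    if trait_range <= 0:
        raise ValueError("trait range must be positive")
    return lambda a, b: abs(a - b) / trait_range


def cwm(p, t) -> float:
    """Community-weighted mean trait CWM = sum_i p_i t_i."""
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    if p.shape != t.shape:
        raise ValueError("abundance and trait vectors differ in length")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("abundance weights must sum to 1")
    return float(p @ t)


# ---------------------------------------------------------------------------
# experiment-level drivers

def _trait_lookup(trait_table: pd.DataFrame) -> dict:
    dupes = trait_table.groupby(["species_id", "environment", "trait"]).size()
    if (dupes > 1).any():
        raise ValueError(
            f"duplicated trait values: {dupes[dupes > 1].index.tolist()}"
        )
    return {
        (r.species_id, r.environment, r.trait): r.value
        for r in trait_table.itertuples()
    }


def trait_composition_table(
    table: pd.DataFrame,
    design: list[PlotRecord],
    trait_table: pd.DataFrame,
    distance: str = "absolute",
) -> pd.DataFrame:
    """Per-mixture CWM and FD for each trait, on the raw trait scale.

    Abundance weights are species proportions of annual aboveground biomass.
    Mixtures in which a sown species is missing (zero biomass) are flagged
    via ``n_missing_species``; trait values absent from ``trait_table`` give
    NA metrics for that trait.
    """
    if distance not in ("absolute", "gower"):
        raise ValueError(f"unknown distance convention {distance!r}")
    lookup = _trait_lookup(trait_table)
    ranges = {
        trait: float(
            trait_table.loc[trait_table["trait"] == trait, "value"].max()
            - trait_table.loc[trait_table["trait"] == trait, "value"].min()
        )
        for trait in TRAITS
    }
    biomass = {(r.plot_id, r.species_id): r.biomass for r in table.itertuples()}

    rows = []
    for plot in sorted(design, key=lambda p: p.plot_id):
        if plot.richness == 1:
            continue
        env = plot.environment.label
        b = np.array(
            [biomass.get((plot.plot_id, s), np.nan) for s in plot.sown_species]
        )
        row = {
            "plot_id": plot.plot_id,
            "block": plot.block,
            "composition": plot.composition,
            "richness": plot.richness,
            "environment": env,
            "n_missing_species": int(np.sum(b == 0) + np.sum(~np.isfinite(b))),
        }
        if np.all(np.isfinite(b)) and b.sum() > 0:
            p = abundance_weights(b)
            for trait in TRAITS:
                t = np.array(
                    [lookup.get((s, env, trait), np.nan) for s in plot.sown_species]
                )
                if np.all(np.isfinite(t)):
                    if distance == "gower" and ranges[trait] > 0:
                        fd = rao_q(p, t, gower_distance_factory(ranges[trait]))
                    else:
                        fd = rao_q(p, t)
                    row[f"CWM_{trait}"] = cwm(p, t)
                    row[f"FD_{trait}"] = fd
                else:
                    row[f"CWM_{trait}"] = np.nan
                    row[f"FD_{trait}"] = np.nan
        else:
            for trait in TRAITS:
                row[f"CWM_{trait}"] = np.nan
                row[f"FD_{trait}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PredictorMatrix:
    """Transformed trait predictors plus the exclusion log."""

    matrix: pd.DataFrame  # indexed by plot_id; 12 predictor columns
    exclusions: pd.DataFrame  # plot_id, reason


def build_predictor_matrix(composition: pd.DataFrame) -> PredictorMatrix:
    """Assemble the mixture x 12 predictor matrix for trait-based inference.

    Natural-log transforms are applied to all six FD columns and to
    CWM_SRL, CWM_RNC and CWM_LNC (right-skewed traits).  Mixtures with a
    missing species (FD not computable from a replacement-series stance),
    missing trait values, or a non-positive value in a log column are
    excluded with a logged reason rather than crashing.
    """
    cols = [f"CWM_{t}" for t in TRAITS] + [f"FD_{t}" for t in TRAITS]
    excluded = []
    kept = []
    for _, row in composition.iterrows():
        if row["n_missing_species"] > 0:
            excluded.append(
                (row["plot_id"], "species missing from mixture; FD not computable")
            )
            continue
        values = {}
        reason = None
        for t in TRAITS:
            cwm_v, fd_v = row[f"CWM_{t}"], row[f"FD_{t}"]
            if not (np.isfinite(cwm_v) and np.isfinite(fd_v)):
                reason = f"missing trait value for {t}"
                break
            if fd_v <= 0:
                reason = f"FD_{t} <= 0; log transform undefined"
                break
            if t in LOG_CWM_TRAITS and cwm_v <= 0:
                reason = f"CWM_{t} <= 0; log transform undefined"
                break
            values[f"FD_{t}"] = np.log(fd_v)
            values[f"CWM_{t}"] = np.log(cwm_v) if t in LOG_CWM_TRAITS else cwm_v
        if reason is not None:
            excluded.append((row["plot_id"], reason))
            continue
        kept.append({"plot_id": row["plot_id"], **values})

    matrix = pd.DataFrame(kept).set_index("plot_id") if kept else pd.DataFrame(
        columns=cols
    )
    return PredictorMatrix(
        matrix=matrix.reindex(columns=cols),
        exclusions=pd.DataFrame(excluded, columns=["plot_id", "reason"]),
    )


def collinearity_screen(matrix: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations among predictors, flagging |r| > threshold.

    Constant columns give NA correlations and are flagged for attention.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    cols = list(matrix.columns)
    rows = []
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if sd[i] == 0 or sd[j] == 0:
                r = np.nan
                flagged = True  # constant column: correlation undefined
            else:
                r = float(np.corrcoef(values[:, i], values[:, j])[0, 1])
                flagged = abs(r) > threshold
            rows.append(
                {"var_a": cols[i], "var_b": cols[j], "r": r, "flagged": flagged}
            )
    return pd.DataFrame(rows)
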