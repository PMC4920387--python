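"""Sequential mixed-model ANOVA, one-sample tests and post-hoc contrasts.

The experiment is a split-plot-like layout: shading is randomized to whole
blocks, fertilization to plots within blocks, and species compositions are
a structural factor replicated across environments.  Fixed effects are
entered sequentially (type-I decomposition) in the order shade,
fertilization, log species richness, functional-group composition, growth
stature composition, then all two- and three-way treatment interactions;
random intercepts for block and mixture identity (community level) or for
block, plot-in-block, mixture identity and species identity (species
level).

F statistics come from an expected-mean-squares (EMS) decomposition: the
design matrix is extended by the random-term indicator blocks, every term's
sequential sum of squares is computed by orthogonal projection, and each
fixed term is tested against the non-negative combination of error-stratum
mean squares whose expectation matches its own EMS under the null
(Satterthwaite degrees of freedom when more than one stratum contributes).
For the balanced design this reproduces the classical exact split-plot
F tests.  Kenward-Roger degrees of freedom are not implemented in the
scientific Python stack; requesting them raises with a pointer to the
implemented methods.

``method="permutation"`` replaces the p-values of terms involving the
randomized treatments by design-based re-randomization p-values: the
shade assignment is re-drawn over all block subsets, the fertilization
assignment via the same quota-respecting sampler used when the design was
built, so the reference draws follow the exact randomization distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import nnls

from .design import PlotRecord, SpeciesInfo, monoculture_reference_table
from .errors import DesignError

__all__ = [
    "ModelSpec",
    "AnovaResult",
    "OneSampleTest",
    "community_model",
    "species_model",
    "add_composition_factors",
    "species_level_prepare",
    "fit_sequential_anova",
    "test_mean_against",
    "posthoc_lsmeans_diff",
]

_ALIAS_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Response, ordered fixed-effect terms and random intercept groupings."""

    response: str
    fixed: tuple[str, ...]
    random: tuple[str, ...]
    shade_col: str = "shade"
    fert_col: str = "fertilized"
    block_col: str = "block"
    composition_col: str = "composition"
    richness_col: str = "richness"
    plot_col: str = "plot_id"


def _treatment_interactions(main: tuple[str, ...]) -> tuple[str, ...]:
    shade, fert = main[0], main[1]
    others = main[2:]
    two_way = [f"{shade}:{fert}"]
    two_way += [f"{shade}:{o}" for o in others] + [f"{fert}:{o}" for o in others]
    # canonical entry order: shade x fert, then per covariate shade x, fert x
    ordered_two = [f"{shade}:{fert}"]
    for o in others:
        ordered_two += [f"{shade}:{o}", f"{fert}:{o}"]
    three_way = [f"{shade}:{fert}:{o}" for o in others]
    return tuple(ordered_two + three_way)


def community_model(response: str) -> ModelSpec:
    """Community-level model: shade, fert, log SR, FG and GS composition."""
    main = ("shade", "fertilized", "log_richness", "fg_comp", "gs_comp")
    return ModelSpec(
        response=response,
        fixed=main + _treatment_interactions(main),
        random=("block", "composition"),
    )


def species_model(response: str) -> ModelSpec:
    """Species-level model with FG and GS identity instead of composition."""
    main = ("shade", "fertilized", "log_richness", "fg_id", "gs_id")
    return ModelSpec(
        response=response,
        fixed=main + _treatment_interactions(main),
        random=("block", "composition", "species_id", "plot_id"),
    )


def add_composition_factors(
    frame: pd.DataFrame, species: list[SpeciesInfo]
) -> pd.DataFrame:
    """Attach log_richness, fg_comp and gs_comp columns to a design frame."""
    fg_of = {s.species_id: s.functional_group for s in species}
    gs_of = {s.species_id: s.stature for s in species}

    def _mix(values: set) -> str:
        return values.pop() if len(values) == 1 else "mixed"

    out = frame.copy()
    out["log_richness"] = np.log(out["richness"].astype(float))
    comps = out["composition"].str.split("+")
    out["fg_comp"] = [_mix({fg_of[s] for s in c}) for c in comps]
    out["gs_comp"] = [_mix({gs_of[s] for s in c}) for c in comps]
    return out


def species_level_prepare(
    table: pd.DataFrame,
    design: list[PlotRecord],
    species: list[SpeciesInfo],
    references: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per plot x species response table for species-level models.

    Biomass and relative yields are multiplied by sown species number S to
    correct for the decreasing sown proportion at higher richness; FG and GS
    identity covariates are attached.  Rows whose monoculture reference is
    non-positive get NA relative yields.
    """
    if references is None:
        references = monoculture_reference_table(table, design)
    ref = {(r.species_id, r.environment): r.biomass for r in references.itertuples()}
    biomass = {(r.plot_id, r.species_id): r.biomass for r in table.itertuples()}
    fg_of = {s.species_id: s.functional_group for s in species}
    gs_of = {s.species_id: s.stature for s in species}

    rows = []
    for plot in sorted(design, key=lambda p: p.plot_id):
        env = plot.environment.label
        for sp in plot.sown_species:
            y = biomass.get((plot.plot_id, sp), np.nan)
            m = ref.get((sp, env), np.nan)
            ry = y / m if np.isfinite(m) and m > 0 and np.isfinite(y) else np.nan
            rows.append(
                {
                    "plot_id": plot.plot_id,
                    "block": plot.block,
                    "composition": plot.composition,
                    "richness": plot.richness,
                    "log_richness": math.log(plot.richness),
                    "shade": plot.environment.shade,
                    "fertilized": plot.environment.fertilized,
                    "environment": env,
                    "species_id": sp,
                    "fg_id": fg_of[sp],
                    "gs_id": gs_of[sp],
                    "biomass": y,
                    "biomass_x_s": y * plot.richness,
                    "ry": ry,
                    "ry_x_s": ry * plot.richness if np.isfinite(ry) else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design-matrix construction

def _encode_factor(series: pd.Series) -> tuple[np.ndarray, list]:
    """Columns for one factor: treatment-coded dummies or the numeric value."""
    if series.dtype == bool:
        return series.to_numpy(dtype=float)[:, None], [True]
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(series))
        cols = np.column_stack(
            [(series == lev).to_numpy(dtype=float) for lev in levels[1:]]
        ) if len(levels) > 1 else np.empty((len(series), 0))
        return cols, levels[1:]
    return series.to_numpy(dtype=float)[:, None], ["linear"]


def _term_matrix(factors: dict[str, np.ndarray], term: str) -> np.ndarray:
    parts = [factors[name] for name in term.split(":")]
    m = parts[0]
    for nxt in parts[1:]:
        m = (m[:, :, None] * nxt[:, None, :]).reshape(len(m), -1)
    return m


def _indicator(series: pd.Series) -> np.ndarray:
    codes, levels = pd.factorize(series)
    z = np.zeros((len(series), len(levels)))
    z[np.arange(len(series)), codes] = 1.0
    return z


@dataclass
class _Block:
    name: str
    kind: str  # "fixed" | "stratum"
    df: int
    ss: float
    basis: np.ndarray  # n x df orthonormal
    keep: np.ndarray  # retained raw-column mask
    raw_first_col: np.ndarray | None = None  # for direction sign (1-df terms)


def _orthonormalize(raw: np.ndarray, q_prev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of raw columns beyond span(q_prev); returns (U, keep)."""
    c = raw - q_prev @ (q_prev.T @ raw)
    c = c - q_prev @ (q_prev.T @ c)  # second pass for stability
    keep = np.zeros(raw.shape[1], dtype=bool)
    scale = max(np.sqrt(len(raw)), float(np.abs(raw).max(initial=1.0)))
    basis_cols = []
    for j in range(c.shape[1]):
        v = c[:, j].copy()
        for u in basis_cols:
            v -= u * (u @ v)
        norm = np.linalg.norm(v)
        if norm > _ALIAS_TOL * scale:
            basis_cols.append(v / norm)
            keep[j] = True
    u = np.column_stack(basis_cols) if basis_cols else np.empty((len(raw), 0))
    return u, keep


def _decompose(
    y: np.ndarray,
    term_names: list[str],
    term_raw: dict[str, np.ndarray],
    strata_names: list[str],
    strata_raw: dict[str, np.ndarray],
) -> tuple[list[_Block], float, int]:
    n = len(y)
    q = np.ones((n, 1)) / math.sqrt(n)
    blocks: list[_Block] = []
    for name in term_names:
        raw = term_raw[name]
        u, keep = _orthonormalize(raw, q)
        proj = u.T @ y
        blocks.append(
            _Block(
                name=name,
                kind="fixed",
                df=u.shape[1],
                ss=float(proj @ proj),
                basis=u,
                keep=keep,
                raw_first_col=raw[:, 0] if raw.shape[1] else None,
            )
        )
        if u.shape[1]:
            q = np.hstack([q, u])
    for name in strata_names:
        raw = strata_raw[name]
        u, keep = _orthonormalize(raw, q)
        proj = u.T @ y
        blocks.append(
            _Block(name=name, kind="stratum", df=u.shape[1], ss=float(proj @ proj), basis=u, keep=keep)
        )
        if u.shape[1]:
            q = np.hstack([q, u])
    rank = q.shape[1]
    ss_res = float(y @ y - (q.T @ y) @ (q.T @ y))
    return blocks, max(ss_res, 0.0), n - rank


def _ems_coefficients(basis: np.ndarray, df: int, indicators: dict[str, np.ndarray]) -> dict[str, float]:
    if df == 0:
        return {g: 0.0 for g in indicators}
    return {g: float(np.sum((z.T @ basis) ** 2)) / df for g, z in indicators.items()}


@dataclass
class OneSampleTest:
    """Two-sided one-sample t-test of a mean against a reference value."""

    n: int
    mean: float
    sd: float
    se: float
    df: int
    t: float
    p: float
    reference: float
    note: str = ""


def test_mean_against(values, reference: float, blocks=None) -> OneSampleTest:
    """Test mean(values) != reference; optionally block-aware via block means."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    note = ""
    if blocks is not None:
        s = pd.Series(values).groupby(np.asarray(blocks)[: len(values)]).mean()
        values = s.to_numpy()
        note = "block-means variant"
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values for a one-sample test")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        # degenerate sample: all values identical.  Exact equality with the
        # reference cannot be rejected (t = 0, p = 1); any difference is
        # infinitely many standard errors away but p is undefined.
        exact = mean == reference
        return OneSampleTest(
            n=n, mean=mean, sd=0.0, se=0.0, df=n - 1,
            t=0.0 if exact else math.inf,
            p=1.0 if exact else float("nan"), reference=reference,
            note=(note + "; " if note else "")
            + ("zero variance: exact equality" if exact else "zero variance: p undefined"),
        )
    se = sd / math.sqrt(n)
    t = (mean - reference) / se
    p = 2 * stats.t.sf(abs(t), n - 1)
    return OneSampleTest(n=n, mean=mean, sd=sd, se=se, df=n - 1, t=float(t), p=float(p), reference=reference, note=note)


# ---------------------------------------------------------------------------
# the sequential ANOVA fit

@dataclass
class AnovaResult:
    """Sequential ANOVA table plus the internals needed for post-hoc work."""

    table: pd.DataFrame
    strata: pd.DataFrame
    spec: ModelSpec
    method: str
    data: pd.DataFrame = field(repr=False)
    _internals: dict = field(default_factory=dict, repr=False)


def _build_matrices(data: pd.DataFrame, spec: ModelSpec):
    factor_names = sorted({f for t in spec.fixed for f in t.split(":")})
    factors = {}
    factor_levels = {}
    for name in factor_names:
        if name not in data.columns:
            raise DesignError(f"model factor {name!r} missing from data")
        factors[name], factor_levels[name] = _encode_factor(data[name])
    term_raw = {t: _term_matrix(factors, t) for t in spec.fixed}
    strata_raw = {g: _indicator(data[g]) for g in spec.random}
    return factors, factor_levels, term_raw, strata_raw


def _match_error(
    term_ems: dict[str, float],
    strata_rows: list[tuple[str, dict[str, float], float, int]],
) -> tuple[np.ndarray, float, float, list[str]]:
    """Non-negative stratum-MS combination matching a term's EMS.

    Returns (weights, denominator MS, Satterthwaite df, stratum names).
    """
    groupings = sorted(term_ems)
    a_mat = np.array(
        [[1.0] + [ems[g] for g in groupings] for _, ems, _, _ in strata_rows]
    ).T  # rows: sigma_e + each grouping; cols: strata
    target = np.array([1.0] + [term_ems[g] for g in groupings])
    weights, _ = nnls(a_mat, target)
    ms = np.array([ms for _, _, ms, _ in strata_rows])
    dfs = np.array([df for _, _, _, df in strata_rows], dtype=float)
    denom = float(weights @ ms)
    contrib = weights * ms
    with np.errstate(divide="ignore", invalid="ignore"):
        denom_df = denom**2 / np.sum(
            np.where(dfs > 0, contrib**2 / np.maximum(dfs, 1e-300), np.inf)
        )
    used = [name for name, w in zip([s[0] for s in strata_rows], weights) if w > 1e-10]
    return weights, denom, float(denom_df), used


def fit_sequential_anova(
    data: pd.DataFrame,
    spec: ModelSpec,
    method: str = "satterthwaite",
    n_perm: int = 499,
    seed: int | None = 0,
    perm_terms=None,
) -> AnovaResult:
    """Sequential (type-I) F tests with the random structure of ``spec``.

    method:
      ``"satterthwaite"`` (default) - EMS stratum-F tests, Satterthwaite df
      where a term's error combines strata;
      ``"permutation"`` - same statistics, but terms involving the
      randomized treatments get design-based re-randomization p-values
      (``n_perm`` draws; the shade orbit is enumerated exhaustively);
      ``perm_terms`` optionally restricts which of those terms are
      re-randomized (the rest keep their stratum-F p-values);
      ``"kenward-roger"`` - unavailable, raises.
    """
    if method == "kenward-roger":
        raise NotImplementedError(
            "Kenward-Roger degrees of freedom are not available in this stack; "
            "use method='satterthwaite' or method='permutation'"
        )
    if method not in ("satterthwaite", "permutation"):
        raise ValueError(f"unknown df method {method!r}")

    data = data.reset_index(drop=True)
    mask = np.isfinite(data[spec.response].to_numpy(dtype=float))
    data = data.loc[mask].reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)

    factors, factor_levels, term_raw, strata_raw = _build_matrices(data, spec)
    blocks, ss_res, df_res = _decompose(y, list(spec.fixed), term_raw, list(spec.random), strata_raw)

    indicators = {g: strata_raw[g] for g in spec.random}
    n = len(y)

    strata_rows = []
    for b in blocks:
        if b.kind != "stratum" or b.df == 0:
            continue
        strata_rows.append((b.name, _ems_coefficients(b.basis, b.df, indicators), b.ss / b.df, b.df))
    # residual stratum: EMS coefficients follow from the trace identity
    # sum over a full orthonormal basis of ||Z' u||^2 = n per grouping
    if df_res > 0:
        used = {g: sum(r[1][g] * r[3] for r in strata_rows) for g in spec.random}
        fixed_part = {
            g: sum(
                _ems_coefficients(b.basis, b.df, {g: indicators[g]})[g] * b.df
                for b in blocks
                if b.kind == "fixed" and b.df > 0
            )
            + float(np.sum(indicators[g].mean(axis=0) ** 2)) * n  # intercept
            for g in spec.random
        }
        resid_ems = {
            g: max(n - used[g] - fixed_part[g], 0.0) / df_res for g in spec.random
        }
        strata_rows.append(("residual", resid_ems, ss_res / df_res, df_res))

    rows = []
    term_denoms = {}
    for b in blocks:
        if b.kind != "fixed":
            continue
        if b.df == 0:
            rows.append(
                {
                    "term": b.name, "df": 0, "ss": np.nan, "ms": np.nan, "f": np.nan,
                    "df_den": np.nan, "p": np.nan, "direction": "",
                    "error": "aliased with earlier terms", "method": "NA",
                }
            )
            continue
        ems = _ems_coefficients(b.basis, b.df, indicators)
        weights, denom, df_den, used_names = _match_error(ems, strata_rows)
        term_denoms[b.name] = weights
        ms = b.ss / b.df
        f = ms / denom if denom > 0 else np.inf
        p = float(stats.f.sf(f, b.df, df_den)) if denom > 0 else 0.0
        direction = ""
        if b.df == 1 and b.raw_first_col is not None:
            c_perp = b.basis[:, 0]
            beta = float(c_perp @ y) * float(np.sign(c_perp @ b.raw_first_col) or 1.0)
            direction = "+" if beta > 0 else "-" if beta < 0 else "0"
        rows.append(
            {
                "term": b.name, "df": b.df, "ss": b.ss, "ms": ms, "f": float(f),
                "df_den": df_den, "p": p, "direction": direction,
                "error": "+".join(used_names), "method": "stratum-F (satterthwaite)",
            }
        )
    table = pd.DataFrame(rows)
    strata_table = pd.DataFrame(
        [
            {"stratum": name, "df": df, "ms": ms, **{f"c_{g}": ems[g] for g in spec.random}}
            for name, ems, ms, df in strata_rows
        ]
    )

    internals = {
        "blocks": blocks,
        "factors": factors,
        "factor_levels": factor_levels,
        "term_raw": term_raw,
        "strata_raw": strata_raw,
        "strata_rows": strata_rows,
        "term_denoms": term_denoms,
        "y": y,
        "ss_res": ss_res,
        "df_res": df_res,
    }
    result = AnovaResult(
        table=table, strata=strata_table, spec=spec, method=method, data=data, _internals=internals
    )
    if method == "permutation":
        _apply_permutation(result, n_perm=n_perm, seed=seed, perm_terms=perm_terms)
    return result


# ---------------------------------------------------------------------------
# design-based re-randomization

def _term_orbit(term: str, spec: ModelSpec) -> str | None:
    parts = set(term.split(":"))
    has_shade = spec.shade_col in parts
    has_fert = spec.fert_col in parts
    if has_shade and has_fert:
        return "joint"
    if has_shade:
        return "shade"
    if has_fert:
        return "fert"
    return None


class _FastSS:
    """Sequential sums of squares via a Cholesky solve on the Gram matrix.

    The retained-column pattern of the base fit is frozen; per draw only the
    treatment-dependent columns are rebuilt.
    """

    def __init__(self, result: AnovaResult):
        self.spec = result.spec
        self.y = result._internals["y"]
        blocks = result._internals["blocks"]
        self.term_names = [b.name for b in blocks if b.kind == "fixed"]
        self.slices: dict[str, slice] = {}
        self.stratum_slices: dict[str, slice] = {}
        cols = [np.ones((len(self.y), 1))]
        start = 1
        self.keep = {}
        for b in blocks:
            raw = (
                result._internals["term_raw"][b.name]
                if b.kind == "fixed"
                else result._internals["strata_raw"][b.name]
            )
            kept = raw[:, b.keep]
            cols.append(kept)
            sl = slice(start, start + kept.shape[1])
            (self.slices if b.kind == "fixed" else self.stratum_slices)[b.name] = sl
            self.keep[b.name] = b.keep
            start += kept.shape[1]
        self.x = np.ascontiguousarray(np.hstack(cols))
        self.factors = dict(result._internals["factors"])
        self.df_total = self.x.shape[1]
        # segment starts (intercept first) for np.add.reduceat block sums;
        # zero-df blocks are skipped (reduceat cannot express empty segments)
        all_slices = {**self.slices, **self.stratum_slices}
        self.block_order = [
            b.name for b in blocks if all_slices[b.name].stop > all_slices[b.name].start
        ]
        self.starts = np.array(
            [0] + [all_slices[n].start for n in self.block_order], dtype=np.intp
        )
        self.terms_by_factor: dict[str, list[str]] = {}
        for name in self.term_names:
            for f in name.split(":"):
                self.terms_by_factor.setdefault(f, []).append(name)
        self.yty = float(self.y @ self.y)

    def rebuild(self, changed_factors: dict[str, np.ndarray]):
        factors = {**self.factors, **changed_factors}
        todo = {n for f in changed_factors for n in self.terms_by_factor.get(f, [])}
        for name in todo:
            raw = _term_matrix(factors, name)
            self.x[:, self.slices[name]] = raw[:, self.keep[name]]

    def sequential_ss(self) -> tuple[np.ndarray, float, int]:
        """Per-block sums of squares (order: self.block_order), residual SS/df."""
        g = self.x.T @ self.x
        v = self.x.T @ self.y
        try:
            lo = linalg.cholesky(g, lower=True, check_finite=False)
            z = linalg.solve_triangular(lo, v, lower=True, check_finite=False)
        except linalg.LinAlgError:
            q, _ = np.linalg.qr(self.x)
            z = q.T @ self.y
        z2 = z * z
        sums = np.add.reduceat(z2, self.starts)
        ss_res = max(self.yty - float(z2.sum()), 0.0)
        return sums[1:], ss_res, len(self.y) - self.df_total


class _OrbitSampler:
    """Re-randomization draws of the treatment labels, numpy-optimized.

    Quotas and per-composition fertilization counts for the observed shade
    assignment come from the data (conditional randomization, exact also for
    subsets such as mixtures-only tables); for joint shade + fertilization
    draws the balanced design rule (half of each composition's replicates,
    equal numbers per block) is applied to the re-drawn shade halves.
    """

    def __init__(self, plots: pd.DataFrame, rng):
        self.rng = rng
        self.plot_ids = plots.index.to_numpy()
        self.block = plots["block"].to_numpy()
        self.comp = pd.factorize(plots["composition"])[0]
        self.richness = plots["richness"].to_numpy()
        self.shade_obs = plots["shade"].to_numpy(dtype=bool)
        self.fert_obs = plots["fertilized"].to_numpy(dtype=bool)
        self.blocks_shaded_obs = np.unique(self.block[self.shade_obs])
        self.all_blocks = np.unique(self.block)
        self.cells_obs = self._build_cells(self.shade_obs, observed=True)

    def _build_cells(self, shade: np.ndarray, observed: bool):
        cells = []
        for sh in (False, True):
            for r in np.unique(self.richness):
                idxs = np.flatnonzero((shade == sh) & (self.richness == r))
                if not len(idxs):
                    continue
                if observed:
                    quotas: dict = {}
                    for i in idxs:
                        quotas[self.block[i]] = quotas.get(self.block[i], 0) + int(
                            self.fert_obs[i]
                        )
                else:
                    blocks_in = np.unique(self.block[idxs])
                    per_block = len(idxs) // (2 * len(blocks_in))
                    quotas = {b: per_block for b in blocks_in}
                by_comp: dict[int, list] = {}
                for i in idxs:
                    by_comp.setdefault(self.comp[i], []).append((int(i), self.block[i]))
                groups = []
                for c, items in by_comp.items():
                    if observed:
                        needed = int(sum(self.fert_obs[i] for i, _ in items))
                    else:
                        needed = len(items) // 2
                    groups.append((needed, items))
                cells.append((groups, quotas))
        return cells

    def draw_fert(self, cells=None) -> np.ndarray:
        from .design import _sample_balanced_labels

        fert = np.zeros(len(self.block), dtype=bool)
        for groups, quotas in cells if cells is not None else self.cells_obs:
            try:
                chosen = _sample_balanced_labels(groups, quotas, self.rng, max_tries=50)
            except DesignError:
                # fall back: shuffle the observed labels within blocks
                for b in quotas:
                    idx = np.array([i for _, items in groups for i, bl in items if bl == b])
                    labels = self.fert_obs[idx].copy()
                    self.rng.shuffle(labels)
                    fert[idx] = labels
                continue
            fert[list(chosen)] = True
        return fert

    def shade_assignments(self, n_perm: int):
        n_shaded = len(self.blocks_shaded_obs)
        subsets = list(itertools.combinations(self.all_blocks.tolist(), n_shaded))
        if len(subsets) <= max(n_perm, 500):
            return subsets, True
        idx = self.rng.choice(len(subsets), size=n_perm, replace=True)
        return [subsets[i] for i in idx], False

    def shade_vector(self, shaded_blocks) -> np.ndarray:
        return np.isin(self.block, np.asarray(list(shaded_blocks))).astype(float)


def _apply_permutation(
    result: AnovaResult, n_perm: int, seed: int | None, perm_terms=None
) -> None:
    spec = result.spec
    data = result.data
    rng = np.random.default_rng(seed)
    engine = _FastSS(result)

    plot_cols = [
        spec.plot_col, spec.block_col, spec.composition_col,
        spec.richness_col, spec.shade_col, spec.fert_col,
    ]
    plots = data[plot_cols].drop_duplicates(spec.plot_col).set_index(spec.plot_col)
    plots = plots.rename(
        columns={
            spec.block_col: "block", spec.composition_col: "composition",
            spec.richness_col: "richness", spec.shade_col: "shade",
            spec.fert_col: "fertilized",
        }
    )
    sampler = _OrbitSampler(plots, rng)
    pos_of_plot = {pid: k for k, pid in enumerate(sampler.plot_ids)}
    row_idx = np.array([pos_of_plot[p] for p in data[spec.plot_col]])

    orbit_terms: dict[str, list[str]] = {"shade": [], "fert": [], "joint": []}
    for term in spec.fixed:
        orbit = _term_orbit(term, spec)
        if orbit and (perm_terms is None or term in perm_terms):
            orbit_terms[orbit].append(term)

    # precomputed lookups for fast per-draw F statistics
    strata_rows = result._internals["strata_rows"]
    strat_names = [r[0] for r in strata_rows]
    strat_dfs = np.array([r[3] for r in strata_rows], dtype=float)
    term_df = {b.name: b.df for b in result._internals["blocks"] if b.kind == "fixed" and b.df > 0}
    denom_w = result._internals["term_denoms"]
    pos = {name: i for i, name in enumerate(engine.block_order)}
    orbit_names = list(denom_w)
    w_mat = np.vstack([denom_w[n] for n in orbit_names]) if orbit_names else np.empty((0, len(strat_names)))
    t_df = np.array([term_df[n] for n in orbit_names], dtype=float)
    t_pos = np.array([pos[n] for n in orbit_names], dtype=np.intp)
    s_is_res = np.array([nm == "residual" for nm in strat_names])
    s_pos = np.array([pos.get(nm, 0) for nm in strat_names], dtype=np.intp)

    def f_stats(sums, ss_res, df_res):
        resid_ms = ss_res / df_res if df_res > 0 else np.nan
        ms = np.where(s_is_res, resid_ms, sums[s_pos] / strat_dfs)
        denom = w_mat @ ms
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(denom > 0, (sums[t_pos] / t_df) / denom, np.inf)
        return dict(zip(orbit_names, f))

    # engine-based observed statistics for comparability with the draws
    f_obs = f_stats(*engine.sequential_ss())

    counts = {t: 0 for t in f_obs}
    totals = {t: 0 for t in f_obs}

    def _count(draw_f, terms):
        for t in terms:
            totals[t] += 1
            if draw_f[t] >= f_obs[t] - 1e-12:
                counts[t] += 1

    def _per_row(plot_level: np.ndarray, name: str) -> dict[str, np.ndarray]:
        return {name: plot_level[row_idx].astype(float)[:, None]}

    shade_note = ""
    if orbit_terms["shade"]:
        subsets, exhaustive = sampler.shade_assignments(n_perm)
        for subset in subsets:
            engine.rebuild(_per_row(sampler.shade_vector(subset), spec.shade_col))
            _count(f_stats(*engine.sequential_ss()), orbit_terms["shade"])
        engine.rebuild(_per_row(sampler.shade_obs.astype(float), spec.shade_col))
        shade_note = f"shade orbit, {len(subsets)} assignments" + (
            " (exhaustive)" if exhaustive else ""
        )
    if orbit_terms["fert"]:
        for _ in range(n_perm):
            engine.rebuild(_per_row(sampler.draw_fert(), spec.fert_col))
            _count(f_stats(*engine.sequential_ss()), orbit_terms["fert"])
        engine.rebuild(_per_row(sampler.fert_obs.astype(float), spec.fert_col))
    if orbit_terms["joint"]:
        n_shaded = len(sampler.blocks_shaded_obs)
        for _ in range(n_perm):
            subset = rng.choice(sampler.all_blocks, size=n_shaded, replace=False)
            shade_vec = sampler.shade_vector(subset)
            cells = sampler._build_cells(shade_vec.astype(bool), observed=False)
            fert_vec = sampler.draw_fert(cells)
            engine.rebuild(
                {
                    **_per_row(shade_vec, spec.shade_col),
                    **_per_row(fert_vec, spec.fert_col),
                }
            )
            _count(f_stats(*engine.sequential_ss()), orbit_terms["joint"])
        engine.rebuild(
            {
                **_per_row(sampler.shade_obs.astype(float), spec.shade_col),
                **_per_row(sampler.fert_obs.astype(float), spec.fert_col),
            }
        )

    for i, row in result.table.iterrows():
        term = row["term"]
        orbit = _term_orbit(term, spec)
        in_orbit = orbit is not None and term in orbit_terms.get(orbit, [])
        if not in_orbit or totals.get(term, 0) == 0:
            continue
        if orbit == "shade":
            # exhaustively enumerated orbit includes the observed assignment
            p = counts[term] / totals[term]
            note = shade_note
        else:
            # +1 convention: the observed assignment joins the sampled draws
            p = (1 + counts[term]) / (1 + totals[term])
            note = f"{orbit} orbit, {totals[term]} draws"
        result.table.loc[i, "p"] = p
        result.table.loc[i, "df_den"] = np.nan
        result.table.loc[i, "method"] = f"permutation ({note})"


# ---------------------------------------------------------------------------
# post-hoc least-squares means

def posthoc_lsmeans_diff(result: AnovaResult, factor: str) -> pd.DataFrame:
    """All pairwise least-squares-mean differences for a categorical factor.

    Least-squares means are model predictions averaged over a balanced
    reference grid of the other categorical factors (continuous covariates
    at their mean).  Differences are tested against the factor's error
    stratum with its Satterthwaite denominator df; p-values are unadjusted.
    """
    internals = result._internals
    factor_levels = internals["factor_levels"]
    if factor not in factor_levels:
        raise ValueError(f"{factor!r} is not a factor of the fitted model")
    data = result.data
    levels_of = {}
    for name in factor_levels:
        col = data[name]
        if col.dtype == bool or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels_of[name] = sorted(pd.unique(col))
        else:
            levels_of[name] = [float(col.mean())]
    target_levels = levels_of[factor]
    if len(target_levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")

    # full-rank fixed design (retained columns of each term, intercept first)
    blocks = [b for b in internals["blocks"] if b.kind == "fixed"]
    x_cols = [np.ones((len(data), 1))]
    for b in blocks:
        x_cols.append(internals["term_raw"][b.name][:, b.keep])
    x = np.hstack(x_cols)
    y = internals["y"]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    xtx_inv = np.linalg.pinv(x.T @ x)

    # grid factors are encoded against the data's levels, not the grid's own
    def _grid_vector(level):
        names = list(levels_of)
        combos = list(
            itertools.product(*[[level] if nm == factor else levels_of[nm] for nm in names])
        )
        vecs = []
        for combo in combos:
            factors = {}
            for nm, val in zip(names, combo):
                if data[nm].dtype == bool:
                    factors[nm] = np.array([[float(val)]])
                elif data[nm].dtype == object or isinstance(data[nm].dtype, pd.CategoricalDtype):
                    levs = sorted(pd.unique(data[nm]))
                    factors[nm] = np.array([[1.0 if val == lv else 0.0 for lv in levs[1:]]])
                else:
                    factors[nm] = np.array([[float(val)]])
            row = [np.ones((1, 1))]
            for b in blocks:
                raw = _term_matrix(factors, b.name)
                row.append(raw[:, b.keep])
            vecs.append(np.hstack(row)[0])
        return np.mean(vecs, axis=0)

    # error stratum of the factor's own term
    row = result.table.set_index("term")
    if factor not in row.index or row.loc[factor, "df"] == 0:
        raise ValueError(f"term {factor!r} is not estimable in this model")
    ms_err = None
    weights = internals["term_denoms"].get(factor)
    strata_ms = np.array([r[2] for r in internals["strata_rows"]])
    ms_err = float(weights @ strata_ms) if weights is not None else internals["ss_res"] / internals["df_res"]
    df_err = float(row.loc[factor, "df_den"])
    if not np.isfinite(df_err):  # permutation method blanks df_den
        df_err = internals["df_res"]

    grid = {lv: _grid_vector(lv) for lv in target_levels}
    out = []
    for a, b in itertools.combinations(target_levels, 2):
        c = grid[a] - grid[b]
        est = float(c @ beta)
        var = ms_err * float(c @ xtx_inv @ c)
        se = math.sqrt(max(var, 0.0))
        t = est / se if se > 0 else (0.0 if est == 0 else math.inf)
        p = 2 * stats.t.sf(abs(t), df_err) if se > 0 else float("nan")
        out.append(
            {"level_a": a, "level_b": b, "estimate": est, "se": se, "df": df_err, "t": t, "p": p}
        )
    return pd.DataFrame(out)
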