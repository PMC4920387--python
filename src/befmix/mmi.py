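"""All-subsets multimodel inference for trait-based predictors.

Candidate models are linear mixed models with a random intercept for block,
containing every subset of the predictor columns up to ``max_terms``
predictors (the cap guards against overfitting at n around 60).  Models are
fitted by maximum likelihood so that AIC values are comparable across fixed
structures, ranked by AIC (or small-sample AICc), and summarized by Akaike
weights.  Coefficients are model-averaged over the confidence set
(delta AIC below a threshold) with the full-average (zero-substitution)
convention and unconditional variances; the relative importance of a
predictor is the summed (renormalized) Akaike weight of the retained models
containing it.

The random-intercept ML fit is profiled analytically: with V proportional
to I + lambda Z Z' for a grouping Z, the inverse square root of each
group's I + lambda J block is I - c J with c = (1 - 1/sqrt(1 + lambda n_g))
/ n_g, so for a given variance ratio lambda the fixed effects reduce to
ordinary least squares on whitened data and only a one-dimensional
optimization over log lambda remains.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "RandomInterceptFit",
    "MMIResult",
    "akaike_weights",
    "fit_random_intercept_ml",
    "all_subsets_mmi",
    "model_average",
]

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


def akaike_weights(deltas) -> np.ndarray:
    """Akaike evidence weights w_m = exp(-delta_m/2) / sum exp(-delta/2)."""
    deltas = np.asarray(deltas, dtype=float)
    raw = np.exp(-deltas / 2.0)
    return raw / raw.sum()


@dataclass(frozen=True)
class RandomInterceptFit:
    """ML fit of y = X beta + u_group + e with a single random intercept."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance
    lambda_ratio: float  # var(u) / var(e)
    loglik: float
    n_params: int  # fixed coefficients + residual variance + random variance
    aic: float
    aicc: float
    n: int


class _Whitener:
    """Precomputed group structure for the profiled ML objective."""

    def __init__(self, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.order = order
        sorted_groups = np.asarray(groups)[order]
        change = np.flatnonzero(
            np.r_[True, sorted_groups[1:] != sorted_groups[:-1]]
        )
        self.starts = change.astype(np.intp)
        self.sizes = np.diff(np.r_[self.starts, len(groups)]).astype(float)
        self.repeat_idx = np.repeat(np.arange(len(self.starts)), self.sizes.astype(int))

    def whiten(self, a: np.ndarray, lam: float) -> np.ndarray:
        """Rows must already be in self.order."""
        if lam <= 0:
            return a
        c = (1.0 - 1.0 / np.sqrt(1.0 + lam * self.sizes)) / self.sizes
        sums = np.add.reduceat(a, self.starts, axis=0)
        return a - (c[self.repeat_idx, None] * sums[self.repeat_idx])

    def logdet(self, lam: float) -> float:
        return float(np.sum(np.log1p(lam * self.sizes)))


def _profile_nll(lam: float, xs: np.ndarray, ys: np.ndarray, wh: _Whitener):
    xw = wh.whiten(xs, lam)
    yw = wh.whiten(ys[:, None], lam)[:, 0]
    g = xw.T @ xw
    v = xw.T @ yw
    try:
        beta = np.linalg.solve(g, v)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(xw, yw, rcond=None)[0]
    resid = yw - xw @ beta
    n = len(yw)
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    nll = 0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0) + wh.logdet(lam))
    return nll, beta, sigma2, g


def fit_random_intercept_ml(
    x: np.ndarray, y: np.ndarray, groups, use_aicc: bool = False
) -> RandomInterceptFit:
    """Profiled-ML fit of a linear model with a random intercept per group.

    ``x`` must include the intercept column if one is wanted.  The parameter
    count for AIC is the number of fixed coefficients plus two variance
    components, matching the convention of ML-fitted mixed models.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("x must be 2-D with one row per observation in y")
    wh = _Whitener(np.asarray(groups))
    xs = x[wh.order]
    ys = y[wh.order]

    def obj(log_lam: float) -> float:
        return _profile_nll(math.exp(log_lam), xs, ys, wh)[0]

    res = minimize_scalar(obj, bounds=_LOG_LAMBDA_BOUNDS, method="bounded")
    # the boundary lambda -> 0 (pure OLS) is outside the log grid; compare
    nll0 = _profile_nll(0.0, xs, ys, wh)[0]
    if nll0 <= res.fun:
        lam, nll = 0.0, nll0
    else:
        lam, nll = math.exp(res.x), float(res.fun)
    _, beta, sigma2, g = _profile_nll(lam, xs, ys, wh)
    cov = sigma2 * np.linalg.pinv(g)
    k = x.shape[1] + 2
    n = len(y)
    aic = 2 * k + 2 * nll
    denom = n - k - 1
    aicc = aic + (2 * k * (k + 1) / denom if denom > 0 else math.inf)
    return RandomInterceptFit(
        beta=beta, cov_beta=cov, sigma2=sigma2, lambda_ratio=lam,
        loglik=-nll, n_params=k, aic=aic, aicc=aicc, n=n,
    )


@dataclass
class MMIResult:
    """Ranked all-subsets candidate models plus their fits."""

    models: pd.DataFrame  # terms, k, loglik, aic(c), delta, weight
    predictors: tuple[str, ...]
    response: str
    criterion: str
    fits: list = field(repr=False, default_factory=list)


def all_subsets_mmi(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    group_col: str = "block",
    max_terms: int = 3,
    use_aicc: bool = False,
) -> MMIResult:
    """Fit every predictor subset of size 0..max_terms and rank by AIC.

    Each model is a random-intercept (per ``group_col``) ML fit of
    ``response`` on an intercept plus the subset; rows with any missing
    value in the response or a used predictor are dropped listwise over the
    full predictor set so every model sees identical data (an AIC
    requirement).
    """
    cols = [response] + list(predictors) + [group_col]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns missing from data: {missing}")
    frame = data[cols].dropna()
    if len(frame) <= max_terms + 3:
        raise ValueError(
            f"only {len(frame)} complete rows; too few for {max_terms}-term models"
        )
    y = frame[response].to_numpy(dtype=float)
    groups = frame[group_col].to_numpy()
    x_all = frame[list(predictors)].to_numpy(dtype=float)
    ones = np.ones((len(frame), 1))

    rows = []
    fits = []
    for size in range(0, max_terms + 1):
        for subset in itertools.combinations(range(len(predictors)), size):
            x = np.hstack([ones, x_all[:, list(subset)]]) if subset else ones
            fit = fit_random_intercept_ml(x, y, groups, use_aicc=use_aicc)
            rows.append(
                {
                    "terms": tuple(predictors[i] for i in subset),
                    "k": fit.n_params,
                    "loglik": fit.loglik,
                    "criterion_value": fit.aicc if use_aicc else fit.aic,
                }
            )
            fits.append(fit)
    models = pd.DataFrame(rows)
    best = models["criterion_value"].min()
    models["delta"] = models["criterion_value"] - best
    models["weight"] = akaike_weights(models["delta"].to_numpy())
    order = models["criterion_value"].sort_values().index
    models = models.loc[order].reset_index(drop=True)
    fits = [fits[i] for i in order]
    return MMIResult(
        models=models,
        predictors=tuple(predictors),
        response=response,
        criterion="AICc" if use_aicc else "AIC",
        fits=fits,
    )


def model_average(result: MMIResult, delta_threshold: float = 4.0) -> pd.DataFrame:
    """Full-average coefficients over the delta < threshold confidence set.

    Absent predictors contribute zero to a model's coefficient
    (zero-substitution / full average); the unconditional variance combines
    within-model variance and between-model spread.  ``importance`` is the
    summed renormalized Akaike weight of the retained models containing the
    predictor, so a predictor absent from every retained model has both
    estimate 0 and importance 0, and the predictors of a single retained
    model all have importance 1.
    """
    models = result.models
    in_set = models["delta"] < delta_threshold
    if not in_set.any():
        raise ValueError("empty confidence set; threshold too small")
    w = models.loc[in_set, "weight"].to_numpy()
    w = w / w.sum()
    set_fits = [f for f, keep in zip(result.fits, in_set) if keep]
    set_terms = [t for t, keep in zip(models["terms"], in_set) if keep]

    out = []
    for name in result.predictors:
        betas = np.zeros(len(set_fits))
        variances = np.zeros(len(set_fits))
        for i, (fit, terms) in enumerate(zip(set_fits, set_terms)):
            if name in terms:
                j = 1 + terms.index(name)  # after the intercept
                betas[i] = fit.beta[j]
                variances[i] = fit.cov_beta[j, j]
        est = float(w @ betas)
        var = float(w @ (variances + (betas - est) ** 2))
        contains = np.array([name in t for t in set_terms])
        importance = float(w[contains].sum())
        out.append(
            {
                "predictor": name,
                "estimate": est,
                "se": math.sqrt(max(var, 0.0)),
                "importance": importance,
                "n_models_in_set": int(sum(name in t for t in set_terms)),
            }
        )
    return pd.DataFrame(out).sort_values("importance", ascending=False).reset_index(drop=True)
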