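"""Fitness models: relative fitness, fixed-origin regressions, AICc, sweeps.

The central comparison is between predictors of MA-line relative fitness:
the count of mutant proteins (psi_tot), the count classified deleterious
(psi_del), absolute-score counts, essential-gene-restricted counts, and the
log-compressed score sum (sigma_tot).  Controls carry zero mutations and —
by construction of relative fitness — zero fitness change, so the regressions
run through the origin; candidate models are ranked by second-order AIC,

    AICc = -2 ln L + 2K + 2K(K+1) / (n - K - 1),

with K counting every estimated parameter including variance components.
All AICc-compared fits use maximum likelihood (not REML) so likelihoods are
comparable across fixed-effect structures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .interchange import GrowthTable

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Relative fitness and repeatability
# ---------------------------------------------------------------------------

def relative_fitness(
    growth: GrowthTable,
    matching: tuple[str, ...] = ("ancestor_id", "environment"),
    response_mode: str = "signed",
    allow_missing_controls: bool = False,
) -> pd.DataFrame:
    """Per-line relative fitness: block-centred line mean minus control mean.

    Measurements are centred by assay-block mean (so a constant offset added
    to one block cancels); each MA line's centred replicate mean is compared
    with the centred mean of control replicates sharing its matching factors.
    ``response_mode='absolute'`` returns |relative fitness| — used for data
    sets where fitness moves in both directions without a mean trend.
    """
    if response_mode not in {"signed", "absolute"}:
        raise ModelError(f"unknown response_mode {response_mode!r}")
    df = growth.data.copy()
    df["_centred"] = df["growth_rate"] - df.groupby("block")["growth_rate"].transform("mean")
    controls = df[df["role"] == "control"]
    ma = df[df["role"] == "ma"]
    control_means = controls.groupby(list(matching))["_centred"].mean()
    rows = []
    for key, sub in ma.groupby(list(matching)):
        key = key if isinstance(key, tuple) else (key,)
        try:
            cmean = control_means.loc[key if len(key) > 1 else key[0]]
        except KeyError:
            if not allow_missing_controls:
                raise ModelError(
                    f"MA lines with matching factors {dict(zip(matching, key))} "
                    "have no matched control rows")
            cmean = 0.0
        for line_id, line_sub in sub.groupby("line_id"):
            value = float(line_sub["_centred"].mean() - cmean)
            rows.append((line_id, value))
    out = pd.DataFrame(rows, columns=["line_id", "relative_fitness"])
    if response_mode == "absolute":
        out["relative_fitness"] = out["relative_fitness"].abs()
    return out


def icc_and_variance(growth: GrowthTable, role: str = "ma") -> tuple[float, float]:
    """Intraclass correlation for line identity among replicated measurements.

    One-way random-effects decomposition (random line intercept, ML mixed
    model): icc = var_line / (var_line + var_resid).  Also returned as the
    percentage of variance attributable to line identity.
    """
    df = growth.data[growth.data["role"] == role]
    sizes = df.groupby("line_id").size()
    if len(sizes) < 2 or (sizes < 2).all():
        raise ModelError("ICC needs at least two lines with replicate measurements")
    model = MixedLM(df["growth_rate"].to_numpy(),
                    np.ones((len(df), 1)),
                    groups=df["line_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    var_line = float(np.asarray(fit.cov_re)[0, 0])
    var_resid = float(fit.scale)
    icc = var_line / (var_line + var_resid)
    return icc, 100.0 * icc


def environment_interaction_pretest(growth: GrowthTable) -> tuple[float, float]:
    """F-test of the role x environment interaction on growth rate.

    A non-significant interaction justifies pooling environments before
    computing relative fitness.
    """
    df = growth.data
    if df["environment"].nunique() < 2:
        raise ModelError("pre-test needs at least two environments")
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    fit = ols("growth_rate ~ C(role) * C(environment)", data=df).fit()
    table = anova_lm(fit, typ=2)
    row = table.loc["C(role):C(environment)"]
    return float(row["F"]), float(row["PR(>F)"])


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    name: str
    predictor_names: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float
    K: int
    n: int
    flags: tuple[str, ...] = ()
    random_slope_sd: float | None = None

    @property
    def AIC(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.K

    @property
    def AICc(self) -> float:
        return aicc(self.log_likelihood, self.K, self.n)


def aicc(log_likelihood: float, K: int, n: int) -> float:
    if n - K - 1 <= 0:
        return float("inf")
    return -2.0 * log_likelihood + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def fit_origin_lm(
    data: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...],
    covariates: tuple[str, ...] = (),
    free_intercept: bool = False,
    name: str | None = None,
) -> ModelFit:
    """Least-squares fit of the response on predictors, intercept fixed at 0.

    ``free_intercept=True`` refits with an estimated intercept — the
    sensitivity analysis for settings without control genotypes.  This is a
    distinct design matrix, not an origin point added to the data.
    """
    if not predictors:
        raise ModelError("at least one predictor is required")
    cols = list(predictors) + list(covariates)
    X = data[cols].astype(float)
    for c in cols:
        if (X[c] == 0).all():
            raise ModelError(f"predictor {c!r} is identically zero; slope unidentifiable")
    if X[cols].isna().any().any() or data[response].isna().any():
        raise ModelError("missing values in model frame")
    if free_intercept:
        X = sm.add_constant(X)
    y = data[response].astype(float)
    fit = sm.OLS(y, X).fit()
    K = len(fit.params) + 1  # + residual variance
    return ModelFit(
        name=name or "+".join(predictors),
        predictor_names=tuple(predictors),
        coefficients=dict(fit.params),
        standard_errors=dict(fit.bse),
        p_values=dict(fit.pvalues),
        log_likelihood=float(fit.llf),
        K=K, n=int(fit.nobs))


def fit_origin_mixed(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    group: str,
    covariates: tuple[str, ...] = (),
    name: str | None = None,
) -> ModelFit:
    """Through-origin fit with a per-group random slope, estimated by ML.

    The fixed slope is shared; each group (ancestral background) gets a
    random deviation of the slope, no intercepts anywhere.  A near-zero
    random-slope variance is flagged ``singular`` rather than hidden.
    """
    if data[group].nunique() < 2:
        raise ModelError("mixed model needs at least two groups")
    cols = [predictor] + list(covariates)
    X = data[cols].astype(float).to_numpy()
    if (X[:, 0] == 0).all():
        raise ModelError(f"predictor {predictor!r} is identically zero")
    y = data[response].astype(float).to_numpy()
    exog_re = data[[predictor]].astype(float).to_numpy()
    groups = data[group].to_numpy()
    # the default optimizer chain can collapse to a degenerate boundary fit
    # (infinite likelihood, zeroed fixed effect); try several and keep the
    # best finite ML solution
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("powell", "nm", "bfgs", "lbfgs"):
            try:
                cand = MixedLM(y, X, groups=groups, exog_re=exog_re).fit(
                    reml=False, method=method, maxiter=2000)
            except Exception:
                continue
            if not np.isfinite(cand.llf) or not np.all(np.isfinite(cand.fe_params)):
                continue
            if fit is None or (bool(cand.converged), cand.llf) > (bool(fit.converged), fit.llf):
                fit = cand
            if fit.converged:
                break
    if fit is None:
        raise ModelError("mixed-model fit failed for every optimizer")
    flags = []
    if not fit.converged:
        flags.append("nonconverged")
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    scale = float(fit.scale)
    if re_var <= 1e-10 * max(scale, 1e-12):
        flags.append("singular")
    K = len(cols) + 2  # fixed effects + random-slope variance + residual variance
    coef = {c: float(v) for c, v in zip(cols, fit.fe_params)}
    ses = {c: float(s) for c, s in zip(cols, np.asarray(fit.bse_fe))}
    pvals = {c: float(p) for c, p in zip(cols, fit.pvalues[:len(cols)])}
    return ModelFit(
        name=name or f"{predictor}|{group}",
        predictor_names=(predictor,),
        coefficients=coef, standard_errors=ses, p_values=pvals,
        log_likelihood=float(fit.llf), K=K, n=len(y),
        flags=tuple(flags), random_slope_sd=float(np.sqrt(max(re_var, 0.0))))


def model_selection_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits on the same response by AICc, ascending, with deltas."""
    if not fits:
        raise ModelError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ModelError(f"fits use different response data (n = {sorted(ns)})")
    rows = [(f.name, f.K, f.log_likelihood, f.AIC, f.AICc) for f in fits]
    table = pd.DataFrame(rows, columns=["model", "K", "logLik", "AIC", "AICc"])
    table = table.sort_values("AICc", kind="mergesort").reset_index(drop=True)
    table["delta_AICc"] = table["AICc"] - table["AICc"].iloc[0]
    return table


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    thresholds: np.ndarray
    AICc_per_threshold: np.ndarray       # NaN where the cutoff is degenerate
    proportion_deleterious: np.ndarray
    best_threshold: float


def default_grid(start: float = -10.0, stop: float = 0.0, step: float = 0.25) -> np.ndarray:
    return np.round(np.arange(start, stop + step / 2, step), 10)


def threshold_sweep(
    scores: pd.DataFrame,
    fitness: pd.DataFrame,
    grid: np.ndarray | None = None,
    mixed_group: str | None = None,
    group_map: dict[str, str] | None = None,
    covariates: tuple[str, ...] = (),
) -> SweepResult:
    """Refit the psi_del model across a grid of deleterious cutoffs.

    ``scores`` is a per-variant frame with ``line_id`` and ``score``;
    ``fitness`` a per-line frame with ``relative_fitness`` (and covariates).
    For each cutoff the per-line deleterious count is recomputed and the
    origin model refitted; cutoffs where every line has zero deleterious
    proteins are recorded as undefined rather than fitted.  The pooled
    proportion of mutant proteins classified deleterious accompanies each
    cutoff; the best threshold minimises AICc.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ModelError("empty threshold grid")
    sc = scores.dropna(subset=["score"])
    merged_template = fitness.copy()
    aiccs = np.full(grid.size, np.nan)
    props = np.zeros(grid.size)
    for k, cut in enumerate(grid):
        del_counts = sc[sc["score"] < cut].groupby("line_id").size()
        data = merged_template.copy()
        data["psi_del"] = data["line_id"].map(del_counts).fillna(0).astype(float)
        props[k] = float((sc["score"] < cut).mean())
        if (data["psi_del"] == 0).all():
            continue
        if mixed_group is not None:
            if mixed_group not in data.columns:
                data[mixed_group] = data["line_id"].map(group_map or {})
            try:
                fit = fit_origin_mixed(data, "relative_fitness", "psi_del",
                                       mixed_group, covariates)
            except Exception:  # degenerate grid points must not kill the sweep
                continue
        else:
            fit = fit_origin_lm(data, "relative_fitness", ("psi_del",), covariates)
        aiccs[k] = fit.AICc
    if np.isnan(aiccs).all():
        raise ModelError("no cutoff on the grid produced a fittable model")
    best = float(grid[int(np.nanargmin(aiccs))])
    return SweepResult(grid, aiccs, props, best)
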