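"""Reference-bias analysis: ancestral variants versus new MA mutations.

Variants separating a laboratory ancestor from the reference genome have
been exposed to natural selection, unlike the (nearly) selection-free new
mutations of MA lines, so their score distributions should differ.  This
module provides the comparisons used for that contrast: a 2x2 deleterious
classification table with Fisher's exact test, a two-sided rank-sum test on
the raw scores, bootstrap confidence intervals for median scores, and a
grouped (random-intercept by ancestral strain) logistic model of deleterious
status on variant origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)


class RefBiasError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Deleterious contingency
# ---------------------------------------------------------------------------

def deleterious_contingency(
    new_scores: np.ndarray,
    ancestral_scores: np.ndarray,
    threshold: float = -2.5,
) -> tuple[np.ndarray, float]:
    """2x2 table {new, ancestral} x {deleterious, neutral} + Fisher exact p.

    Both score sets are classified at the same threshold (strictly below =
    deleterious); the two-sided p-value is exact, by hypergeometric
    enumeration of tables with the observed margins.
    """
    new_scores = np.asarray(new_scores, dtype=float)
    ancestral_scores = np.asarray(ancestral_scores, dtype=float)
    table = np.array([
        [int((new_scores < threshold).sum()), int((new_scores >= threshold).sum())],
        [int((ancestral_scores < threshold).sum()), int((ancestral_scores >= threshold).sum())],
    ])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise RefBiasError(f"contingency table has an empty margin: {table.tolist()}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

def score_ranksum(new_scores, ancestral_scores, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p for new vs ancestral scores.

    Exact enumeration when the combined sample size is at most
    ``exact_max_n`` (and there are no ties); otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(new_scores, dtype=float)
    b = np.asarray(ancestral_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise RefBiasError("both groups need at least one score")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= exact_max_n and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Median bootstrap CI
# ---------------------------------------------------------------------------

def median_ci(
    scores, n_boot: int = 10_000, seed: int | None = None, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Median and seeded percentile-bootstrap confidence interval."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise RefBiasError("median CI needs at least two scores")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    medians = np.median(x[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(np.median(x)), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Grouped logistic model
# ---------------------------------------------------------------------------

@dataclass
class GroupedLogisticResult:
    coefficient: float          # log-odds of deleterious, ancestral vs new
    se: float
    z: float
    p_value: float              # likelihood-ratio (profile) p for the origin effect
    random_intercept_sd: float
    per_group_log_odds: dict[str, float]
    flags: tuple[str, ...]


def _gh_loglik(params, y, x, groups, nodes, weights):
    """Marginal log-likelihood of a random-intercept logistic model."""
    b0, b1, log_sigma = params
    sigma = np.exp(log_sigma)
    total = 0.0
    for g in groups:
        yg, xg = g
        eta = b0 + b1 * xg  # (n_g,)
        # Gauss-Hermite: integral over u ~ N(0, sigma^2)
        u = np.sqrt(2.0) * sigma * nodes  # (q,)
        lin = eta[:, None] + u[None, :]
        ll = yg[:, None] * lin - np.logaddexp(0.0, lin)
        group_ll = special.logsumexp(ll.sum(axis=0) + np.log(weights / np.sqrt(np.pi)))
        total += group_ll
    return total


def _fit_gh(y, x, group_ids, n_nodes=25, fix_b1=None):
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    groups = [(y[group_ids == g], x[group_ids == g]) for g in np.unique(group_ids)]

    def negll(p):
        if fix_b1 is None:
            return -_gh_loglik(p, y, x, groups, nodes, weights)
        return -_gh_loglik((p[0], fix_b1, p[1]), y, x, groups, nodes, weights)

    x0 = np.array([0.0, 0.0, np.log(0.5)]) if fix_b1 is None else np.array([0.0, np.log(0.5)])
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    return res


def grouped_deleterious_model(data: pd.DataFrame) -> GroupedLogisticResult:
    """Logistic model of deleterious status on variant origin, by ancestor.

    ``data`` needs columns ``deleterious`` (0/1), ``origin`` ('new' or
    'ancestral') and ``ancestor``.  The primary fit is a maximum-likelihood
    random-intercept (per ancestor) logistic regression via Gauss-Hermite
    quadrature; if the random-intercept variance collapses to zero the model
    is refitted with fixed ancestor effects and flagged.  Complete separation
    in any ancestor x origin cell is flagged and the p-value comes from the
    likelihood-ratio (profile) test, which stays finite under separation.
    """
    required = {"deleterious", "origin", "ancestor"}
    if not required <= set(data.columns):
        raise RefBiasError(f"data lacks columns {sorted(required - set(data.columns))}")
    if data["ancestor"].nunique() < 2:
        raise RefBiasError("grouped model needs at least two ancestral groups")
    y = data["deleterious"].astype(int).to_numpy()
    x = (data["origin"] == "ancestral").astype(float).to_numpy()
    g = data["ancestor"].to_numpy()

    flags: list[str] = []
    per_group: dict[str, float] = {}
    for anc in np.unique(g):
        mask = g == anc
        sub_y, sub_x = y[mask], x[mask]
        cells = np.array([
            [((sub_x == 0) & (sub_y == 1)).sum(), ((sub_x == 0) & (sub_y == 0)).sum()],
            [((sub_x == 1) & (sub_y == 1)).sum(), ((sub_x == 1) & (sub_y == 0)).sum()],
        ], dtype=float)
        for oi in (0, 1):
            n_cell = cells[oi].sum()
            if n_cell > 0 and (cells[oi][0] == 0 or cells[oi][1] == 0):
                if "separation" not in flags:
                    flags.append("separation")
        c = cells + 0.5  # Haldane-Anscombe for a finite per-group log-odds
        per_group[str(anc)] = float(np.log(c[1, 0] * c[0, 1] / (c[1, 1] * c[0, 0])))

    full = _fit_gh(y, x, g)
    b0, b1, log_sigma = full.x
    sigma = float(np.exp(log_sigma))
    ll_full = -full.fun
    null = _fit_gh(y, x, g, fix_b1=0.0)
    ll_null = -null.fun
    lr = max(0.0, 2.0 * (ll_full - ll_null))
    p_lr = float(stats.chi2.sf(lr, df=1))

    # Wald se from a numerical Hessian on (b0, b1); informational only.
    se = _wald_se(y, x, g, full.x)
    if sigma < 1e-4:
        flags.append("singular_random_effect")
        import statsmodels.api as sm
        anc_dummies = pd.get_dummies(pd.Series(g), drop_first=True, dtype=float)
        X = np.column_stack([np.ones_like(x), x, anc_dummies.to_numpy()])
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            b1 = float(fit.params[1])
            se = float(fit.bse[1])
        except Exception:
            logger.warning("fixed-effect fallback fit failed; keeping GH estimates")
    z = b1 / se if se > 0 else np.inf
    return GroupedLogisticResult(
        coefficient=float(b1), se=float(se), z=float(z), p_value=p_lr,
        random_intercept_sd=sigma, per_group_log_odds=per_group,
        flags=tuple(flags))


def _wald_se(y, x, g, params, eps=1e-4):
    nodes, weights = np.polynomial.hermite.hermgauss(25)
    groups = [(y[g == gg], x[g == gg]) for gg in np.unique(g)]

    def ll(b0, b1):
        return _gh_loglik((b0, b1, params[2]), y, x, groups, nodes, weights)

    b0, b1 = params[0], params[1]
    d2 = (ll(b0, b1 + eps) - 2 * ll(b0, b1) + ll(b0, b1 - eps)) / eps**2
    if d2 >= 0:
        return float("inf")
    return float(np.sqrt(-1.0 / d2))
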