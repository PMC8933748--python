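"""Cohort-level statistics for the morphometric metric battery.

Covers the group-comparison workflow of the reference analysis: pooled-variance
t-tests and chi-square tests for demographics, ANCOVA (group effect adjusted
for age, with optional extra covariates for the absolute-difference outcomes),
Cohen's d, a one-between-group MANCOVA (Wilks' lambda with Rao's F, exact for
a single-df hypothesis), stepwise linear regression of head circumference on
the brain metrics, a noncentral-t power/sample-size calculator, and Cronbach's
alpha for measurement reliability.

No multiple-testing correction is applied anywhere: p-values are raw, matching
the analysis this package reproduces; callers can correct downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, HeadmorphError, SingularityError

__all__ = [
    "GroupTestResult",
    "MancovaResult",
    "StepwiseResult",
    "two_sample_t",
    "chi_square_independence",
    "ancova_group",
    "cohens_d",
    "cohens_d_from_groups",
    "mancova",
    "stepwise_regression",
    "two_sample_t_power",
    "required_sample_size",
    "cronbach_alpha",
]

GROUP_LEVELS = ("HC", "ASD")


@dataclass(frozen=True)
class GroupTestResult:
    """A univariate group comparison: t or F, df, p, and group descriptives."""

    statistic: float
    df: tuple[float, ...]
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    cohens_d: float | None = None
    adjusted_means: dict[str, float] | None = None
    adjusted_d: float | None = None
    kind: str = "t"


@dataclass(frozen=True)
class MancovaResult:
    """Multivariate group effect (Wilks' lambda, Rao's F) with per-outcome post hocs."""

    wilks_lambda: float
    statistic: float
    df: tuple[float, float]
    p_value: float
    pillai: float
    posthoc_p: dict[str, float]
    outcomes: tuple[str, ...]


@dataclass(frozen=True)
class StepwiseResult:
    """Forward/backward stepwise path: entered terms with cumulative R^2."""

    entered: list[tuple[str, float]] = field(default_factory=list)
    f_statistic: float = float("nan")
    df: tuple[float, float] = (float("nan"), float("nan"))
    p_value: float = float("nan")
    r_squared: float = 0.0

    @property
    def terms(self) -> list[str]:
        return [name for name, _ in self.entered]


def _group_arrays(values, groups=None):
    if groups is not None:
        values = np.asarray(values, dtype=float)
        groups = np.asarray(groups)
        levels = [g for g in GROUP_LEVELS if g in set(groups)] or sorted(set(groups))
        return {g: values[groups == g] for g in levels}
    return {k: np.asarray(v, dtype=float) for k, v in dict(values).items()}


def two_sample_t(values, groups=None) -> GroupTestResult:
    """Two-sided pooled-variance (Student) t-test between two groups.

    Accepts either a mapping ``{label: array}`` or ``(values, group_labels)``.
    A zero pooled variance with unequal means yields an infinite t and p = 0.
    """
    data = _group_arrays(values, groups)
    if len(data) != 2:
        raise HeadmorphError(f"two_sample_t needs exactly two groups, got {list(data)}")
    (g1, x1), (g2, x2) = data.items()
    n1, n2 = len(x1), len(x2)
    if min(n1, n2) < 2:
        raise HeadmorphError("need at least two observations per group")
    m1, m2 = x1.mean(), x2.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 == 0:
        t = 0.0 if m1 == m2 else float("inf") * np.sign(m2 - m1)
        p = 1.0 if m1 == m2 else 0.0
    else:
        t = (m2 - m1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return GroupTestResult(
        statistic=float(t),
        df=(float(df),),
        p_value=float(p),
        group_means={g1: float(m1), g2: float(m2)},
        group_sds={g1: float(np.sqrt(v1)), g2: float(np.sqrt(v2))},
        group_ns={g1: n1, g2: n2},
        cohens_d=cohens_d(m1, np.sqrt(v1), n1, m2, np.sqrt(v2), n2),
        kind="t",
    )


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Zero-margin rows/columns are dropped with a warning before testing.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise HeadmorphError("contingency table must hold non-negative integer counts")
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table", stacklevel=2)
        table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise HeadmorphError("contingency table needs at least 2 non-empty rows and columns")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def _design(table: pd.DataFrame, columns) -> np.ndarray:
    X = np.column_stack([np.ones(len(table))] + [np.asarray(table[c], dtype=float) for c in columns])
    rank = 1
    for j, col in enumerate(columns, start=1):
        rank_j = np.linalg.matrix_rank(X[:, : j + 1])
        if rank_j == rank:
            raise CollinearityError(f"covariate '{col}' is collinear with earlier model terms")
        rank = rank_j
    return X

def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def ancova_group(
    table: pd.DataFrame,
    outcome: str,
    covariates=("age",),
    extra_covariates=(),
    group_col: str = "group",
) -> GroupTestResult:
    """ANCOVA: group effect on ``outcome`` adjusting for covariates.

    Least-squares fit of ``outcome ~ 1 + group + covariates``; the group F is
    the nested-model comparison F = ((SSE_reduced - SSE_full)/1) / MSE_full on
    (1, n - p) df.  Adjusted group means are model predictions at the grand
    covariate mean, and an age-adjusted Cohen's d is derived from them and the
    root MSE.
    """
    covs = list(covariates) + list(extra_covariates)
    cols = [outcome, group_col] + covs
    data = table[cols].dropna()
    groups = np.asarray(data[group_col])
    levels = [g for g in GROUP_LEVELS if g in set(groups)] or sorted(set(groups))
    if len(levels) != 2:
        raise HeadmorphError(f"group column must have two levels, got {levels}")
    y = np.asarray(data[outcome], dtype=float)
    g = (groups == levels[1]).astype(float)
    n = len(y)
    if n <= len(covs) + 2:
        raise HeadmorphError("not enough complete cases for the model")
    work = data.assign(__group=g)
    X_full = _design(work, ["__group"] + covs)
    X_red = _design(work, covs) if covs else np.ones((n, 1))
    p_full = X_full.shape[1]
    sse_full = _sse(X_full, y)
    sse_red = _sse(X_red, y)
    df2 = n - p_full
    mse = sse_full / df2
    F = max(sse_red - sse_full, 0.0) / mse if mse > 0 else float("inf")
    p = float(stats.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0

    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    cov_means = X_full[:, 2:].mean(axis=0) if covs else np.empty(0)
    adj = {
        levels[0]: float(beta[0] + cov_means @ beta[2:]),
        levels[1]: float(beta[0] + beta[1] + cov_means @ beta[2:]),
    }
    root_mse = float(np.sqrt(mse)) if mse > 0 else float("nan")
    masks = {lvl: groups == lvl for lvl in levels}
    return GroupTestResult(
        statistic=float(F),
        df=(1.0, float(df2)),
        p_value=p,
        group_means={lvl: float(y[m].mean()) for lvl, m in masks.items()},
        group_sds={lvl: float(y[m].std(ddof=1)) for lvl, m in masks.items()},
        group_ns={lvl: int(m.sum()) for lvl, m in masks.items()},
        cohens_d=cohens_d(
            y[masks[levels[0]]].mean(), y[masks[levels[0]]].std(ddof=1), int(masks[levels[0]].sum()),
            y[masks[levels[1]]].mean(), y[masks[levels[1]]].std(ddof=1), int(masks[levels[1]].sum()),
        ),
        adjusted_means=adj,
        adjusted_d=(adj[levels[1]] - adj[levels[0]]) / root_mse if root_mse > 0 else None,
        kind="F",
    )


def cohens_d(m1, sd1, n1, m2, sd2, n2) -> float:
    """Standardized mean difference (m2 - m1) / pooled SD; NaN if the pooled SD is 0."""
    if min(n1, n2) < 2 or sd1 < 0 or sd2 < 0:
        raise HeadmorphError("cohens_d needs n >= 2 and non-negative SDs per group")
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if sp == 0:
        return float("nan")
    return float((m2 - m1) / sp)


def cohens_d_from_groups(x1, x2) -> float:
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    return cohens_d(x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2))


def mancova(
    table: pd.DataFrame,
    outcomes,
    covariates=("age",),
    group_col: str = "group",
    method: str = "wilks",
) -> MancovaResult:
    """MANCOVA group effect on a set of outcomes, adjusting for covariates.

    The group hypothesis has one degree of freedom, so Wilks' lambda with
    Rao's transformation gives an exact F on (p, n - r - p + 1) df, where p is
    the number of outcomes and r the rank of the full design.  Pillai's trace
    is reported alongside (identical inference for a 1-df hypothesis).
    Per-outcome post-hoc ANCOVAs provide univariate p-values.
    """
    outcomes = list(outcomes)
    covs = list(covariates)
    data = table[outcomes + [group_col] + covs].dropna()
    groups = np.asarray(data[group_col])
    levels = [g for g in GROUP_LEVELS if g in set(groups)] or sorted(set(groups))
    if len(levels) != 2:
        raise HeadmorphError(f"group column must have two levels, got {levels}")
    Y = np.asarray(data[outcomes], dtype=float)
    n, p = Y.shape
    if n <= p + len(covs) + 2:
        raise HeadmorphError("not enough complete cases for the multivariate model")
    work = data.assign(__group=(groups == levels[1]).astype(float))
    X_full = _design(work, ["__group"] + covs)
    X_red = _design(work, covs) if covs else np.ones((n, 1))

    def resid_sscp(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        return R.T @ R

    E = resid_sscp(X_full)
    H = resid_sscp(X_red) - E
    sign, logdet_E = np.linalg.slogdet(E)
    if sign <= 0 or np.linalg.cond(E) > 1e12:
        raise SingularityError(
            "within-group residual covariance is singular; reduce or decorrelate the outcome list"
        )
    sign_t, logdet_T = np.linalg.slogdet(E + H)
    wilks = float(np.exp(logdet_E - logdet_T))
    df_e = n - X_full.shape[1]
    df2 = df_e - p + 1
    F = (1.0 - wilks) / wilks * df2 / p
    pval = float(stats.f.sf(F, p, df2))
    pillai = float(np.trace(np.linalg.solve(E + H, H)))
    if method not in ("wilks", "pillai"):
        raise HeadmorphError("method must be 'wilks' or 'pillai'")
    posthoc = {
        out: ancova_group(table, out, covariates=covs, group_col=group_col).p_value
        for out in outcomes
    }
    return MancovaResult(
        wilks_lambda=wilks,
        statistic=float(F),
        df=(float(p), float(df2)),
        p_value=pval,
        pillai=pillai,
        posthoc_p=posthoc,
        outcomes=tuple(outcomes),
    )


def _partial_p(X_base: np.ndarray, x_new: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(p-value, R^2 of augmented model) for adding x_new to the base design."""
    X = np.column_stack([X_base, x_new])
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        return 1.0, float("nan")
    sse_base = _sse(X_base, y)
    sse = _sse(X, y)
    df2 = n - k
    sst = float(((y - y.mean()) ** 2).sum())
    if sse_base <= 1e-12 * max(sst, 1e-300):  # base model already saturated
        return 1.0, 1.0
    if df2 <= 0 or sse <= 1e-12 * sst:
        return 0.0, 1.0
    F = max(sse_base - sse, 0.0) / (sse / df2)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return float(stats.f.sf(F, 1, df2)), r2


def stepwise_regression(
    table: pd.DataFrame,
    outcome: str,
    candidates,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward-entry / backward-removal stepwise linear regression.

    At each forward step the candidate with the smallest partial-F p-value
    enters if p < ``p_enter``; entered terms whose partial p rises above
    ``p_remove`` are removed.  Iterates to stability.  An empty final model is
    a valid result, not an error.
    """
    candidates = list(candidates)
    data = table[[outcome] + candidates].dropna()
    y = np.asarray(data[outcome], dtype=float)
    n = len(y)
    cols = {c: np.asarray(data[c], dtype=float) for c in candidates}
    entered: list[str] = []
    path: list[tuple[str, float]] = []

    def base_design(names):
        return np.column_stack([np.ones(n)] + [cols[c] for c in names])

    changed = True
    while changed:
        changed = False
        # forward
        remaining = [c for c in candidates if c not in entered]
        if remaining:
            Xb = base_design(entered)
            best, best_p, best_r2 = None, 1.0, 0.0
            for c in remaining:
                pval, r2 = _partial_p(Xb, cols[c], y)
                if pval < best_p - 1e-15 or best is None:
                    best, best_p, best_r2 = c, pval, r2
            if best is not None and best_p < p_enter:
                entered.append(best)
                path.append((best, best_r2))
                changed = True
        # backward
        removed = True
        while removed and len(entered) > 0:
            removed = False
            worst, worst_p = None, 0.0
            for c in entered:
                others = [o for o in entered if o != c]
                pval, _ = _partial_p(base_design(others), cols[c], y)
                if pval > worst_p:
                    worst, worst_p = c, pval
            if worst is not None and worst_p > p_remove:
                entered.remove(worst)
                path = [(nm, r2) for nm, r2 in path if nm != worst]
                removed = True
                changed = True
        if not entered:
            break

    if not entered:
        return StepwiseResult()
    # recompute cumulative R^2 along the surviving entry order
    cum = []
    for i in range(1, len(entered) + 1):
        sse = _sse(base_design(entered[:i]), y)
        sst = float(((y - y.mean()) ** 2).sum())
        cum.append((entered[i - 1], 1.0 - sse / sst if sst > 0 else 1.0))
    k = len(entered)
    sse_full = _sse(base_design(entered), y)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse_full / sst if sst > 0 else 1.0
    df = (float(k), float(n - k - 1))
    if sse_full <= 0:
        F, pval = float("inf"), 0.0
    else:
        F = (sst - sse_full) / k / (sse_full / (n - k - 1))
        pval = float(stats.f.sf(F, *df))
    return StepwiseResult(entered=cum, f_statistic=float(F), df=df, p_value=pval, r_squared=r2)


def two_sample_t_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at effect size d, equal n."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    nc = d * np.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Smallest per-group n at which the two-sided t-test reaches target power."""
    if d <= 0 or not (0 < alpha < 1) or not (alpha < power < 1):
        raise HeadmorphError("need d > 0 and 0 < alpha < power < 1")
    hi = 2
    while two_sample_t_power(d, hi, alpha) < power:
        hi *= 2
        if hi > 10_000_000:
            raise HeadmorphError("required sample size exceeds 10 million per group")
    lo = hi // 2
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if two_sample_t_power(d, mid, alpha) >= power:
            hi = mid
        else:
            lo = mid
    return hi


def cronbach_alpha(measurements) -> float:
    """Cronbach's alpha over a subjects x repeated-measurements matrix.

    alpha = k/(k-1) * (1 - sum of column variances / variance of row sums).
    NaN when the total-score variance is zero.
    """
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise HeadmorphError("need at least 2 subjects and 2 measurement columns")
    k = X.shape[1]
    col_var = X.var(axis=0, ddof=1).sum()
    tot_var = X.sum(axis=1).var(ddof=1)
    if tot_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - col_var / tot_var))
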