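"""Group-level statistics for ROI metric tables.

The battery applied to each ROI metric: Z-score quality control with
quantile-quantile export, ANCOVA with type-III sums of squares, partial
eta-squared and Bonferroni-adjusted pairwise contrasts of covariate-adjusted
means, Benjamini-Hochberg FDR over a metric family, partial correlation
against cognition scores, and stepwise linear regression preceded by
Mahalanobis outlier filtering.

Named covariate tiers: ``age_edu`` (age + education) and
``age_edu_fazekas`` (adds the Fazekas ratings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "COVARIATE_SETS", "AncovaResult", "FdrResult",
    "zscore_qc", "ancova", "bh_fdr", "partial_correlation",
    "mahalanobis_filter", "stepwise_regression",
]

COVARIATE_SETS = {
    "age_edu": ["age", "education"],
    "age_edu_fazekas": ["age", "education", "fazekas_pv", "fazekas_deep",
                        "fazekas_total"],
}


def zscore_qc(values: np.ndarray, threshold: float = 2.0):
    """Flag univariate outliers with |Z| > threshold against the sample
    mean/SD and export quantile-quantile points for visual inspection.

    Returns ``(kept_indices, outlier_indices, qq_points)`` where qq_points is
    an (n, 2) array of (theoretical normal quantile, sorted sample value).
    A zero-variance input yields no outliers (with a warning).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance: no outliers flagged")
        z = np.zeros(n)
    else:
        z = (values - values.mean()) / sd
    out = np.flatnonzero(np.abs(z) > threshold)
    kept = np.flatnonzero(np.abs(z) <= threshold)
    order = np.argsort(values)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = np.column_stack([theo, values[order]])
    return kept, out, qq


@dataclass
class AncovaResult:
    """Group effect from a covariate-adjusted linear model."""

    F: float
    p: float
    partial_eta_sq: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, diff, p_adj, ci_low, ci_high
    n: int
    df_group: int
    df_resid: int


def ancova(table: pd.DataFrame, outcome: str, covariates: list[str],
           group_col: str = "group") -> AncovaResult:
    """ANCOVA of ``outcome ~ group + covariates``.

    The group F-test uses type-III sums of squares (sum-to-zero contrasts);
    partial eta-squared is SS_group / (SS_group + SS_error).  Pairwise
    contrasts compare covariate-adjusted group means with Bonferroni-adjusted
    p-values (capped at 1) and Bonferroni-adjusted 95% confidence intervals.
    """
    data = table[[outcome, group_col] + covariates].dropna().copy()
    groups = sorted(data[group_col].unique())
    if any((data[group_col] == g).sum() < 2 for g in groups):
        raise ValueError("each group needs at least 2 subjects")
    if data[outcome].nunique() == 1:
        # constant outcome: no group variance to explain
        m = len(groups) * (len(groups) - 1) // 2
        pairs = [{"group_a": a, "group_b": b, "diff": 0.0, "p_adj": 1.0,
                  "ci_low": 0.0, "ci_high": 0.0}
                 for i, a in enumerate(groups) for b in groups[i + 1:]]
        return AncovaResult(F=0.0, p=1.0, partial_eta_sq=0.0,
                            pairwise=pd.DataFrame(pairs), n=len(data),
                            df_group=len(groups) - 1,
                            df_resid=len(data) - len(groups) - len(covariates))
    cov_terms = " + ".join([f"Q('{c}')" for c in covariates])
    formula = f"Q('{outcome}') ~ C(Q('{group_col}'), Sum)"
    if covariates:
        formula += " + " + cov_terms
    model = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("singular design: collinear covariates "
                         f"{covariates}")
    aov = sm.stats.anova_lm(model, typ=3)
    grp_row = [ix for ix in aov.index if group_col in ix][0]
    ss_group = float(aov.loc[grp_row, "sum_sq"])
    ss_error = float(aov.loc["Residual", "sum_sq"])
    F = float(aov.loc[grp_row, "F"])
    p = float(aov.loc[grp_row, "PR(>F)"])
    eta = ss_group / (ss_group + ss_error) if ss_group + ss_error > 0 else 0.0

    # adjusted means via treatment-coded refit: differences of group effects
    model_t = smf.ols(
        f"Q('{outcome}') ~ C(Q('{group_col}'))" + (" + " + cov_terms if covariates else ""),
        data=data).fit()
    names = model_t.model.exog_names
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            c = np.zeros(len(names))
            for j, name in enumerate(names):
                if f"[T.{ga}]" in name:
                    c[j] += 1.0
                if f"[T.{gb}]" in name:
                    c[j] -= 1.0
            diff = float(c @ model_t.params)
            se = float(np.sqrt(c @ model_t.cov_params() @ c))
            df = model_t.df_resid
            t = diff / se
            p_pair = min(1.0, 2 * stats.t.sf(abs(t), df) * m)
            tcrit = stats.t.ppf(1 - 0.05 / (2 * m), df)
            rows.append({"group_a": ga, "group_b": gb, "diff": diff,
                         "p_adj": p_pair, "ci_low": diff - tcrit * se,
                         "ci_high": diff + tcrit * se})
    return AncovaResult(F=F, p=p, partial_eta_sq=eta,
                        pairwise=pd.DataFrame(rows), n=len(data),
                        df_group=len(groups) - 1, df_resid=int(model.df_resid))


@dataclass
class FdrResult:
    """Benjamini-Hochberg step-up decision over one family of tests."""

    m: int
    q: float
    critical_value: float
    significant: np.ndarray
    any_significant: bool


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up rule at level ``q``.

    The critical value is the largest p(k) with p(k) <= (k/m) q; every
    p-value at or below it is significant.  With no passing p-value the
    critical value is reported as 0 with ``any_significant=False``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    thresh = np.arange(1, m + 1) / m * q
    passing = order <= thresh
    if passing.any():
        crit = float(order[np.flatnonzero(passing).max()])
        return FdrResult(m=m, q=q, critical_value=crit,
                         significant=p <= crit, any_significant=True)
    return FdrResult(m=m, q=q, critical_value=0.0,
                     significant=np.zeros(m, dtype=bool), any_significant=False)


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None):
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualised on the covariates (with intercept) by
    OLS; r is the Pearson correlation of the residuals and p comes from the
    t distribution with n - k - 2 degrees of freedom (k covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        Z = np.column_stack([np.ones(n), covariates])
        k = Z.shape[1] - 1
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residuals: correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_ = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_ * np.sqrt(df / (1 - r_ ** 2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def mahalanobis_filter(design: np.ndarray, threshold: float = 2.0):
    """Remove rows whose squared Mahalanobis distance from the predictor
    centroid, divided by the number of predictors, exceeds ``threshold``.

    The distance is non-negative, so the mirrored lower branch of the rule
    can never fire and is omitted.  A singular sample covariance is
    ridge-regularised (1e-8 of the mean variance) with a warning.

    Returns ``(kept_indices, removed_indices)``.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than predictors")
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False).reshape(p, p)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; applying ridge regularisation")
        S = S + 1e-8 * np.trace(S) / p * np.eye(p)
        Sinv = np.linalg.inv(S)
    diff = X - mu
    d2 = np.einsum("ij,jk,ik->i", diff, Sinv, diff)
    removed = np.flatnonzero(d2 / p > threshold)
    kept = np.flatnonzero(d2 / p <= threshold)
    return kept, removed


def stepwise_regression(table: pd.DataFrame, outcome: str,
                        candidates: list[str], covariates: list[str] | None = None,
                        p_enter: float = 0.05, p_remove: float = 0.10) -> pd.DataFrame:
    """Forward-entry / backward-removal stepwise linear regression.

    Covariates (if any) stay in the model throughout.  At each step the
    candidate with the smallest partial-F p-value enters if p <= ``p_enter``;
    entered candidates whose p-value rises to >= ``p_remove`` are dropped.
    Returns one row per retained candidate with the standardised coefficient
    (beta), t and p from the final model; empty frame if nothing enters.
    """
    covariates = covariates or []
    data = table[[outcome] + candidates + covariates].dropna()
    y = data[outcome].to_numpy(dtype=float)
    selected: list[str] = []

    def fit(cols: list[str]):
        X = sm.add_constant(data[covariates + cols].to_numpy(dtype=float)) \
            if covariates + cols else np.ones((len(y), 1))
        return sm.OLS(y, X).fit()

    while True:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        best_p, best_c = None, None
        for c in remaining:
            res = fit(selected + [c])
            p_c = res.pvalues[-1]
            if best_p is None or p_c < best_p:
                best_p, best_c = p_c, c
        if best_c is not None and best_p <= p_enter:
            selected.append(best_c)
            changed = True
        if selected:
            res = fit(selected)
            ps = res.pvalues[1 + len(covariates):]
            worst = int(np.argmax(ps))
            if ps[worst] >= p_remove:
                selected.pop(worst)
                changed = True
        if not changed:
            break

    if not selected:
        return pd.DataFrame(columns=["predictor", "beta", "t", "p"])
    res = fit(selected)
    sy = y.std(ddof=1)
    rows = []
    for i, c in enumerate(selected):
        j = 1 + len(covariates) + i
        b = res.params[j]
        sx = data[c].to_numpy(dtype=float).std(ddof=1)
        rows.append({"predictor": c, "beta": b * sx / sy,
                     "t": float(res.tvalues[j]), "p": float(res.pvalues[j])})
    return pd.DataFrame(rows)
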