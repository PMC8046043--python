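"""Canonical discriminant analysis with bootstrap validation.

The canonical functions solve the generalized eigenproblem of the
between-group scatter B against the pooled within-group scatter S_w.  For
eigenvalues lambda_i (decreasing):

    canonical correlation_i = sqrt(lambda_i / (1 + lambda_i))
    Wilks' Lambda(k..K)     = prod_{i >= k} 1 / (1 + lambda_i)

Coefficients are scaled so canonical scores have pooled within-group
variance 1; classification assigns each subject to the nearest group
centroid in canonical space (equal priors, common covariance).  Accuracy is
resubstitution (fit and classify the same sample) to match the reporting
convention of classical statistics packages; a cross-validated variant is
available and labelled distinctly.  Validation uses stratified resampling
within groups with a bias-corrected and accelerated (BCa) percentile
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .cohort import SUBREGIONS, HEMISPHERES, metric_column
from .group_stats import zscore_qc

__all__ = [
    "CdaModel", "ClassificationReport", "BootstrapSummary",
    "fit_cda", "classify", "combination_sweep", "bootstrap_validate",
    "feature_columns", "bca_interval",
]


@dataclass
class CdaModel:
    """Fitted canonical discriminant functions."""

    groups: list
    feature_names: list[str] | None
    coefficients: np.ndarray          # (p, K) raw canonical weights
    grand_mean: np.ndarray            # (p,)
    eigenvalues: np.ndarray           # (K,) decreasing
    canonical_correlations: np.ndarray
    wilks_lambda: np.ndarray          # (K,), entry k-1 spans functions k..K
    chi2: np.ndarray
    chi2_p: np.ndarray
    centroids: np.ndarray             # (g, K)
    priors: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.grand_mean):
            raise ValueError("feature count mismatch with the fitted model")
        return (X - self.grand_mean) @ self.coefficients


@dataclass
class ClassificationReport:
    confusion_matrix: pd.DataFrame
    accuracy: float                   # percent correct
    per_group_accuracy: dict


@dataclass
class BootstrapSummary:
    n_resamples: int
    mean_accuracy: float
    ci_low: float
    ci_high: float
    point_accuracy: float
    accuracies: np.ndarray
    n_redrawn: int
    outlier_removal_applied: bool


def fit_cda(features: np.ndarray, groups, priors: str = "equal",
            ridge: float = 0.0, feature_names: list[str] | None = None) -> CdaModel:
    """Fit canonical discriminant functions.

    ``priors`` is "equal" or "proportional" (stored on the model; centroid
    classification under a common covariance uses them only through the
    decision rule, which is prior-free when equal).  Set ``ridge`` > 0 to
    regularise a singular within-group scatter by ridge * trace / p.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n, p = X.shape
    counts = np.array([(groups == lab).sum() for lab in labels])
    if n - g < p and ridge == 0.0:
        warnings.warn("fewer within-group degrees of freedom than features; "
                      "within-group scatter may be singular")
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab, cnt in zip(labels, counts):
        Xi = X[groups == lab]
        mi = Xi.mean(axis=0)
        Sw += (Xi - mi).T @ (Xi - mi)
        B += cnt * np.outer(mi - grand, mi - grand)
    if ridge > 0.0:
        Sw = Sw + ridge * np.trace(Sw) / p * np.eye(p)
    try:
        evals, evecs = linalg.eigh(B, Sw)
    except linalg.LinAlgError:
        warnings.warn("singular within-group scatter; applying ridge 1e-8")
        Sw = Sw + 1e-8 * np.trace(Sw) / p * np.eye(p)
        evals, evecs = linalg.eigh(B, Sw)
    order = np.argsort(evals)[::-1]
    K = min(g - 1, p)
    lam = np.clip(evals[order[:K]], 0.0, None)
    V = evecs[:, order[:K]]
    # eigh normalises v' Sw v = 1; rescale for pooled within-group variance 1
    A = V * np.sqrt(n - g)

    cancorr = np.sqrt(lam / (1.0 + lam))
    wilks = np.array([np.prod(1.0 / (1.0 + lam[k:])) for k in range(K)])
    # Bartlett's chi-square approximation for functions k..K
    chi2 = -(n - 1 - (p + g) / 2.0) * np.log(wilks)
    dfs = np.array([(p - k) * (g - k - 1) for k in range(K)])
    chi2_p = stats.chi2.sf(chi2, np.maximum(dfs, 1))

    scores = (X - grand) @ A
    centroids = np.vstack([scores[groups == lab].mean(axis=0) for lab in labels])
    pri = (np.full(g, 1.0 / g) if priors == "equal"
           else counts / counts.sum())
    return CdaModel(groups=labels, feature_names=feature_names,
                    coefficients=A, grand_mean=grand, eigenvalues=lam,
                    canonical_correlations=cancorr, wilks_lambda=wilks,
                    chi2=chi2, chi2_p=chi2_p, centroids=centroids, priors=pri)


def classify(model: CdaModel, features: np.ndarray, true_groups=None):
    """Assign subjects to the nearest group centroid in canonical space.

    Returns predictions, plus a :class:`ClassificationReport` when
    ``true_groups`` is given.
    """
    scores = model.transform(features)
    d2 = ((scores[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    pred = np.array(model.groups, dtype=object)[np.argmin(d2, axis=1)]
    if true_groups is None:
        return pred
    true = np.asarray(true_groups)
    labs = model.groups
    cm = pd.DataFrame(0, index=labs, columns=labs)
    for t, q in zip(true, pred):
        cm.loc[t, q] += 1
    acc = 100.0 * np.trace(cm.to_numpy()) / len(true)
    per_group = {lab: 100.0 * cm.loc[lab, lab] / max(cm.loc[lab].sum(), 1)
                 for lab in labs}
    return pred, ClassificationReport(confusion_matrix=cm, accuracy=float(acc),
                                      per_group_accuracy=per_group)


def feature_columns(metrics: list[str], roi_mode: str) -> list[str]:
    """Cohort-table columns for a metric combination.

    ``roi_mode="whole"`` uses the two bilateral-hemisphere averages per
    metric; ``"segregated"`` all 14 subregion columns per metric.
    """
    cols = []
    for m in metrics:
        if roi_mode == "whole":
            cols += [f"{m}_thal_{h}" for h in HEMISPHERES]
        elif roi_mode == "segregated":
            cols += [metric_column(m, s, h) for h in HEMISPHERES for s in SUBREGIONS]
        else:
            raise ValueError(f"unknown roi_mode {roi_mode!r}")
    return cols


def _resubstitution_accuracy(X: np.ndarray, y: np.ndarray,
                             ridge: float = 0.0) -> float:
    model = fit_cda(X, y, ridge=ridge)
    _, rep = classify(model, X, y)
    return rep.accuracy


def combination_sweep(table: pd.DataFrame, feature_sets: dict[str, list[str]],
                      roi_mode: str = "segregated", group_col: str = "group",
                      ridge: float = 0.0) -> pd.DataFrame:
    """Resubstitution accuracy of each named metric combination.

    ``feature_sets`` maps a display name to a list of metric names, e.g.
    ``{"MK + K_radial + K_axial": ["mk", "k_radial", "k_axial"]}``.
    """
    rows = []
    y = table[group_col].to_numpy()
    for name, metrics in feature_sets.items():
        cols = feature_columns(metrics, roi_mode)
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise KeyError(f"combination {name!r}: missing columns {missing}")
        X = table[cols].to_numpy(dtype=float)
        acc = _resubstitution_accuracy(X, y, ridge=ridge)
        rows.append({"combination": name, "roi_mode": roi_mode,
                     "n_features": len(cols), "accuracy": acc})
    return pd.DataFrame(rows)


def bca_interval(point: float, boot: np.ndarray, jack: np.ndarray,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval.

    ``point`` is the statistic on the original sample, ``boot`` the bootstrap
    replicates and ``jack`` the leave-one-out (jackknife) replicates used for
    the acceleration constant.  Degenerate distributions collapse to a
    zero-width interval.
    """
    boot = np.asarray(boot, dtype=float)
    if np.allclose(boot, boot[0]):
        return float(boot[0]), float(boot[0])
    prop = np.mean(boot < point) + 0.5 * np.mean(boot == point)
    prop = np.clip(prop, 1e-9, 1 - 1e-9)
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


def bootstrap_validate(table: pd.DataFrame, feature_cols: list[str],
                       n_resamples: int = 1000, seed: int = 0,
                       group_col: str = "group", outlier_mode: str | None = "scores",
                       ridge: float = 0.0) -> BootstrapSummary:
    """Validate discriminant accuracy by stratified bootstrap with a BCa
    interval.

    Outliers are removed first by the |Z| > 2 rule (``outlier_mode``):
    ``"scores"`` (default) applies it to the canonical discriminant scores of
    an initial fit, which keeps removal independent of the feature count;
    ``"per_feature"`` applies it to every feature column and removes the
    union (aggressive for wide feature sets); ``None`` disables removal.
    Each resample draws subjects with replacement within groups, refits and
    scores resubstitution accuracy; resamples leaving fewer than 2 distinct
    subjects in a group are redrawn (counted).  The reported validated
    accuracy is the mean of the resample accuracies.
    """
    data = table[[group_col] + feature_cols].dropna().reset_index(drop=True)
    if outlier_mode is not None:
        bad: set[int] = set()
        if outlier_mode == "scores":
            model0 = fit_cda(data[feature_cols].to_numpy(dtype=float),
                             data[group_col].to_numpy(), ridge=ridge)
            scores0 = model0.transform(data[feature_cols].to_numpy(dtype=float))
            for k in range(scores0.shape[1]):
                _, out, _ = zscore_qc(scores0[:, k])
                bad |= set(out.tolist())
        elif outlier_mode == "per_feature":
            for c in feature_cols:
                _, out, _ = zscore_qc(data[c].to_numpy(dtype=float))
                bad |= set(out.tolist())
        else:
            raise ValueError(f"unknown outlier_mode {outlier_mode!r}")
        data = data.drop(index=sorted(bad)).reset_index(drop=True)
    X = data[feature_cols].to_numpy(dtype=float)
    y = data[group_col].to_numpy()
    labels = sorted(pd.unique(y).tolist())
    idx_by_group = {lab: np.flatnonzero(y == lab) for lab in labels}
    if any(len(idx) < 2 for idx in idx_by_group.values()):
        raise ValueError("a group has fewer than 2 subjects after outlier removal")

    point = _resubstitution_accuracy(X, y, ridge=ridge)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_resamples)
    n_redrawn = 0
    for b in range(n_resamples):
        for _attempt in range(1000):
            take = np.concatenate([
                rng.choice(idx, size=len(idx), replace=True)
                for idx in idx_by_group.values()
            ])
            if all(len(np.unique(take[ (y[take] == lab) ])) >= 2 for lab in labels):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate resample")
        accs[b] = _resubstitution_accuracy(X[take], y[take], ridge=ridge)
    if n_redrawn:
        warnings.warn(f"{n_redrawn} degenerate resamples redrawn")

    jack = np.empty(len(y))
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        jack[i] = _resubstitution_accuracy(X[keep], y[keep], ridge=ridge)
    lo, hi = bca_interval(point, accs, jack)
    return BootstrapSummary(n_resamples=n_resamples,
                            mean_accuracy=float(accs.mean()),
                            ci_low=float(np.clip(lo, 0, 100)),
                            ci_high=float(np.clip(hi, 0, 100)),
                            point_accuracy=float(point),
                            accuracies=accs, n_redrawn=n_redrawn,
                            outlier_removal_applied=outlier_mode is not None)
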