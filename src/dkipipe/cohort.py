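"""Synthetic three-group cohort tables.

Generates per-subject rows for the SIVD / AD / NC design: group label,
demographic covariates (age, education, Fazekas ratings), cognition scores
(CDR sum-of-boxes, MMSE, CASI) and ROI diffusion-metric columns.  Metric
distributions follow user-specified per-group means and SDs; the packaged
defaults carry the published whole-thalamus group statistics, with
subregion-level means derived from the hemisphere means via fixed
multiplicative offsets.  Selected metric-cognition pairs are linked through
a Gaussian copula at specified target correlations.

Column naming: ``{metric}_{subregion}_{hemisphere}`` for segregated ROIs
(e.g. ``mk_ANT_R``) and ``{metric}_thal_{hemisphere}`` for the
whole-hemisphere averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS", "SUBREGIONS", "HEMISPHERES", "METRICS",
    "CohortSpec", "metric_column", "default_cohort_spec", "simulate_cohort",
]

GROUPS = ("SIVD", "AD", "NC")
SUBREGIONS = ("PUL", "ANT", "MedioD", "VLD", "C", "VA", "VLV")
HEMISPHERES = ("L", "R")
METRICS = ("md", "d_axial", "d_radial", "fa", "mk", "k_axial", "k_radial")

#: published whole-thalamus group means and SDs, {(metric, hemi): {group: (mean, sd)}}
#: diffusivities in 10^-3 mm^2/s
WHOLE_THALAMUS_STATS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("d_axial", "L"): {"SIVD": (1.46, 0.20), "AD": (1.41, 0.17), "NC": (1.28, 0.16)},
    ("d_radial", "L"): {"SIVD": (0.95, 0.20), "AD": (0.88, 0.19), "NC": (0.79, 0.13)},
    ("md", "L"): {"SIVD": (1.11, 0.19), "AD": (1.05, 0.17), "NC": (0.95, 0.14)},
    ("fa", "L"): {"SIVD": (0.31, 0.05), "AD": (0.33, 0.05), "NC": (0.32, 0.02)},
    ("k_axial", "L"): {"SIVD": (0.44, 0.03), "AD": (0.44, 0.03), "NC": (0.44, 0.03)},
    ("k_radial", "L"): {"SIVD": (1.05, 0.11), "AD": (1.13, 0.12), "NC": (1.12, 0.08)},
    ("mk", "L"): {"SIVD": (0.86, 0.09), "AD": (0.96, 0.10), "NC": (0.95, 0.06)},
    ("d_axial", "R"): {"SIVD": (1.49, 0.18), "AD": (1.40, 0.15), "NC": (1.29, 0.19)},
    ("d_radial", "R"): {"SIVD": (1.01, 0.19), "AD": (0.90, 0.17), "NC": (0.84, 0.17)},
    ("md", "R"): {"SIVD": (1.16, 0.17), "AD": (1.06, 0.15), "NC": (0.99, 0.17)},
    ("fa", "R"): {"SIVD": (0.29, 0.05), "AD": (0.31, 0.05), "NC": (0.30, 0.02)},
    ("k_axial", "R"): {"SIVD": (0.44, 0.04), "AD": (0.44, 0.04), "NC": (0.45, 0.03)},
    ("k_radial", "R"): {"SIVD": (0.95, 0.10), "AD": (1.05, 0.11), "NC": (1.00, 0.10)},
    ("mk", "R"): {"SIVD": (0.81, 0.06), "AD": (0.88, 0.08), "NC": (0.87, 0.06)},
}

#: demographic / cognition columns, {column: {group: (mean, sd)}}
COVARIATE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"SIVD": (74.0, 8.52), "AD": (78.3, 6.43), "NC": (65.9, 7.31)},
    "education": {"SIVD": (7.5, 2.71), "AD": (7.9, 3.53), "NC": (10.0, 3.36)},
    "fazekas_pv": {"SIVD": (2.0, 0.56), "AD": (1.0, 0.58), "NC": (0.5, 0.58)},
    "fazekas_deep": {"SIVD": (2.0, 0.51), "AD": (0.7, 0.59), "NC": (0.5, 0.50)},
    "fazekas_total": {"SIVD": (4.1, 0.92), "AD": (1.7, 0.95), "NC": (1.1, 0.85)},
    "cdr_sob": {"SIVD": (6.3, 4.57), "AD": (4.6, 2.64), "NC": (0.6, 0.51)},
    "casi": {"SIVD": (59.3, 19.73), "AD": (62.8, 17.36), "NC": (87.5, 4.91)},
    "mmse": {"SIVD": (18.2, 6.63), "AD": (20.9, 4.37), "NC": (27.7, 1.61)},
}

#: multiplicative offsets deriving subregion means from the hemisphere mean;
#: small, fixed, identical across groups so subregions inherit the hemisphere
#: level group contrasts
SUBREGION_OFFSETS = {
    "PUL": -0.04, "ANT": 0.05, "MedioD": 0.02, "VLD": 0.00,
    "C": -0.02, "VA": 0.03, "VLV": -0.05,
}

#: default metric-cognition links: (metric column, cognition column, target r)
#: from the published pooled partial-correlation grid
DEFAULT_COGNITION_LINKS: tuple[tuple[str, str, float], ...] = (
    ("k_axial_PUL_R", "cdr_sob", -0.299),
    ("k_radial_ANT_R", "cdr_sob", -0.340),
    ("mk_ANT_R", "cdr_sob", -0.360),
    ("mk_VLV_L", "cdr_sob", -0.314),
    ("k_radial_PUL_L", "mmse", 0.243),
    ("mk_PUL_L", "mmse", 0.267),
)

COGNITION_COLUMNS = ("cdr_sob", "mmse", "casi")

#: physical plausibility bounds applied after sampling
_CLIP = {"fa": (0.0, 1.0), "mk": (0.0, 3.0), "k_axial": (0.0, 3.0),
         "k_radial": (0.0, 3.0)}


def metric_column(metric: str, subregion: str, hemisphere: str) -> str:
    """Canonical column name for an ROI metric, e.g. ``mk_ANT_R``."""
    return f"{metric}_{subregion}_{hemisphere}"


@dataclass
class CohortSpec:
    """Full parameterisation of a synthetic cohort.

    ``metric_stats`` maps column name -> {group: (mean, sd)};
    ``covariate_stats`` likewise for demographic/cognition columns;
    ``cognition_links`` lists (metric column, cognition column, target r).
    """

    group_sizes: dict[str, int]
    metric_stats: dict[str, dict[str, tuple[float, float]]]
    covariate_stats: dict[str, dict[str, tuple[float, float]]]
    cognition_links: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g} must have at least 2 subjects")
        for col, per_group in {**self.metric_stats, **self.covariate_stats}.items():
            for g, (_, sd) in per_group.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {col} in group {g}")
        for mcol, ccol, r in self.cognition_links:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation for ({mcol}, {ccol}) outside [-1, 1]")


def default_cohort_spec(seed: int = 0,
                        group_sizes: dict[str, int] | None = None,
                        cognition_links=DEFAULT_COGNITION_LINKS) -> CohortSpec:
    """The packaged study conditions: group sizes 23/30/24, whole-thalamus
    metric statistics from the published group table, subregion statistics
    derived via :data:`SUBREGION_OFFSETS`, demographic and cognition
    distributions from the published demographics table."""
    if group_sizes is None:
        group_sizes = {"SIVD": 23, "AD": 30, "NC": 24}
    metric_stats: dict[str, dict[str, tuple[float, float]]] = {}
    for (metric, hemi), per_group in WHOLE_THALAMUS_STATS.items():
        metric_stats[f"{metric}_thal_{hemi}"] = dict(per_group)
        for sub in SUBREGIONS:
            off = SUBREGION_OFFSETS[sub]
            metric_stats[metric_column(metric, sub, hemi)] = {
                g: (m * (1.0 + off), s) for g, (m, s) in per_group.items()
            }
    return CohortSpec(
        group_sizes=dict(group_sizes),
        metric_stats=metric_stats,
        covariate_stats={k: dict(v) for k, v in COVARIATE_STATS.items()},
        cognition_links=tuple(cognition_links),
        seed=seed,
    )


def _copula_matrix(spec: CohortSpec, linked_metrics: list[str]):
    """Correlation matrix over [linked metrics..., cognition columns...];
    metric-metric and cognition-cognition entries are zero, metric-cognition
    entries carry the target correlations."""
    cols = linked_metrics + list(COGNITION_COLUMNS)
    k = len(cols)
    R = np.eye(k)
    for mcol, ccol, r in spec.cognition_links:
        i, j = cols.index(mcol), cols.index(ccol)
        R[i, j] = R[j, i] = r
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() <= 1e-10:
        # find an offending pair by greedy removal
        for mcol, ccol, r in spec.cognition_links:
            R2 = R.copy()
            i, j = cols.index(mcol), cols.index(ccol)
            R2[i, j] = R2[j, i] = 0.0
            if np.linalg.eigvalsh(R2).min() > 1e-10:
                raise ValueError(
                    "infeasible correlation structure: removing the link "
                    f"({mcol}, {ccol}, r={r}) restores positive definiteness"
                )
        worst = max(spec.cognition_links, key=lambda link: abs(link[2]))
        raise ValueError(
            "infeasible correlation structure (not positive definite); "
            f"strongest implicated link: ({worst[0]}, {worst[1]}, r={worst[2]})"
        )
    return cols, R


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from ``spec``.

    Within each group, linked metric and cognition columns are sampled
    jointly from a Gaussian copula at the target correlations; all other
    columns are independent normals with the group's mean and SD.  FA is
    clipped to [0, 1] and kurtosis metrics to [0, 3] after sampling.
    """
    rng = np.random.default_rng(spec.seed)
    linked_metrics = sorted({m for m, _, _ in spec.cognition_links})
    copula_cols, R = _copula_matrix(spec, linked_metrics)
    chol = np.linalg.cholesky(R)

    frames = []
    offset = 0
    for group in GROUPS:
        if group not in spec.group_sizes:
            continue
        n = spec.group_sizes[group]
        row: dict[str, np.ndarray] = {
            "subject": np.array([f"sub-{offset + i + 1:03d}" for i in range(n)]),
            "group": np.repeat(group, n),
        }
        z_joint = (rng.standard_normal((n, len(copula_cols))) @ chol.T)
        z_by_col = dict(zip(copula_cols, z_joint.T))
        for col, per_group in {**spec.covariate_stats, **spec.metric_stats}.items():
            if group not in per_group:
                raise ValueError(f"no statistics for column {col} in group {group}")
            mean, sd = per_group[group]
            z = z_by_col.get(col, None)
            if z is None:
                z = rng.standard_normal(n)
            vals = mean + sd * z
            for metric, bounds in _CLIP.items():
                if col.startswith(metric + "_"):
                    vals = np.clip(vals, *bounds)
            row[col] = vals
        frames.append(pd.DataFrame(row))
        offset += n
    table = pd.concat(frames, ignore_index=True)
    return table
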