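"""Diffusion kurtosis model fitting and scalar metric derivation.

The model for a voxel is

    ln S(b, n) = ln S0 - b * n^T D n + (b^2 / 6) * V_app(n),
    V_app(n)   = sum_ijkl n_i n_j n_k n_l V_ijkl,   V = MD^2 * W,

linear in the 22 parameters (ln S0, 6 unique D components, 15 unique V
components).  Fitting proceeds in three stages: ordinary least squares on
log-signals, weighted least squares with weights equal to the squared
predicted signals (the standard heteroscedasticity correction after the log
transform), and a Levenberg-Marquardt refinement minimising squared error in
the signal domain.  The kurtosis tensor is recovered as W = V / MD^2.

Scalar metrics: mean/axial/radial diffusivity and FA from the eigensystem of
D; mean kurtosis as the arithmetic mean of the apparent kurtosis over the
acquisition's gradient directions; axial kurtosis along the principal
eigenvector; radial kurtosis as the mean over directions uniformly spaced in
the perpendicular plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .acquisition import AcquisitionScheme
from . import tensors

__all__ = [
    "VoxelFit",
    "MetricSet",
    "build_design",
    "fit_voxel",
    "fit_volume",
    "apparent_diffusivity",
    "apparent_kurtosis",
    "dti_metrics",
    "dki_metrics",
]

#: plausibility bounds applied to directional apparent kurtosis in metrics
K_APP_BOUNDS = (0.0, 3.0)


@dataclass
class VoxelFit:
    """Fitted (S0, D, W) for one voxel plus optimiser diagnostics."""

    S0_hat: float
    D_hat: np.ndarray
    W_hat: np.ndarray
    residual_norm: float
    converged: bool
    n_iterations: int


@dataclass(frozen=True)
class MetricSet:
    """The seven scalar metrics.  Diffusivities are in mm^2/s (multiply by
    1e3 for the conventional 10^-3 mm^2/s printing); kurtoses and FA are
    dimensionless."""

    md: float
    d_axial: float
    d_radial: float
    fa: float
    mk: float
    k_axial: float
    k_radial: float

    def as_dict(self) -> dict[str, float]:
        return {
            "md": self.md, "d_axial": self.d_axial, "d_radial": self.d_radial,
            "fa": self.fa, "mk": self.mk, "k_axial": self.k_axial,
            "k_radial": self.k_radial,
        }


def build_design(scheme: AcquisitionScheme) -> np.ndarray:
    """Design matrix mapping (ln S0, d6, v15) to log-signals, one row per
    scheme volume.  Raises if the scheme cannot determine all 22 parameters.
    """
    bvals = scheme.bvals[:, None]
    bvecs = scheme.bvecs
    ones = np.ones((scheme.total_volumes, 1))
    d_cols = -bvals * tensors.direction_monomials_d(bvecs)
    w_cols = (bvals ** 2 / 6.0) * tensors.direction_monomials_w(bvecs)
    X = np.hstack([ones, d_cols, w_cols])
    rank = np.linalg.matrix_rank(X)
    if rank < 22:
        raise ValueError(
            f"scheme cannot determine the kurtosis model: design rank {rank} < 22 "
            "(need >= 2 shells, or >= 21 independent (b, n) combinations)"
        )
    return X


def _extract(theta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(ln S0, d6, v15) -> (S0, D projected to PSD, W = V / MD^2)."""
    s0 = float(np.exp(theta[0]))
    D = tensors.d6_to_dmat(theta[1:7])
    eigvals, eigvecs = np.linalg.eigh(D)
    eigvals = np.clip(eigvals, 0.0, None)
    D = eigvecs @ np.diag(eigvals) @ eigvecs.T
    md = eigvals.mean()
    W = theta[7:] / md ** 2 if md > 0 else np.zeros(15)
    return s0, D, W


def fit_voxel(signals: np.ndarray, scheme: AcquisitionScheme,
              method: str = "wls_init_then_lm", design: np.ndarray | None = None,
              max_iter: int = 500, xtol: float = 1e-8) -> VoxelFit:
    """Fit the kurtosis model to one voxel's signals.

    ``method`` is ``"wls_init_then_lm"`` (default) or ``"wls"`` to stop after
    the weighted linear pass.  Pass ``design`` to reuse a precomputed design
    matrix across voxels.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (scheme.total_volumes,):
        raise ValueError("signal vector length must match the scheme")
    if np.any(signals <= 0):
        raise ValueError("all signals must be positive")
    if method not in ("wls_init_then_lm", "wls"):
        raise ValueError(f"unknown method {method!r}")

    X = build_design(scheme) if design is None else design
    logs = np.log(signals)
    theta = np.linalg.lstsq(X, logs, rcond=None)[0]
    # WLS with weights = squared predicted signals from the OLS pass
    w = np.exp(X @ theta) ** 2
    Xw = X * w[:, None]
    theta = np.linalg.solve(X.T @ Xw, Xw.T @ logs)

    if method == "wls":
        resid = np.exp(X @ theta) - signals
        s0, D, W = _extract(theta)
        return VoxelFit(s0, D, W, float(np.linalg.norm(resid)), True, 0)

    def residuals(t: np.ndarray) -> np.ndarray:
        return np.exp(X @ t) - signals

    def jac(t: np.ndarray) -> np.ndarray:
        return np.exp(X @ t)[:, None] * X

    sol = least_squares(residuals, theta, jac=jac, method="lm",
                        xtol=xtol, ftol=1e-14, gtol=1e-14, max_nfev=max_iter)
    s0, D, W = _extract(sol.x)
    return VoxelFit(s0, D, W, float(np.linalg.norm(sol.fun)),
                    bool(sol.status > 0), int(sol.nfev))


def apparent_diffusivity(D: np.ndarray, n: np.ndarray) -> float:
    """Quadratic form n^T D n along unit direction n (mm^2/s)."""
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    return float(n @ np.asarray(D, dtype=float) @ n)


def apparent_kurtosis(D: np.ndarray, W: np.ndarray, n: np.ndarray,
                      tol: float = 1e-12) -> float:
    """Directional apparent kurtosis (MD^2 / D_app^2) * W_app(n)."""
    d_app = apparent_diffusivity(D, n)
    if d_app <= tol:
        raise ValueError(f"apparent diffusivity vanishes along direction {n}")
    md = float(np.trace(np.asarray(D))) / 3.0
    return float(md ** 2 / d_app ** 2 * tensors.w_app(W, n))


def dti_metrics(D: np.ndarray) -> tuple[float, float, float, float, np.ndarray]:
    """(MD, D_axial, D_radial, FA, e1) from the eigensystem of D.

    Eigenvalues sorted descending; FA = sqrt(3/2) * ||lambda - MD|| /
    ||lambda||, defined as 0 for the all-zero tensor.
    """
    D = np.asarray(D, dtype=float)
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(D)
    order = np.argsort(eigvals)[::-1]
    lam = eigvals[order]
    e1 = eigvecs[:, order[0]]
    md = lam.mean()
    norm = np.linalg.norm(lam)
    fa = 0.0 if norm == 0 else float(np.sqrt(1.5) * np.linalg.norm(lam - md) / norm)
    return float(md), float(lam[0]), float((lam[1] + lam[2]) / 2.0), fa, e1


def _perpendicular_directions(e1: np.ndarray, n: int) -> np.ndarray:
    """n directions uniformly spaced in the plane perpendicular to e1."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(e1, ref)
    u /= np.linalg.norm(u)
    v = np.cross(e1, u)
    t = np.linspace(0.0, np.pi, n, endpoint=False)
    return np.cos(t)[:, None] * u + np.sin(t)[:, None] * v


def dki_metrics(fit: VoxelFit, scheme: AcquisitionScheme,
                n_radial_samples: int = 64, clip_k: bool = True,
                allow_unconverged: bool = False) -> MetricSet:
    """Derive the seven scalar metrics from a voxel fit.

    MK averages the apparent kurtosis over the scheme's gradient directions
    (the acquisition convention, not the analytic spherical mean); K_axial is
    taken along the principal eigenvector; K_radial averages
    ``n_radial_samples`` equally spaced perpendicular directions.  Directional
    kurtosis values are clipped to [0, 3] when ``clip_k`` (plausibility
    bounds for brain tissue).
    """
    if not fit.converged and not allow_unconverged:
        raise ValueError("fit did not converge; pass allow_unconverged=True to override")
    md, d_ax, d_rad, fa, e1 = dti_metrics(fit.D_hat)

    def k_app(dirs: np.ndarray) -> np.ndarray:
        vals = np.array([apparent_kurtosis(fit.D_hat, fit.W_hat, d) for d in dirs])
        return np.clip(vals, *K_APP_BOUNDS) if clip_k else vals

    mk = float(np.mean(k_app(scheme.directions)))
    k_axial = float(k_app(e1[None, :])[0])
    k_radial = float(np.mean(k_app(_perpendicular_directions(e1, n_radial_samples))))
    return MetricSet(md, d_ax, d_rad, fa, mk, k_axial, k_radial)


def fit_volume(dwi: np.ndarray, scheme: AcquisitionScheme,
               mask: np.ndarray | None = None,
               method: str = "wls_init_then_lm") -> dict[str, np.ndarray]:
    """Fit every masked voxel of a 4D DWI array and return the seven metric
    maps as float arrays (diffusivities in mm^2/s; NaN outside the mask or
    where signals are degenerate)."""
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != scheme.total_volumes:
        raise ValueError("last DWI axis must match the scheme volume count")
    spatial = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    maps = {k: np.full(spatial, np.nan)
            for k in ("md", "d_axial", "d_radial", "fa", "mk", "k_axial", "k_radial")}
    X = build_design(scheme)
    for idx in np.ndindex(*spatial):
        if not mask[idx]:
            continue
        sig = dwi[idx]
        if np.any(sig <= 0):
            continue  # degenerate voxel: skipped, left masked
        fit = fit_voxel(sig, scheme, method=method, design=X)
        ms = dki_metrics(fit, scheme, allow_unconverged=True)
        for k, v in ms.as_dict().items():
            maps[k][idx] = v
    return maps
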