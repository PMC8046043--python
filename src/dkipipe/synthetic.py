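"""Synthetic diffusion-weighted signals and fiber phantoms.

Signals follow the two-term cumulant (kurtosis) expansion

    S(b, n) = S0 * exp(-b * D_app(n) + (1/6) * b^2 * D_app(n)^2 * K_app(n))

with apparent diffusivity ``D_app(n) = n^T D n`` and apparent kurtosis
``K_app(n) = (MD^2 / D_app(n)^2) * sum n_i n_j n_k n_l W_ijkl``, so the
exponent is linear in D and in V = MD^2 * W.  Magnitude-MRI noise is Rician:
independent Gaussian noise of standard deviation sigma on the real and
imaginary channels, followed by taking the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme
from . import tensors

__all__ = [
    "GroundTruthVoxel",
    "FiberPhantom",
    "predict_signal",
    "simulate_dwi",
    "make_fiber_phantom",
    "random_truth",
]


@dataclass(frozen=True)
class GroundTruthVoxel:
    """Known (S0, D, W) for one voxel.

    ``D`` is symmetric positive semi-definite, in mm^2/s (typical brain
    values are around 1e-3); ``W`` is the 15-component kurtosis tensor.
    """

    S0: float
    D: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        D = np.asarray(self.D, dtype=float)
        if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("D must be a symmetric 3x3 tensor")
        if np.linalg.eigvalsh(D).min() < -1e-15:
            raise ValueError("D must be positive semi-definite")
        W = np.asarray(self.W, dtype=float)
        if W.shape == (3, 3, 3, 3):
            W = tensors.full_to_w15(W)
        elif W.shape != (15,):
            raise ValueError("W must be a 15-vector or full 3x3x3x3 tensor")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "W", W)


def predict_signal(model: GroundTruthVoxel, b: float, n: np.ndarray) -> float:
    """Noise-free signal along unit direction ``n`` at b-value ``b`` (s/mm^2)."""
    if b < 0:
        raise ValueError("b-value must be non-negative")
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    if b == 0:
        return float(model.S0)
    d_app = float(n @ model.D @ n)
    md = np.trace(model.D) / 3.0
    w_app = float(tensors.w_app(model.W, n))
    exponent = -b * d_app + (b ** 2 / 6.0) * md ** 2 * w_app
    return float(model.S0 * np.exp(exponent))


def signal_vector(model: GroundTruthVoxel, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free signals for every volume of ``scheme``."""
    bvals = scheme.bvals
    out = np.empty(scheme.total_volumes)
    out[: scheme.n_b0] = model.S0
    md = np.trace(model.D) / 3.0
    d6 = tensors.dmat_to_d6(model.D)
    d_app = tensors.direction_monomials_d(scheme.directions) @ d6
    w_app = tensors.direction_monomials_w(scheme.directions) @ model.W
    k = scheme.n_b0
    for b in scheme.shells:
        out[k : k + scheme.n_directions] = model.S0 * np.exp(
            -b * d_app + (b ** 2 / 6.0) * md ** 2 * w_app
        )
        k += scheme.n_directions
    return out


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    real = signal + rng.normal(0.0, sigma, size=signal.shape)
    imag = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt(real ** 2 + imag ** 2)


def simulate_dwi(truth_field, scheme: AcquisitionScheme, snr: float | None = None,
                 seed: int = 0, noise: str = "rician") -> np.ndarray:
    """Simulate a 4D DWI array from a grid of ground-truth voxels.

    Parameters
    ----------
    truth_field : a single :class:`GroundTruthVoxel` or an object array of
        them (any grid shape); ``None`` entries yield zero signal.
    snr : signal-to-noise ratio defined against the mean ground-truth S0;
        ``None`` gives noise-free signals.
    noise : "rician" (default, magnitude MRI) or "gaussian" (debugging).

    Returns
    -------
    (grid..., total_volumes) float array.
    """
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    if isinstance(truth_field, GroundTruthVoxel):
        field = np.empty((1,), dtype=object)
        field[0] = truth_field
        squeeze = True
    else:
        field = np.asarray(truth_field, dtype=object)
        squeeze = False
    if field.size == 0:
        raise ValueError("truth_field must be non-empty")
    flat = field.reshape(-1)
    sig = np.zeros((flat.size, scheme.total_volumes))
    s0s = []
    for i, vox in enumerate(flat):
        if vox is None:
            continue
        sig[i] = signal_vector(vox, scheme)
        s0s.append(vox.S0)
    if snr is not None:
        sigma = float(np.mean(s0s)) / snr
        rng = np.random.default_rng(seed)
        if noise == "rician":
            sig = _rician(rng, sig, sigma)
        elif noise == "gaussian":
            sig = sig + rng.normal(0.0, sigma, size=sig.shape)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
    sig = sig.reshape(field.shape + (scheme.total_volumes,))
    return sig[0] if squeeze else sig


def random_truth(rng: np.random.Generator, s0: float = 1000.0,
                 eig_range: tuple[float, float] = (0.3e-3, 2.0e-3),
                 k_range: tuple[float, float] = (0.4, 1.5)) -> GroundTruthVoxel:
    """Random plausible ground-truth voxel: PSD D with uniform eigenvalues,
    random orientation, and an orthotropic W with per-axis kurtosis drawn
    from ``k_range``."""
    D = tensors.random_psd_tensor(rng, eig_range)
    eigvals, eigvecs = np.linalg.eigh(D)
    k_axes = rng.uniform(*k_range, size=3)
    W = tensors.orthotropic_w15(eigvecs, eigvals, k_axes)
    return GroundTruthVoxel(S0=s0, D=D, W=W)


# --------------------------------------------------------------------------
# Fiber phantoms for tractography


@dataclass
class FiberPhantom:
    """Voxel grid carrying a principal-direction field, an FA field, a mean
    kurtosis field, and integer ROI labels marking bundle end regions
    (label 1: thalamic-subregion stand-in; label 2: superior-frontal-gyrus
    stand-in)."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    principal_direction_field: np.ndarray  # (X, Y, Z, 3)
    fa_field: np.ndarray                   # (X, Y, Z)
    mk_field: np.ndarray                   # (X, Y, Z)
    roi_labels: np.ndarray                 # (X, Y, Z) int

    def __post_init__(self) -> None:
        if self.roi_labels.min() < 0:
            raise ValueError("ROI labels must be non-negative")


_BACKGROUND_FA = 0.05


def make_fiber_phantom(geometry: str, grid_shape=(60, 20, 20),
                       voxel_size=(1.0, 1.0, 1.0), fa_inside: float = 0.5,
                       bundle_radius_mm: float = 4.0, mk_inside: float = 0.9,
                       roi_depth_mm: float = 3.0) -> FiberPhantom:
    """Construct a fiber phantom with known geometry.

    Geometries
    ----------
    ``straight``: a cylinder along +x spanning the grid.
    ``curved``: a 90-degree arc in the x-y plane.
    ``crossing``: two orthogonal straight bundles; overlap voxels carry the
        dominant (first) bundle's direction, the single-tensor convention.

    ROI labels 1 and 2 mark the two bundle end regions (``roi_depth_mm``
    thick).
    """
    if not 0.0 <= fa_inside <= 1.0:
        raise ValueError("fa_inside must lie in [0, 1]")
    grid_shape = tuple(int(s) for s in grid_shape)
    voxel_size = tuple(float(v) for v in voxel_size)
    if bundle_radius_mm < min(voxel_size):
        raise ValueError("bundle thinner than one voxel")

    nx, ny, nz = grid_shape
    # voxel-centre coordinates in mm
    xs = (np.arange(nx) + 0.5) * voxel_size[0]
    ys = (np.arange(ny) + 0.5) * voxel_size[1]
    zs = (np.arange(nz) + 0.5) * voxel_size[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    dirs = np.zeros(grid_shape + (3,))
    fa = np.full(grid_shape, _BACKGROUND_FA)
    labels = np.zeros(grid_shape, dtype=int)
    cy, cz = ny * voxel_size[1] / 2.0, nz * voxel_size[2] / 2.0

    if geometry == "straight":
        inside = (Y - cy) ** 2 + (Z - cz) ** 2 <= bundle_radius_mm ** 2
        dirs[inside] = (1.0, 0.0, 0.0)
        fa[inside] = fa_inside
        labels[inside & (X <= roi_depth_mm)] = 1
        labels[inside & (X >= nx * voxel_size[0] - roi_depth_mm)] = 2
    elif geometry == "curved":
        # quarter circle centred at the (x=0, y=0) edge, in the z = mid plane
        radius = min(nx * voxel_size[0], ny * voxel_size[1]) * 0.7
        r = np.sqrt(X ** 2 + Y ** 2)
        inside = (np.abs(r - radius) <= bundle_radius_mm) & (
            np.abs(Z - cz) <= bundle_radius_mm
        )
        theta = np.arctan2(Y, X)
        tang = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
        dirs[inside] = tang[inside]
        fa[inside] = fa_inside
        labels[inside & (theta <= np.deg2rad(8))] = 1
        labels[inside & (theta >= np.deg2rad(82))] = 2
    elif geometry == "crossing":
        in_a = (Y - cy) ** 2 + (Z - cz) ** 2 <= bundle_radius_mm ** 2
        cx = nx * voxel_size[0] / 2.0
        in_b = (X - cx) ** 2 + (Z - cz) ** 2 <= bundle_radius_mm ** 2
        dirs[in_b] = (0.0, 1.0, 0.0)
        dirs[in_a] = (1.0, 0.0, 0.0)  # dominant bundle wins in the overlap
        fa[in_a | in_b] = fa_inside
        labels[in_a & (X <= roi_depth_mm)] = 1
        labels[in_a & (X >= nx * voxel_size[0] - roi_depth_mm)] = 2
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    mk = np.where(fa > _BACKGROUND_FA, mk_inside, 0.2)
    return FiberPhantom(
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        principal_direction_field=dirs,
        fa_field=fa,
        mk_field=mk,
        roi_labels=labels,
    )
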