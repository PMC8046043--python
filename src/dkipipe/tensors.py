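"""Symmetric tensor utilities for the diffusion kurtosis model.

The diffusion tensor ``D`` is a symmetric 3x3 matrix (units mm^2/s).  The
kurtosis tensor ``W`` is a fully symmetric rank-4 tensor with 15 unique
components (dimensionless).  Throughout the package ``W`` travels as a
15-vector in the index ordering below; helpers convert to and from the full
3x3x3x3 representation.
"""

from __future__ import annotations

import itertools

import numpy as np

#: Unique index quadruples of a fully symmetric rank-4 tensor, as exponent
#: triples (a, b, c) meaning x^a y^b z^c with a + b + c = 4.
W_EXPONENTS: tuple[tuple[int, int, int], ...] = (
    (4, 0, 0),  # W_xxxx
    (0, 4, 0),  # W_yyyy
    (0, 0, 4),  # W_zzzz
    (3, 1, 0),  # W_xxxy
    (3, 0, 1),  # W_xxxz
    (1, 3, 0),  # W_xyyy
    (0, 3, 1),  # W_yyyz
    (1, 0, 3),  # W_xzzz
    (0, 1, 3),  # W_yzzz
    (2, 2, 0),  # W_xxyy
    (2, 0, 2),  # W_xxzz
    (0, 2, 2),  # W_yyzz
    (2, 1, 1),  # W_xxyz
    (1, 2, 1),  # W_xyyz
    (1, 1, 2),  # W_xyzz
)

#: Multiplicity of each unique component among the 81 index permutations.
W_MULTIPLICITY = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)

#: Exponent triples for the 6 unique components of D (xx, yy, zz, xy, xz, yz).
D_EXPONENTS: tuple[tuple[int, int, int], ...] = (
    (2, 0, 0),
    (0, 2, 0),
    (0, 0, 2),
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
)
D_MULTIPLICITY = np.array([1, 1, 1, 2, 2, 2], dtype=float)


def dmat_to_d6(D: np.ndarray) -> np.ndarray:
    """Flatten a symmetric 3x3 tensor to (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    D = np.asarray(D, dtype=float)
    return np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])


def d6_to_dmat(d6: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dmat_to_d6`."""
    xx, yy, zz, xy, xz, yz = np.asarray(d6, dtype=float)
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


def w15_to_full(w15: np.ndarray) -> np.ndarray:
    """Expand a 15-vector into the full 3x3x3x3 symmetric tensor."""
    w15 = np.asarray(w15, dtype=float)
    full = np.zeros((3, 3, 3, 3))
    for value, (a, b, c) in zip(w15, W_EXPONENTS):
        idx = (0,) * a + (1,) * b + (2,) * c
        for perm in set(itertools.permutations(idx)):
            full[perm] = value
    return full


def full_to_w15(full: np.ndarray) -> np.ndarray:
    """Extract the 15 unique components from a full rank-4 tensor."""
    full = np.asarray(full, dtype=float)
    out = np.empty(15)
    for k, (a, b, c) in enumerate(W_EXPONENTS):
        idx = (0,) * a + (1,) * b + (2,) * c
        out[k] = full[idx]
    return out


def direction_monomials_d(n: np.ndarray) -> np.ndarray:
    """Monomials n_i n_j (with symmetry multiplicity) mapping d6 -> n^T D n.

    Accepts a single direction (3,) or a stack (m, 3); returns (6,) or (m, 6).
    """
    n = np.asarray(n, dtype=float)
    x, y, z = n[..., 0], n[..., 1], n[..., 2]
    cols = [x * x, y * y, z * z, x * y, x * z, y * z]
    return np.stack(cols, axis=-1) * D_MULTIPLICITY


def direction_monomials_w(n: np.ndarray) -> np.ndarray:
    """Monomials n_i n_j n_k n_l (with multiplicity) mapping w15 -> W_app(n)."""
    n = np.asarray(n, dtype=float)
    x, y, z = n[..., 0], n[..., 1], n[..., 2]
    cols = [x ** a * y ** b * z ** c for (a, b, c) in W_EXPONENTS]
    return np.stack(cols, axis=-1) * W_MULTIPLICITY


def w_app(w15: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Directional contraction sum_ijkl n_i n_j n_k n_l W_ijkl."""
    return direction_monomials_w(n) @ np.asarray(w15, dtype=float)


def isotropic_w15(k_app: float) -> np.ndarray:
    """W whose apparent kurtosis equals ``k_app`` in every direction, for
    isotropic D."""
    w = np.zeros(15)
    w[0] = w[1] = w[2] = k_app
    w[9] = w[10] = w[11] = k_app / 3.0
    return w


def orthotropic_w15(eigvecs: np.ndarray, eigvals: np.ndarray,
                    k_axes: np.ndarray) -> np.ndarray:
    """Build a kurtosis tensor with prescribed apparent kurtosis along the
    diffusion eigenvectors.

    In the eigenframe the tensor carries the pure-axis components
    ``W'_iiii = K_i * lambda_i^2 / MD^2`` plus cross terms
    ``W'_iijj = sqrt(W'_iiii W'_jjjj) / 3``, which reduce the construction to
    the exact isotropic tensor when all axes agree.

    Parameters
    ----------
    eigvecs : (3, 3) orthonormal matrix, columns are the diffusion eigenvectors.
    eigvals : (3,) diffusion eigenvalues (mm^2/s).
    k_axes : (3,) target apparent kurtosis along each eigenvector.
    """
    eigvecs = np.asarray(eigvecs, dtype=float)
    eigvals = np.asarray(eigvals, dtype=float)
    k_axes = np.asarray(k_axes, dtype=float)
    md = eigvals.mean()
    wdiag = k_axes * eigvals ** 2 / md ** 2
    if np.any(wdiag < 0):
        raise ValueError("apparent kurtosis along an axis must be >= 0")
    prime = np.zeros((3, 3, 3, 3))
    for i in range(3):
        prime[i, i, i, i] = wdiag[i]
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        cross = np.sqrt(wdiag[i] * wdiag[j]) / 3.0
        idx = (i, i, j, j)
        for perm in set(itertools.permutations(idx)):
            prime[perm] = cross
    full = np.einsum("ia,jb,kc,ld,abcd->ijkl", eigvecs, eigvecs, eigvecs, eigvecs, prime)
    return full_to_w15(full)


def random_psd_tensor(rng: np.random.Generator,
                      eig_range: tuple[float, float] = (0.3e-3, 2.0e-3)) -> np.ndarray:
    """Random positive semi-definite diffusion tensor with eigenvalues drawn
    uniformly from ``eig_range`` and a uniformly random orientation."""
    eigvals = rng.uniform(*eig_range, size=3)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    return q @ np.diag(eigvals) @ q.T
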