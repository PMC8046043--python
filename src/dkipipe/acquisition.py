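"""Two-shell diffusion acquisition schemes.

A scheme is the full ordered list of acquired volumes: ``n_b0`` unweighted
images followed by every gradient direction repeated once per shell.  The
clinical protocol this emulates uses 30 directions at b = 1,000 and
2,000 s/mm^2 plus five b0 volumes, 65 volumes in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme", "make_scheme"]


@dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion sampling scheme.

    Attributes
    ----------
    directions : (m, 3) array of unit gradient directions.
    shells : b-values in s/mm^2, one per shell.
    n_b0 : number of unweighted (b = 0) volumes, acquired first.
    """

    directions: np.ndarray
    shells: tuple[float, ...]
    n_b0: int

    def __post_init__(self) -> None:
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        norms = np.linalg.norm(dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("gradient directions must be unit vectors")
        if any(b <= 0 for b in self.shells):
            raise ValueError("shell b-values must be strictly positive")
        if self.n_b0 < 0:
            raise ValueError("n_b0 must be non-negative")
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "shells", tuple(float(b) for b in self.shells))

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def total_volumes(self) -> int:
        return self.n_b0 + self.n_directions * len(self.shells)

    @property
    def bvals(self) -> np.ndarray:
        """Per-volume b-values, b0 volumes first then shell blocks."""
        return np.concatenate(
            [np.zeros(self.n_b0)] + [np.full(self.n_directions, b) for b in self.shells]
        )

    @property
    def bvecs(self) -> np.ndarray:
        """Per-volume gradient directions, (total_volumes, 3); zero rows for b0."""
        return np.concatenate(
            [np.zeros((self.n_b0, 3))] + [self.directions] * len(self.shells)
        )


def _repulsion_layout(n: int, seed: int, n_iter: int = 2000, lr: float = 5e-3) -> np.ndarray:
    """Electrostatic-repulsion direction layout on the hemisphere.

    Antipodally symmetric Coulomb energy (each point interacts with every
    other point and its antipode) minimised by projected gradient descent,
    then canonicalised to the z >= 0 hemisphere.
    """
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    for _ in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]
        dsum = p[:, None, :] + p[None, :, :]
        r1 = np.linalg.norm(diff, axis=-1)
        r2 = np.linalg.norm(dsum, axis=-1)
        np.fill_diagonal(r1, np.inf)
        np.fill_diagonal(r2, np.inf)
        force = (diff / r1[..., None] ** 3).sum(axis=1) + (dsum / r2[..., None] ** 3).sum(axis=1)
        # keep only the tangential component so points stay near the sphere
        force -= (force * p).sum(axis=1, keepdims=True) * p
        p = p + lr * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    p[p[:, 2] < 0] *= -1.0
    return p


def make_scheme(n_directions: int, shells: list[float], n_b0: int,
                seed: int = 0) -> AcquisitionScheme:
    """Create a multi-shell scheme with repulsion-optimised directions.

    Parameters
    ----------
    n_directions : number of gradient directions (>= 6; two shells or >= 15
        directions are needed downstream to determine the kurtosis tensor).
    shells : non-empty list of positive b-values in s/mm^2.
    n_b0 : number of unweighted volumes.
    seed : seed for the repulsion initialisation; layouts are reproducible.
    """
    if n_directions < 6:
        raise ValueError("at least 6 gradient directions are required")
    if not shells:
        raise ValueError("at least one shell is required")
    if any(b <= 0 for b in shells):
        raise ValueError("shell b-values must be strictly positive")
    dirs = _repulsion_layout(n_directions, seed)
    return AcquisitionScheme(directions=dirs, shells=tuple(shells), n_b0=n_b0)
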