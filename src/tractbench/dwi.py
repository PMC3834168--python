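"""Diffusion-weighted volumes and gradient tables.

All diffusivities in this package are expressed in units of 1e-3 mm^2/s
(the scale on which white-matter values are ~0.2-1.6), b-values in s/mm^2,
and spatial coordinates in world millimetres via the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Conversion so that exp(-b * BSCALE * D) is the attenuation for b in s/mm^2
#: and D in 1e-3 mm^2/s.
BSCALE = 1.0e-3


class GradientTableError(ValueError):
    """Raised when a gradient table violates its contract."""


@dataclass(frozen=True)
class GradientTable:
    """Diffusion sensitisation scheme: unit directions and b-values.

    Parameters
    ----------
    bvals : (N,) array of b-values in s/mm^2. At least one must be 0.
    bvecs : (N, 3) array of sensitisation directions. Every direction with
        b > 0 must be unit length; b=0 rows may be zero vectors.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientTableError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise GradientTableError(
                f"{len(bvals)} b-values but {len(bvecs)} directions"
            )
        if not np.any(bvals == 0):
            raise GradientTableError("at least one b=0 entry is required")
        dwi = bvals > 0
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise GradientTableError("b>0 directions must be unit vectors")
        if _n_independent_directions(bvecs[dwi]) < 6:
            raise GradientTableError(
                "need >= 6 non-collinear diffusion directions for a tensor fit"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


def _n_independent_directions(vecs: np.ndarray) -> int:
    """Rank of the 6-component quadratic-form design spanned by directions.

    A tensor fit needs the outer-product design matrix to have rank 6;
    collinear (antipodal) duplicates do not add rank.
    """
    if len(vecs) == 0:
        return 0
    g = vecs
    design = np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         g[:, 0] * g[:, 1], g[:, 0] * g[:, 2], g[:, 1] * g[:, 2]]
    )
    return int(np.linalg.matrix_rank(design, tol=1e-8))


def make_gradient_table(n_directions: int = 61, bvalue: float = 1000.0,
                        n_b0: int = 1) -> GradientTable:
    """Deterministic single-shell scheme: n_b0 b=0 volumes plus
    ``n_directions`` directions spread over the hemisphere by a spherical
    Fibonacci lattice (the emulated acquisition uses 61 directions at
    b = 1000 s/mm^2).
    """
    i = np.arange(n_directions, dtype=float) + 0.5
    # hemisphere (z >= 0): antipodal directions are redundant for diffusion
    z = i / n_directions
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, bvalue)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its voxel-to-world affine.

    ``signal`` is indexed (x, y, z, gradient); the affine maps homogeneous
    voxel indices to world millimetres.
    """

    signal: np.ndarray
    affine: np.ndarray
    gradients: GradientTable

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, gradient)")
        if self.signal.shape[3] != len(self.gradients):
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but the gradient "
                f"table has {len(self.gradients)} entries"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.signal.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def b0_mean(self) -> np.ndarray:
        return self.signal[..., self.gradients.b0_mask].mean(axis=-1)


def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map world-mm points to (fractional) voxel indices."""
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(points)
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out.reshape(np.shape(points))


def voxel_to_world(affine: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Map (possibly fractional) voxel indices to world millimetres."""
    ix = np.atleast_2d(idx)
    out = ix @ affine[:3, :3].T + affine[:3, 3]
    return out.reshape(np.shape(np.asarray(idx, dtype=float)))
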