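"""Rank-2 diffusion-tensor fitting and eigen-metrics (FA, MD, AD, RD).

The tensor D (units 1e-3 mm^2/s) is fitted per voxel by weighted log-linear
least squares from S(g) = S0 exp(-b g^T D g), then decomposed into sorted
eigenvalues lambda1 >= lambda2 >= lambda3 and orthonormal eigenvectors.

Scalar metrics:

    MD = (l1 + l2 + l3) / 3          mean diffusivity
    AD = l1                          axial diffusivity
    RD = (l2 + l3) / 2               radial diffusivity
    FA = sqrt(3/2 * sum_i (l_i - MD)^2 / sum_i l_i^2)

FA of the zero tensor is 0 by convention (the isotropic limit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dwi import BSCALE, DWIVolume

log = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """Gradient scheme cannot determine all six tensor components."""


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 tensor (1e-3 mm^2/s) with a validity mask."""

    tensors: np.ndarray  # (X, Y, Z, 3, 3)
    mask: np.ndarray     # (X, Y, Z) bool

    def __post_init__(self):
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must be (..., 3, 3)")
        if self.mask.shape != self.tensors.shape[:-2]:
            raise ValueError("mask/tensor grid mismatch")


@dataclass
class EigenSystem:
    """Sorted eigen-decomposition of a tensor field.

    ``evals[..., i]`` is lambda_{i+1} (descending); ``evecs[..., :, i]`` the
    matching unit eigenvector. Out-of-mask voxels hold zeros.
    """

    evals: np.ndarray  # (X, Y, Z, 3)
    evecs: np.ndarray  # (X, Y, Z, 3, 3), columns are eigenvectors
    mask: np.ndarray
    n_clipped: int = 0

    @property
    def v1(self) -> np.ndarray:
        return self.evecs[..., :, 0]


@dataclass
class ScalarMaps:
    """FA (dimensionless, [0, 1]) and MD/AD/RD (1e-3 mm^2/s) maps."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    mask: np.ndarray


def design_matrix(gradients) -> np.ndarray:
    """(N, 7) log-linear design: columns [1, -b*gx^2, -b*gy^2, -b*gz^2,
    -2b*gxgy, -2b*gxgz, -2b*gygz], b rescaled so D comes out in 1e-3 mm^2/s."""
    b = gradients.bvals * BSCALE
    g = gradients.bvecs
    return np.column_stack([
        np.ones(len(b)),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _coef_to_tensor(coef: np.ndarray) -> np.ndarray:
    """Map fitted coefficients (..., 7) to symmetric tensors (..., 3, 3)."""
    dxx, dyy, dzz, dxy, dxz, dyz = (coef[..., i] for i in range(1, 7))
    t = np.empty(coef.shape[:-1] + (3, 3))
    t[..., 0, 0] = dxx
    t[..., 1, 1] = dyy
    t[..., 2, 2] = dzz
    t[..., 0, 1] = t[..., 1, 0] = dxy
    t[..., 0, 2] = t[..., 2, 0] = dxz
    t[..., 1, 2] = t[..., 2, 1] = dyz
    return t


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Weighted log-linear least-squares tensor fit (weights S^2).

    Voxels with any non-positive b0 signal are flagged invalid in the output
    mask rather than raising. A single weighted pass is used, with weights
    taken from the measured signal.
    """
    if mask is None:
        mask = np.ones(dwi.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape:
        raise ValueError("mask/volume grid mismatch")

    A = design_matrix(dwi.gradients)
    if np.linalg.matrix_rank(A, tol=1e-8) < 7:
        raise DegenerateDesignError(
            "gradient scheme does not determine all tensor components"
        )

    sig = dwi.signal[mask]                      # (n_vox, N)
    b0 = sig[:, dwi.gradients.b0_mask]
    valid = np.all(b0 > 0, axis=1) & np.all(sig > 0, axis=1)
    n_invalid = int(np.count_nonzero(~valid))
    if n_invalid:
        log.warning("%d in-mask voxels with non-positive signal flagged "
                    "invalid", n_invalid)

    tensors = np.zeros(dwi.shape + (3, 3))
    out_mask = np.zeros(dwi.shape, dtype=bool)
    if np.any(valid):
        s = sig[valid]
        y = np.log(s)
        w = s ** 2                              # WLS weights
        # normal equations per voxel: (A^T W A) x = A^T W y
        lhs = np.einsum("gi,ng,gj->nij", A, w, A)
        rhs = np.einsum("gi,ng,ng->ni", A, w, y)
        coef = np.linalg.solve(lhs, rhs[..., None])[..., 0]
        t = _coef_to_tensor(coef)
        idx = np.argwhere(mask)[valid]
        tensors[idx[:, 0], idx[:, 1], idx[:, 2]] = t
        out_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return TensorField(tensors, out_mask)


def _fix_eigvec_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| entry positive."""
    # vecs: (..., 3, 3) columns are eigenvectors
    comp = np.abs(vecs)
    arg = comp.argmax(axis=-2)                   # (..., 3) per column
    picked = np.take_along_axis(vecs, arg[..., None, :], axis=-2)[..., 0, :]
    sign = np.where(picked < 0, -1.0, 1.0)
    return vecs * sign[..., None, :]


def eigendecompose(field: TensorField) -> EigenSystem:
    """Sorted (descending) eigen-decomposition of every in-mask tensor.

    Negative eigenvalues (possible under noise) are clipped to zero and
    counted; the reconstruction contract V diag(l) V^T == D therefore holds
    only for the unclipped spectrum.
    """
    t = field.tensors
    if not np.allclose(t, np.swapaxes(t, -1, -2), atol=1e-9):
        raise ValueError("tensors must be symmetric")
    evals = np.zeros(t.shape[:-2] + (3,))
    evecs = np.zeros_like(t)
    evecs[..., :, :] = np.eye(3)
    n_clipped = 0
    if np.any(field.mask):
        w, v = np.linalg.eigh(t[field.mask])     # ascending
        w = w[:, ::-1]
        v = v[:, :, ::-1]
        n_clipped = int(np.count_nonzero(w < 0))
        if n_clipped:
            log.info("clipped %d negative eigenvalues to 0", n_clipped)
        w = np.clip(w, 0.0, None)
        v = _fix_eigvec_signs(v)
        evals[field.mask] = w
        evecs[field.mask] = v
    return EigenSystem(evals, evecs, field.mask.copy(), n_clipped)


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (last axis length 3); 0 where all eigenvalues are 0."""
    lam = np.asarray(evals, dtype=float)
    md = lam.mean(axis=-1, keepdims=True)
    num = 3.0 * ((lam - md) ** 2).sum(axis=-1)
    den = 2.0 * (lam ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def mean_axial_radial(evals: np.ndarray) -> tuple:
    """(MD, AD, RD) from descending-sorted eigenvalues."""
    lam = np.asarray(evals, dtype=float)
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = 0.5 * (lam[..., 1] + lam[..., 2])
    return md, ad, rd


def scalar_maps(eigs: EigenSystem) -> ScalarMaps:
    """All four eigen-metrics on the grid; zeros outside the mask."""
    md, ad, rd = mean_axial_radial(eigs.evals)
    fa = fractional_anisotropy(eigs.evals)
    m = eigs.mask
    return ScalarMaps(fa * m, md * m, ad * m, rd * m, m.copy())


def axial_symmetric_evals(ad: float, rd: float) -> np.ndarray:
    """Eigenvalue triple (AD, RD, RD) of an axially symmetric tensor."""
    return np.array([ad, rd, rd], dtype=float)
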