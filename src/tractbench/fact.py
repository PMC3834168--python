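"""Deterministic streamline tractography (fibre assignment by continuous
tracking, FACT).

Streamlines follow the per-voxel principal eigenvector v1 with
nearest-neighbour direction lookup, propagating bidirectionally from each
seed voxel center at a fixed step (default half a voxel). Termination rules:
entering a voxel with FA below ``fa_stop`` (default 0.1), a turn between two
consecutive steps exceeding ``max_angle_deg`` (default 90 — deliberately
liberal so that sharp bends remain trackable), leaving the tracking mask or
the grid, or reaching ``max_length_mm``. The eigenvector sign at every step
is chosen to minimise the turning angle, so the tracker is invariant to
global sign flips of the eigenvector field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dwi import voxel_to_world, world_to_voxel
from .tensor import EigenSystem

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FactParams:
    fa_stop: float = 0.1
    max_angle_deg: float = 90.0
    step_mm: float = 1.0
    max_length_mm: float = 300.0

    def __post_init__(self):
        if not 0 <= self.fa_stop < 1:
            raise ValueError("fa_stop must be in [0, 1)")
        if not 0 < self.max_angle_deg <= 90:
            raise ValueError("max_angle_deg must be in (0, 90]")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")


@dataclass
class StreamlineSet:
    """Polylines in world coordinates (mm) with per-streamline seed ids."""

    streamlines: list = field(default_factory=list)   # of (K, 3) arrays
    seed_ids: list = field(default_factory=list)
    affine: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def all_points(self) -> np.ndarray:
        if not self.streamlines:
            return np.zeros((0, 3))
        return np.vstack(self.streamlines)

    def visited_mask(self, shape: tuple, affine: np.ndarray) -> np.ndarray:
        """Boolean grid of voxels containing any streamline point."""
        out = np.zeros(shape, dtype=bool)
        pts = self.all_points()
        if len(pts) == 0:
            return out
        idx = np.round(world_to_voxel(affine, pts)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        idx = idx[ok]
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return out


def _half_track(pos, direction, v1, fa, wm_mask, affine, inv_rot, inv_off,
                params: FactParams) -> list:
    """Propagate one direction; returns points after the start position."""
    shape = np.array(fa.shape)
    max_steps = int(params.max_length_mm / params.step_mm)
    cos_limit = np.cos(np.deg2rad(params.max_angle_deg)) - 1e-12
    pts = []
    prev = direction
    for _ in range(max_steps):
        vox = np.round(pos @ inv_rot + inv_off).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            break
        i, j, k = vox
        if not wm_mask[i, j, k] or fa[i, j, k] < params.fa_stop:
            break
        d = v1[i, j, k]
        n = np.linalg.norm(d)
        if n < 1e-12:
            break
        d = d / n
        c = float(d @ prev)
        if c < 0:
            d, c = -d, -c
        if c < cos_limit:
            break
        pos = pos + params.step_mm * d
        pts.append(pos)
        prev = d
    return pts


def track_fact(eigs: EigenSystem, fa: np.ndarray, seeds: np.ndarray,
               wm_mask: np.ndarray, params: FactParams = FactParams(),
               affine: np.ndarray | None = None) -> StreamlineSet:
    """FACT tractography from every seed-voxel center, bidirectional along
    the principal eigenvector. Streamlines with fewer than 2 points (seeds in
    sub-threshold voxels) are dropped."""
    if affine is None:
        affine = np.eye(4)
    fa = np.asarray(fa)
    if fa.shape != eigs.evals.shape[:-1]:
        raise ValueError("fa/eigensystem grid mismatch")
    seeds = np.asarray(seeds, dtype=bool)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if seeds.shape != fa.shape or wm_mask.shape != fa.shape:
        raise ValueError("mask/grid mismatch")
    if not np.any(seeds):
        log.warning("empty seed mask: returning no streamlines")
        return StreamlineSet(affine=affine)

    inv = np.linalg.inv(affine)
    inv_rot, inv_off = inv[:3, :3].T.copy(), inv[:3, 3].copy()
    v1 = eigs.v1
    out = StreamlineSet(affine=affine)
    for seed_id, vox in enumerate(np.argwhere(seeds)):
        i, j, k = vox
        if not wm_mask[i, j, k] or fa[i, j, k] < params.fa_stop:
            continue
        d0 = v1[i, j, k]
        n = np.linalg.norm(d0)
        if n < 1e-12:
            continue
        d0 = d0 / n
        start = voxel_to_world(affine, vox.astype(float))
        fwd = _half_track(start, d0, v1, fa, wm_mask, affine, inv_rot,
                          inv_off, params)
        bwd = _half_track(start, -d0, v1, fa, wm_mask, affine, inv_rot,
                          inv_off, params)
        line = np.array(list(reversed(bwd)) + [start] + fwd)
        if len(line) >= 2:
            out.streamlines.append(line)
            out.seed_ids.append(seed_id)
    return out
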