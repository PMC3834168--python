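"""Probabilistic connectivity mapping via Monte-Carlo visiting maps.

Each walk starts at a random seed voxel and propagates like FACT, except the
step direction oscillates around the locally dominant eigen-axis. Two walk
models are available:

* ``adaptive`` (default): the walker follows the eigen-axis that best
  continues its path weighted by the eigenvalue (argmax_i  l_i |v_i . prev|)
  and oscillates around it with in-plane magnitudes proportional to the
  remaining eigenvalue ratios. In a stick voxel (l2 = l3 = 0) this is
  exactly FACT; in a planar crossing voxel the walker can lock onto the
  secondary axis and pass straight through the crossing, at the price of
  occasional off-bundle leakage (false-positive fibres) — the behaviour
  probabilistic connectivity maps show on crossing phantoms.
* ``v1``: the direction is redrawn around the principal eigenvector only,
  d = normalize(v1 + u (l2/l1) v2 + w (l3/l1) v3), u, w ~ U(-1, 1). This is
  the simplest oscillating-largest-vector model; with a single fitted
  tensor per voxel it cannot traverse a crossing from the minor bundle.

Per
voxel, the number of visiting walks and the mean direction of first entry
are accumulated. Inside the walk's own seed region only the departure
direction (the initial direction of the longer half-walk, which is the one
leading into the tract) is recorded, so that seed-region voxels carry a
coherent "leaving toward the target" direction instead of a knife-edge mix
of departures and backward passes. Two visiting maps seeded from the two ends of a tract are
combined into a probabilistic map of connectivity: the product of visit
frequencies, kept only where the mean entry directions oppose each other
(the walks passed through the voxel travelling in opposite senses, i.e. the
voxel lies on a direct path between the seeds). An intrinsic threshold then
prunes speckle: the score level minimising the number of 26-connected
suprathreshold components while still keeping a component that touches both
seed regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fact import FactParams
from .tensor import EigenSystem

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class NotFoundError(RuntimeError):
    """No suprathreshold component touches both seed regions."""


@dataclass
class VisitingMap:
    """Per-voxel walk-visit counts with entry-direction bookkeeping."""

    visits: np.ndarray          # (X, Y, Z) int
    entry_sum: np.ndarray       # (X, Y, Z, 3) summed entry unit vectors
    n_walks: int
    seed_name: str = ""

    def mean_entry(self) -> np.ndarray:
        """Mean entry unit vector per voxel (zero where unvisited)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            m = self.entry_sum / self.visits[..., None]
        m[self.visits == 0] = 0.0
        return m

    def frequency(self) -> np.ndarray:
        if self.n_walks == 0:
            return np.zeros_like(self.visits, dtype=float)
        return self.visits / float(self.n_walks)


@dataclass
class ConnectivityMap:
    """Voxelwise evidence of lying on a direct path between two seed regions."""

    score: np.ndarray
    source_labels: tuple
    threshold: float = 0.0

    def support(self) -> np.ndarray:
        return self.score > self.threshold


def random_walks(eigs: EigenSystem, fa: np.ndarray, seeds: np.ndarray,
                 wm_mask: np.ndarray, n_walks: int, rng_seed: int,
                 params: FactParams = FactParams(),
                 seed_name: str = "",
                 affine: np.ndarray | None = None,
                 model: str = "adaptive") -> VisitingMap:
    """Monte-Carlo visiting map from a seed region (bidirectional walks).

    Stop rules are FACT's (FA threshold, max turn angle, mask, max length).
    Visits are counted once per walk per voxel at first entry; the seed voxel
    is visited by every walk. ``model`` selects the walk model (see module
    docstring).
    """
    if model not in ("adaptive", "v1"):
        raise ValueError(f"unknown walk model {model!r}")
    fa = np.asarray(fa)
    seeds = np.asarray(seeds, dtype=bool)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    shape = fa.shape
    visits = np.zeros(shape, dtype=np.int64)
    entry_sum = np.zeros(shape + (3,))
    if n_walks < 1:
        return VisitingMap(visits, entry_sum, 0, seed_name)
    seed_idx = np.argwhere(seeds & wm_mask & (fa >= params.fa_stop))
    if len(seed_idx) == 0:
        log.warning("no usable seed voxels for %s", seed_name or "walks")
        return VisitingMap(visits, entry_sum, n_walks, seed_name)

    rng = np.random.default_rng(rng_seed)
    evals = eigs.evals
    evecs = eigs.evecs
    if affine is None:
        affine = np.eye(4)
    voxel_mm = float(np.mean(np.sqrt((affine[:3, :3] ** 2).sum(axis=0))))
    step = params.step_mm / voxel_mm  # walk in voxel units
    cos_limit = np.cos(np.deg2rad(params.max_angle_deg)) - 1e-12
    max_steps = int(params.max_length_mm / params.step_mm)
    shape_arr = np.array(shape)

    def perturbed_dir(vox, prev, rng):
        lam = evals[vox[0], vox[1], vox[2]]
        if lam[0] < 1e-12:
            return None
        V = evecs[vox[0], vox[1], vox[2]]
        if model == "adaptive" and prev is not None:
            a = int(np.argmax(lam * np.abs(V.T @ prev)))
        else:
            a = 0
        d = V[:, a].copy()
        if prev is not None and float(d @ prev) < 0:
            d = -d
        for i in range(3):
            if i == a:
                continue
            r = min(1.0, lam[i] / lam[a]) if lam[a] > 1e-12 else 0.0
            d = d + rng.uniform(-1.0, 1.0) * r * V[:, i]
        n = np.linalg.norm(d)
        return d / n if n > 1e-12 else None

    for _ in range(n_walks):
        svox = seed_idx[rng.integers(len(seed_idx))]
        visited = {tuple(svox)}
        half_dirs = [None, None]
        half_lens = [0, 0]
        for half, sign in enumerate((1.0, -1.0)):
            pos = svox.astype(float)
            d = perturbed_dir(svox, None, rng)
            if d is None:
                break
            prev = sign * d
            half_dirs[half] = prev
            for _ in range(max_steps):
                vox = np.round(pos).astype(int)
                if np.any(vox < 0) or np.any(vox >= shape_arr):
                    break
                i, j, k = vox
                if not wm_mask[i, j, k] or fa[i, j, k] < params.fa_stop:
                    break
                d = perturbed_dir(vox, prev, rng)
                if d is None:
                    break
                c = float(d @ prev)
                if c < 0:
                    d, c = -d, -c
                if c < cos_limit:
                    break
                pos = pos + step * d
                key = (int(round(pos[0])), int(round(pos[1])),
                       int(round(pos[2])))
                if (0 <= key[0] < shape[0] and 0 <= key[1] < shape[1]
                        and 0 <= key[2] < shape[2] and key not in visited):
                    visited.add(key)
                    visits[key] += 1
                    half_lens[half] += 1
                    if not seeds[key]:   # own-seed voxels: departures only
                        entry_sum[key] += d
                prev = d
        visits[svox[0], svox[1], svox[2]] += 1
        departure = half_dirs[int(half_lens[1] > half_lens[0])]
        if departure is not None:
            entry_sum[svox[0], svox[1], svox[2]] += departure
    return VisitingMap(visits, entry_sum, n_walks, seed_name)


def combine_maps(a: VisitingMap, b: VisitingMap) -> ConnectivityMap:
    """Product of visit frequencies where the mean entry directions oppose.

    score(v) = freq_a(v) * freq_b(v) if mean_entry_a(v) . mean_entry_b(v) < 0
    else 0. Opposed entry operationalises "entered from opposite sides".
    """
    if a.visits.shape != b.visits.shape:
        raise ValueError("visiting maps on different grids")
    if a.n_walks < 1 or b.n_walks < 1:
        raise ValueError("both maps need at least one walk")
    opposed = np.einsum("...i,...i->...", a.mean_entry(), b.mean_entry()) < 0
    score = a.frequency() * b.frequency() * opposed
    return ConnectivityMap(score=score,
                           source_labels=(a.seed_name, b.seed_name))


def intrinsic_threshold(cmap: ConnectivityMap, roi_a: np.ndarray,
                        roi_b: np.ndarray, n_levels: int = 30) -> ConnectivityMap:
    """Pick the score level where the fewest fibres appear.

    Candidate levels are quantiles of the positive scores; for each, the
    26-connected suprathreshold components are counted. The chosen level
    minimises the component count among levels retaining a component that
    touches both ROIs (ties resolved toward the higher level, which prunes
    more speckle). Raises NotFoundError if no level connects the ROIs.
    """
    pos = cmap.score[cmap.score > 0]
    if pos.size == 0:
        raise NotFoundError("connectivity map is empty")
    qs = np.quantile(pos, np.linspace(0.0, 0.95, n_levels))
    levels = np.unique(np.concatenate([[0.0], qs]))
    best = None
    for lev in levels:
        sup = cmap.score > lev
        labels, n = ndimage.label(sup, structure=_STRUCT26)
        if n == 0:
            continue
        la = np.unique(labels[roi_a & sup])
        lb = np.unique(labels[roi_b & sup])
        if len(np.intersect1d(la[la > 0], lb[lb > 0])) == 0:
            continue
        if best is None or n <= best[0]:
            best = (n, lev)
    if best is None:
        raise NotFoundError("no component touches both ROIs at any level")
    out = ConnectivityMap(score=cmap.score.copy(),
                          source_labels=cmap.source_labels,
                          threshold=float(best[1]))
    return out
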