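"""Tract-level measurements: detection classification, metric profiles along
z, tract-to-midline deviation (index of deviation), and planar tumour area.

The index of deviation compares the healthy-side and pathological-side
distance of the tract's in-plane centroid to the midsagittal plane (x = 0
in world coordinates):

    ID = |D_h - D_p| / (D_h + D_p)

It is 0 for mirror-symmetric tracts and approaches 1 when one tract is
pushed onto (or across) the midline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dwi import voxel_to_world
from .fact import StreamlineSet
from .prob import ConnectivityMap, NotFoundError
from .tensor import ScalarMaps

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TractROI:
    """Voxel set of a depicted tract, with its source method label."""

    mask: np.ndarray
    affine: np.ndarray
    method: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def world_coords(self) -> np.ndarray:
        idx = np.argwhere(self.mask).astype(float)
        return voxel_to_world(self.affine, idx)


@dataclass
class MetricProfile:
    """Per-z-bin mean diffusion metrics along a tract."""

    z: np.ndarray              # bin centers, world mm
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray             # NaN where a bin holds no tract voxels


@dataclass
class DeviationMeasurement:
    d_h: float
    d_p: float
    id_value: float
    z_level_mm: float | None = None


def classify_detection(result, seeds: np.ndarray, targets: np.ndarray,
                       shape: tuple | None = None,
                       affine: np.ndarray | None = None) -> str:
    """"found" iff the tracking output contains a connected tract meeting
    both the seed and the target region.

    ``result`` may be a StreamlineSet (found iff one streamline touches both
    ROIs), a thresholded ConnectivityMap (found iff one 26-connected
    suprathreshold component touches both), or a boolean voxel mask.
    """
    seeds = np.asarray(seeds, dtype=bool)
    targets = np.asarray(targets, dtype=bool)
    if isinstance(result, StreamlineSet):
        if shape is None or affine is None:
            raise ValueError("streamline classification needs shape + affine")
        inv = np.linalg.inv(affine)
        for line in result:
            idx = np.round(line @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
            idx = idx[ok]
            hit = np.zeros(shape, dtype=bool)
            hit[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            if np.any(hit & seeds) and np.any(hit & targets):
                return "found"
        return "not_found"
    if isinstance(result, ConnectivityMap):
        support = result.support()
    else:
        support = np.asarray(result, dtype=bool)
    labels, n = ndimage.label(support, structure=_STRUCT26)
    if n == 0:
        return "not_found"
    la = np.unique(labels[seeds & support])
    lb = np.unique(labels[targets & support])
    common = np.intersect1d(la[la > 0], lb[lb > 0])
    return "found" if len(common) else "not_found"


def roi_from_connectivity(cmap: ConnectivityMap, seeds: np.ndarray,
                          targets: np.ndarray, affine: np.ndarray,
                          method: str = "PT") -> TractROI:
    """Tract ROI = the suprathreshold component connecting seed and target."""
    support = cmap.support()
    labels, n = ndimage.label(support, structure=_STRUCT26)
    la = np.unique(labels[np.asarray(seeds, bool) & support])
    lb = np.unique(labels[np.asarray(targets, bool) & support])
    common = np.intersect1d(la[la > 0], lb[lb > 0])
    if len(common) == 0:
        raise NotFoundError("no component connects the two regions")
    mask = np.isin(labels, common)
    return TractROI(mask=mask, affine=affine, method=method)


def profile_along_z(roi: TractROI, maps: ScalarMaps,
                    z_step_mm: float = 2.0,
                    z_range: tuple | None = None) -> MetricProfile:
    """Mean FA/MD/AD/RD over the tract ROI in consecutive z bins.

    Bins with no tract voxels are NaN. ``z_range`` defaults to the ROI's own
    extent; pass (10, 70) to mimic a fixed craniocaudal window.
    """
    if roi.voxel_count() == 0:
        raise ValueError("tract ROI is empty")
    coords = roi.world_coords()
    zs = coords[:, 2]
    if z_range is None:
        z_range = (zs.min(), zs.max() + 1e-9)
    z_lo, z_hi = float(z_range[0]), float(z_range[1])
    n_bins = max(1, int(np.ceil((z_hi - z_lo) / z_step_mm)))
    edges = z_lo + z_step_mm * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.argwhere(roi.mask)
    vals = {name: getattr(maps, name)[idx[:, 0], idx[:, 1], idx[:, 2]]
            for name in ("fa", "md", "ad", "rd")}
    out = {name: np.full(n_bins, np.nan) for name in vals}
    which = np.digitize(zs, edges) - 1
    for b in range(n_bins):
        sel = which == b
        if np.any(sel):
            for name in vals:
                out[name][b] = vals[name][sel].mean()
    return MetricProfile(z=centers, **out)


def deviation_index(d_h: float, d_p: float) -> float:
    """ID = |D_h - D_p| / (D_h + D_p); undefined when both distances are 0."""
    if d_h < 0 or d_p < 0:
        raise ValueError("distances must be non-negative")
    if d_h + d_p == 0:
        raise ValueError("deviation index undefined for d_h + d_p = 0")
    return abs(d_h - d_p) / (d_h + d_p)


def midline_distances(roi_path: TractROI, roi_healthy: TractROI,
                      z_level_mm: float, z_tol_mm: float = 1.0) -> tuple:
    """(d_h, d_p): |x| of each tract's in-plane centroid at a z level,
    relative to the midsagittal plane x = 0."""
    out = []
    for roi in (roi_healthy, roi_path):
        coords = roi.world_coords()
        sel = np.abs(coords[:, 2] - z_level_mm) <= z_tol_mm
        if not np.any(sel):
            raise ValueError(f"tract has no voxels at z = {z_level_mm} mm")
        out.append(abs(float(coords[sel, 0].mean())))
    return out[0], out[1]


def strongest_deviation_level(roi_path: TractROI, roi_healthy: TractROI,
                              z_levels: np.ndarray,
                              z_tol_mm: float = 1.0) -> DeviationMeasurement:
    """Scan z levels and return the deviation at argmax |d_h - d_p|."""
    best = None
    for z in np.atleast_1d(z_levels):
        try:
            d_h, d_p = midline_distances(roi_path, roi_healthy, float(z),
                                         z_tol_mm)
        except ValueError:
            continue
        gap = abs(d_h - d_p)
        if best is None or gap > best[0]:
            best = (gap, d_h, d_p, float(z))
    if best is None:
        raise ValueError("no z level with voxels in both tracts")
    _, d_h, d_p, z = best
    return DeviationMeasurement(d_h=d_h, d_p=d_p,
                                id_value=deviation_index(d_h, d_p),
                                z_level_mm=z)


def ellipse_area(d1_mm: float, d2_mm: float) -> float:
    """Planar area from two orthogonal diameters: pi * d1 * d2 / 4 (mm^2)."""
    if d1_mm <= 0 or d2_mm <= 0:
        raise ValueError("diameters must be positive")
    return np.pi * d1_mm * d2_mm / 4.0
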