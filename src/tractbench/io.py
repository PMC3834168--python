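"""File formats and reproducibility plumbing.

Volumes are NIfTI-1, gradient tables FSL-style bval/bvec whitespace text
(bvec has one row per axis), streamlines TrackVis .trk. Voxel indices are
0-based; world coordinates come from the NIfTI affine; streamlines are kept
in world millimetres in memory and converted at the .trk boundary.
"""

from __future__ import annotations

import json
import logging
import sys

import nibabel as nib
import numpy as np
import yaml

from .dwi import DWIVolume, GradientTable
from .fact import StreamlineSet

log = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


def read_gradient_table(bval_path, bvec_path) -> GradientTable:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T          # ambiguous; FSL convention is row-per-axis
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise FormatError(f"cannot interpret bvec shape {bvecs.shape}")
    dwi = bvals > 0
    norms = np.linalg.norm(bvecs[dwi], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        log.warning("renormalising %d bvec rows off unit length by > 1e-3",
                    int((np.abs(norms - 1.0) > 1e-3).sum()))
    bvecs = bvecs.copy()
    bvecs[dwi] /= norms[:, None]
    return GradientTable(bvals, bvecs)


def write_gradient_table(gtab: GradientTable, bval_path, bvec_path):
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.8f")


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    try:
        img = nib.load(str(nifti_path))
    except Exception as e:                      # unreadable header
        raise FormatError(f"cannot read {nifti_path}: {e}") from e
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError("DWI NIfTI must be 4D")
    gtab = read_gradient_table(bval_path, bvec_path)
    if data.shape[3] != len(gtab):
        raise FormatError(
            f"{data.shape[3]} volumes but {len(gtab)} gradient entries"
        )
    return DWIVolume(signal=np.clip(data, 0, None), affine=img.affine,
                     gradients=gtab)


def write_dwi(dwi: DWIVolume, nifti_path, bval_path=None, bvec_path=None):
    # float64 so a simulate -> write -> read round trip is bit-identical
    nib.Nifti1Image(dwi.signal, dwi.affine).to_filename(str(nifti_path))
    if bval_path is not None:
        write_gradient_table(dwi.gradients, bval_path, bvec_path)


def write_volume(data: np.ndarray, affine: np.ndarray, path):
    arr = data.astype(np.float32) if data.dtype != bool \
        else data.astype(np.uint8)
    nib.Nifti1Image(arr, affine).to_filename(str(path))


def read_volume(path) -> tuple:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_streamlines(sset: StreamlineSet, path, shape=None):
    """TrackVis .trk with voxel size and dimensions recorded in the header."""
    if sset.affine is None:
        raise ValueError("streamline set has no affine")
    affine = sset.affine
    header = {}
    if shape is not None:
        header["dimensions"] = np.asarray(shape, dtype=np.int16)
    header["voxel_sizes"] = np.sqrt((affine[:3, :3] ** 2).sum(axis=0)) \
        .astype(np.float32)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in sset.streamlines],
        affine_to_rasmm=np.eye(4),   # points already in world mm
    )
    nib.streamlines.save(nib.streamlines.TrkFile(tractogram, header),
                         str(path))


def read_streamlines(path) -> StreamlineSet:
    trk = nib.streamlines.load(str(path))
    out = StreamlineSet(affine=np.eye(4))
    for i, s in enumerate(trk.tractogram.streamlines):
        out.streamlines.append(np.asarray(s, dtype=float))
        out.seed_ids.append(i)
    return out


def write_streamlines_text(sset: StreamlineSet, path):
    """Plain-text dump: one line per point, blank line between streamlines."""
    with open(path, "w") as f:
        for s in sset.streamlines:
            for p in s:
                f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            f.write("\n")


def save_config(config: dict, path):
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def write_manifest(path, config: dict, seed: int):
    """Record everything needed to re-execute a run bit-identically."""
    manifest = {
        "config": config,
        "seed": int(seed),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "nibabel": nib.__version__,
        },
    }
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True, default=str)
    return manifest
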