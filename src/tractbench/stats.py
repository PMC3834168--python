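"""Group-level statistics and phantom scoring.

Ships the 17-patient clinical reference table (WHO grade, motor impairment,
planar tumour area, index of deviation, and ipsilateral FA/MD/AD/RD in
1e-3 mm^2/s) and implements the statistical layer applied to it: column
summaries, Pearson correlation, paired t-tests with Bonferroni correction,
and the lambda chart (per-patient RD vs AD against contralateral
mean +- 2 SD bands). Only the contralateral summary values are available
(FA 0.51 +- 0.15, MD 0.67 +- 0.03, AD 1.08 +- 0.16, RD 0.46 +- 0.08);
per-patient contralateral values were never published, so paired-test
behaviour is validated on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .fact import StreamlineSet

#: contralateral (healthy-side) group summaries: metric -> (mean, sd)
CONTRALATERAL_SUMMARY = {
    "fa": (0.51, 0.15),
    "md": (0.67, 0.03),
    "ad": (1.08, 0.16),
    "rd": (0.46, 0.08),
}

METRIC_COLUMNS = ("planar_area_mm2", "deviation_index", "fa", "md", "ad",
                  "rd")


def load_reference_table() -> pd.DataFrame:
    """The packaged 17-patient table (one row per patient)."""
    with resources.files("tractbench.data").joinpath("table2.csv").open() as f:
        df = pd.read_csv(f)
    if len(df) != 17:
        raise RuntimeError("reference table must have 17 rows")
    if not df["who_grade"].isin(["II", "III"]).all():
        raise RuntimeError("WHO grade must be II or III")
    if not df["deviation_index"].between(0, 1).all():
        raise RuntimeError("deviation index must lie in [0, 1]")
    return df


def summarize(records: pd.DataFrame,
              columns=METRIC_COLUMNS) -> pd.DataFrame:
    """Per-column mean and sample SD (n-1 denominator)."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    return pd.DataFrame({
        "mean": records[list(columns)].mean(),
        "sd": records[list(columns)].std(ddof=1),
    })


def pearson(x, y) -> tuple:
    """Pearson r with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_t_bonferroni(path_values: dict, contra_values: dict,
                        n_tests: int = 4) -> pd.DataFrame:
    """Paired t-test per metric with Bonferroni-corrected p-values.

    The family size defaults to 4 (FA, MD, AD, RD).
    """
    rows = {}
    for name, x in path_values.items():
        y = np.asarray(contra_values[name], dtype=float)
        x = np.asarray(x, dtype=float)
        if len(x) != len(y) or len(x) < 2:
            raise ValueError("need equal-length paired samples, n >= 2")
        d = x - y
        if np.std(d, ddof=1) == 0:
            if np.all(d == 0):      # identical pairs: no effect, no evidence
                rows[name] = {"t": 0.0, "p_uncorr": 1.0, "p_corr": 1.0}
                continue
            raise ValueError(f"zero-variance differences for {name}")
        t, p = sps.ttest_rel(x, y)
        rows[name] = {"t": float(t), "p_uncorr": float(p),
                      "p_corr": min(1.0, n_tests * float(p))}
    return pd.DataFrame(rows).T


@dataclass
class LambdaChartData:
    """Per-patient (RD, AD) points against contralateral +-2 SD bands."""

    rd: np.ndarray
    ad: np.ndarray
    patient: np.ndarray
    rd_band: tuple              # (lo, hi) = mean -+ 2 SD
    ad_band: tuple
    rd_outside: np.ndarray      # -1 below band, 0 inside, +1 above
    ad_outside: np.ndarray


def lambda_chart(records: pd.DataFrame,
                 contra_summary: dict = CONTRALATERAL_SUMMARY
                 ) -> LambdaChartData:
    """Classify each patient against the contralateral mean +- 2 SD bands."""
    rd_m, rd_s = contra_summary["rd"]
    ad_m, ad_s = contra_summary["ad"]
    rd_band = (rd_m - 2 * rd_s, rd_m + 2 * rd_s)
    ad_band = (ad_m - 2 * ad_s, ad_m + 2 * ad_s)

    def flag(v, band):
        return np.where(v < band[0], -1, np.where(v > band[1], 1, 0))

    rd = records["rd"].to_numpy(dtype=float)
    ad = records["ad"].to_numpy(dtype=float)
    return LambdaChartData(
        rd=rd, ad=ad, patient=records["patient"].to_numpy(),
        rd_band=rd_band, ad_band=ad_band,
        rd_outside=flag(rd, rd_band), ad_outside=flag(ad, ad_band),
    )


# ---------------------------------------------------------------------------
# phantom scoring


@dataclass
class BundleScore:
    coverage: float            # fraction of centerline voxels reached
    false_positive: float      # fraction of output points off-truth/wrong arm


def _output_mask(result, shape, affine) -> np.ndarray:
    if isinstance(result, StreamlineSet):
        return result.visited_mask(shape, affine)
    return np.asarray(result, dtype=bool)


def phantom_score(result, gt, dilate_vox: int = 1) -> dict:
    """Score tracking output against phantom ground truth.

    Returns per-bundle BundleScore plus summary keys:

    * ``coverage``: fraction of a bundle's centerline voxels within
      ``dilate_vox`` voxels of the output;
    * ``false_positive``: fraction of output voxels (restricted to the
      bundle's axial slab) outside the dilated union of all bundle masks;
    * ``crossing_jumps(out_a, out_b)`` is exposed separately via
      :func:`count_cross_bundle_jumps`.
    """
    shape, affine = gt.shape, gt.affine
    out_mask = _output_mask(result, shape, affine)
    union = gt.bundle_union()
    union_dil = ndimage.binary_dilation(union, iterations=dilate_vox)
    out_dil = ndimage.binary_dilation(out_mask, iterations=dilate_vox)
    scores = {}
    for name, bt in gt.bundles.items():
        cl = bt.centerline_mask
        cov = float((cl & out_dil).sum() / max(1, cl.sum()))
        # restrict FP assessment to the slab (z rows) this bundle occupies
        zsel = np.zeros(shape, dtype=bool)
        zs = np.unique(np.argwhere(bt.mask)[:, 2])
        zsel[:, :, zs] = True
        n_out = (out_mask & zsel).sum()
        fp = float(((out_mask & zsel) & ~union_dil).sum() / max(1, n_out))
        scores[name] = BundleScore(coverage=cov, false_positive=fp)
    return scores


def n_branches_found(scores: dict, branch_names, threshold: float = 0.5
                     ) -> int:
    """Count split branches whose centerline coverage exceeds threshold."""
    return int(sum(scores[n].coverage > threshold for n in branch_names))


def count_cross_bundle_jumps(result, gt, name_a: str, name_b: str,
                             dilate_vox: int = 1) -> int:
    """Number of streamlines entering exclusive territory of both crossing
    bundles (i.e. jumping from one bundle onto the other)."""
    a = gt.bundles[name_a].mask
    b = gt.bundles[name_b].mask
    a_dil = ndimage.binary_dilation(a, iterations=dilate_vox)
    b_dil = ndimage.binary_dilation(b, iterations=dilate_vox)
    only_a = a & ~b_dil
    only_b = b & ~a_dil
    inv = np.linalg.inv(gt.affine)
    shape = np.array(gt.shape)
    n = 0
    for line in result:
        idx = np.round(line @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        hit = np.zeros(gt.shape, dtype=bool)
        hit[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        if np.any(hit & only_a) and np.any(hit & only_b):
            n += 1
    return n
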