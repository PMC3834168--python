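"""Synthetic DWI phantoms with known fibre geometry and glioma-like lesions.

The standard phantom packs the three classic tractography challenges into one
volume, each in its own axial slab:

* a ~90 degree crossing of two straight bundles with different FA (high ~0.8
  vs low ~0.5, set via their axial/radial diffusivities),
* one bundle with a sharp (90 degree) bend,
* one major bundle splitting into three daughter branches.

Bundles are tubes around polyline centerlines; per-voxel volume fractions come
from 3x3x3 subvoxel sampling. The forward model is a multi-tensor mixture per
voxel plus an isotropic background compartment, with optional Rician noise
(magnitude MR). Lesions rescale the local axial/radial diffusivities with a
smooth Gaussian falloff and can displace bundle midlines, emulating oedema
(AD/RD up), compression (AD/RD down) and mass effect (tract deviation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .dwi import BSCALE, DWIVolume, GradientTable, make_gradient_table

#: isotropic background diffusivity, 1e-3 mm^2/s (order of grey matter)
BACKGROUND_ADC = 0.8

#: diffusivities (1e-3 mm^2/s) giving FA ~0.77 ("high") and ~0.49 ("low")
HIGH_FA_AD, HIGH_FA_RD = 1.43, 0.29
LOW_FA_AD, LOW_FA_RD = 1.05, 0.45


@dataclass(frozen=True)
class BundleGeometry:
    """A tube of radius ``radius_mm`` around a polyline centerline (world mm)."""

    name: str
    centerline: np.ndarray          # (K, 3) control points, world mm
    radius_mm: float
    target_ad: float                # 1e-3 mm^2/s
    target_rd: float
    endpoint_labels: tuple          # (roi_at_start, roi_at_end)

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if len(pts) < 2:
            raise ValueError("centerline needs >= 2 control points")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if not (self.target_ad >= self.target_rd > 0):
            raise ValueError("need target_ad >= target_rd > 0")
        object.__setattr__(self, "centerline", pts)


@dataclass(frozen=True)
class LesionSpec:
    """Focal diffusivity change plus optional bundle displacement.

    ``ad_multiplier``/``rd_multiplier`` scale the local bundle diffusivities
    at the lesion center, decaying as exp(-d^2 / (2 sigma^2)) with
    sigma = radius_mm / 2. ``displacement_mm`` shifts bundle midlines with the
    same Gaussian falloff (full shift where a centerline passes through the
    center).
    """

    center: np.ndarray
    radius_mm: float
    ad_multiplier: float = 1.0
    rd_multiplier: float = 1.0
    displacement_mm: np.ndarray = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.ad_multiplier <= 0 or self.rd_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float))
        object.__setattr__(self, "displacement_mm",
                           np.asarray(self.displacement_mm, dtype=float))


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one synthetic acquisition."""

    shape: tuple                    # grid voxels (nx, ny, nz)
    voxel_mm: float
    bundles: tuple                  # of BundleGeometry
    lesions: tuple = ()             # of LesionSpec
    background_adc: float = BACKGROUND_ADC
    snr: float | None = 20.0
    rng_seed: int = 0
    #: endpoint ROIs match the bundle radius so seeds stay inside the tube
    roi_radius_mm: float = 2.5

    def __post_init__(self):
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive or None")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world affine centred so the midsagittal plane is x = 0."""
        nx, ny, nz = self.shape
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_mm
        a[0, 3] = -self.voxel_mm * (nx - 1) / 2.0
        a[1, 3] = -self.voxel_mm * (ny - 1) / 2.0
        a[2, 3] = self.voxel_mm / 2.0   # z starts just above 0
        return a


@dataclass
class BundleTruth:
    """Rasterized ground truth for one bundle."""

    name: str
    mask: np.ndarray                # voxels with nonzero fraction
    fraction: np.ndarray            # normalised volume fraction
    tangent: np.ndarray             # (X, Y, Z, 3) local unit tangent
    ad: np.ndarray                  # voxelwise diffusivities after lesions
    rd: np.ndarray
    centerline_mask: np.ndarray     # voxels the centerline passes through
    centerline_points: np.ndarray   # densified centerline, world mm
    endpoint_labels: tuple


@dataclass
class GroundTruth:
    """Voxelwise truth for all bundles plus endpoint ROI masks."""

    bundles: dict                   # name -> BundleTruth
    rois: dict                      # label -> bool mask
    affine: np.ndarray
    shape: tuple

    def bundle_union(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for b in self.bundles.values():
            out |= b.mask
        return out

    def background_fraction(self) -> np.ndarray:
        total = np.zeros(self.shape)
        for b in self.bundles.values():
            total += b.fraction
        return 1.0 - total


def _densify(centerline: np.ndarray, step: float = 0.5) -> tuple:
    """Resample a control polyline at ~step mm; returns (points, tangents)."""
    pts = [centerline[0]]
    for a, b in zip(centerline[:-1], centerline[1:]):
        seg = b - a
        n = max(1, int(np.ceil(np.linalg.norm(seg) / step)))
        for i in range(1, n + 1):
            pts.append(a + seg * (i / n))
    pts = np.asarray(pts)
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return pts, tang


def _lesion_weight(points: np.ndarray, lesion: LesionSpec) -> np.ndarray:
    d2 = ((points - lesion.center) ** 2).sum(axis=-1)
    sigma = lesion.radius_mm / 2.0
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _arc(center_xy, radius, a0, a1, z, n=12):
    th = np.linspace(a0, a1, n)
    return np.column_stack([
        center_xy[0] + radius * np.cos(th),
        center_xy[1] + radius * np.sin(th),
        np.full(n, z),
    ])


def rasterize(spec: PhantomSpec) -> GroundTruth:
    """Voxelise all bundles: fractions by 3^3 subvoxel sampling, tangents from
    the nearest centerline point, diffusivities after lesion multipliers,
    fractions normalised so their per-voxel sum is <= 1."""
    nx, ny, nz = spec.shape
    affine = spec.affine
    v = spec.voxel_mm
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    centers = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3) @ \
        affine[:3, :3].T + affine[:3, 3]
    off1 = np.array([-v / 3.0, 0.0, v / 3.0])
    ox, oy, oz = np.meshgrid(off1, off1, off1, indexing="ij")
    offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)   # (27, 3)
    sub = centers[:, None, :] + offsets[None, :, :]            # (V, 27, 3)
    sub_flat = sub.reshape(-1, 3)

    bundles = {}
    fractions = []
    for b in spec.bundles:
        pts, tang = _densify(b.centerline)
        # mass effect: displace the densified centerline
        for les in spec.lesions:
            disp = np.asarray(les.displacement_mm, dtype=float)
            if np.any(disp != 0):
                w = _lesion_weight(pts, les)
                pts = pts + w[:, None] * disp
        tree = cKDTree(pts)
        dist, idx = tree.query(sub_flat, workers=-1)
        inside = (dist <= b.radius_mm).reshape(len(centers), 27)
        frac = inside.mean(axis=1).reshape(nx, ny, nz)
        dist_c, idx_c = tree.query(centers, workers=-1)
        tangent = np.zeros((nx, ny, nz, 3))
        tangent.reshape(-1, 3)[:] = tang[idx_c]
        mask = frac > 0
        tangent[~mask] = 0.0
        # voxelwise diffusivities with lesion falloff
        ad = np.where(mask, b.target_ad, 0.0)
        rd = np.where(mask, b.target_rd, 0.0)
        for les in spec.lesions:
            w = _lesion_weight(centers, les).reshape(nx, ny, nz)
            ad = ad * (1.0 + (les.ad_multiplier - 1.0) * w)
            rd = rd * (1.0 + (les.rd_multiplier - 1.0) * w)
        cl_mask = np.zeros(spec.shape, dtype=bool)
        inv = np.linalg.inv(affine)
        cl_idx = np.round(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((cl_idx >= 0) & (cl_idx < np.array(spec.shape)), axis=1)
        cl_idx = cl_idx[ok]
        cl_mask[cl_idx[:, 0], cl_idx[:, 1], cl_idx[:, 2]] = True
        bundles[b.name] = BundleTruth(
            name=b.name, mask=mask, fraction=frac, tangent=tangent,
            ad=ad, rd=rd, centerline_mask=cl_mask, centerline_points=pts,
            endpoint_labels=b.endpoint_labels,
        )
        fractions.append(frac)

    total = np.sum(fractions, axis=0) if fractions else np.zeros(spec.shape)
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-12), 1.0)
    for bt in bundles.values():
        bt.fraction = bt.fraction * scale

    rois = {}
    for b in spec.bundles:
        pts = bundles[b.name].centerline_points
        for label, p in zip(b.endpoint_labels, (pts[0], pts[-1])):
            if label in rois:
                continue
            d = np.linalg.norm(centers - p, axis=1).reshape(nx, ny, nz)
            rois[label] = d <= spec.roi_radius_mm
    return GroundTruth(bundles=bundles, rois=rois, affine=affine,
                       shape=spec.shape)


def simulate_dwi(spec: PhantomSpec, gt: GroundTruth,
                 gradients: GradientTable | None = None,
                 rng_seed: int | None = None) -> DWIVolume:
    """Multi-tensor forward model with optional Rician noise.

    Per voxel: S(g)/S0 = sum_i f_i exp(-b (rd_i + (ad_i - rd_i)(g.t_i)^2))
    + f_bg exp(-b d_bg). Rician noise: S -> sqrt((S + e1)^2 + e2^2),
    e ~ N(0, S0/snr). S0 = 1 everywhere.
    """
    if gradients is None:
        gradients = make_gradient_table()
    if gt.shape != spec.shape:
        raise ValueError("spec/ground-truth grid mismatch")
    b = gradients.bvals * BSCALE                     # per-gradient, scaled
    g = gradients.bvecs
    nvol = len(gradients)
    signal = np.zeros(spec.shape + (nvol,))
    # isotropic background for the non-bundle fraction
    bg = np.exp(-b * spec.background_adc)            # (N,)
    signal += gt.background_fraction()[..., None] * bg
    for bt in gt.bundles.values():
        m = bt.mask
        if not np.any(m):
            continue
        t = bt.tangent[m]                            # (V, 3)
        cos2 = (t @ g.T) ** 2                        # (V, N)
        ad = bt.ad[m][:, None]
        rd = bt.rd[m][:, None]
        att = np.exp(-b[None, :] * (rd + (ad - rd) * cos2))
        signal[m] += bt.fraction[m][:, None] * att
    if spec.snr is not None:
        seed = spec.rng_seed if rng_seed is None else rng_seed
        rng = np.random.default_rng(seed)
        sigma = 1.0 / spec.snr
        e1 = rng.normal(0.0, sigma, signal.shape)
        e2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2 ** 2)
    return DWIVolume(signal=signal, affine=spec.affine, gradients=gradients)


def apply_lesion(spec: PhantomSpec, gt: GroundTruth,
                 lesion: LesionSpec) -> tuple:
    """Add a lesion and re-rasterize. Identity lesion leaves output equal to
    the input (up to re-rasterization, which is deterministic)."""
    extent = np.array(spec.shape) * spec.voxel_mm
    if lesion.radius_mm >= extent.min():
        raise ValueError("lesion radius exceeds grid extent")
    new_spec = replace(spec, lesions=spec.lesions + (lesion,))
    return new_spec, rasterize(new_spec)


def rician_mean(amplitude: np.ndarray, sigma: float) -> np.ndarray:
    """Analytic first moment of a Rician variate with the given underlying
    amplitude and Gaussian channel noise sigma."""
    from scipy.special import ive
    a = np.asarray(amplitude, dtype=float)
    x = -a ** 2 / (2.0 * sigma ** 2)
    # sqrt(pi/2) L_{1/2}(x); the exp of the Laguerre identity cancels
    # against the scaling of ive
    l_half = (1.0 - x) * ive(0, -x / 2.0) - x * ive(1, -x / 2.0)
    return sigma * np.sqrt(np.pi / 2.0) * l_half


def calibrated_lesion_targets(ad_obs: float, rd_obs: float, snr: float,
                              gradients: GradientTable | None = None,
                              n_iter: int = 4, n_rep: int = 2000) -> tuple:
    """Generating (AD, RD) whose *fitted* metrics match the observed pair.

    Magnitude MR noise shrinks fitted diffusivities (the Rician floor props
    up strongly attenuated signals, and the log-domain fit adds further
    shrinkage), and published patient metrics are themselves fits of noisy
    magnitude data. To emulate a lesion whose measured metrics equal a
    published regime, the generating diffusivities must be pre-corrected:
    this solves the fixed point of the mean fitted metric, estimated by a
    deterministic internal Monte-Carlo of the full noise-and-fit chain.
    """
    from .tensor import eigendecompose, fit_tensor, mean_axial_radial

    if gradients is None:
        gradients = make_gradient_table()
    sigma = 1.0 / snr
    rng = np.random.default_rng(20160415)     # internal, fixed

    def fitted(ad, rd):
        tang = np.array([1.0, 0.0, 0.0])
        cos2 = (gradients.bvecs @ tang) ** 2
        b = gradients.bvals * BSCALE
        s = np.exp(-b * (rd + (ad - rd) * cos2))
        e1 = rng.normal(0.0, sigma, (n_rep, len(s)))
        e2 = rng.normal(0.0, sigma, (n_rep, len(s)))
        noisy = np.sqrt((s + e1) ** 2 + e2 ** 2)
        vol = DWIVolume(noisy[None, None], np.eye(4), gradients)
        eigs = eigendecompose(fit_tensor(vol))
        _, ad_f, rd_f = mean_axial_radial(eigs.evals)
        return float(ad_f.mean()), float(rd_f.mean())

    ad_gen, rd_gen = ad_obs, rd_obs
    for _ in range(n_iter):
        ad_f, rd_f = fitted(ad_gen, rd_gen)
        ad_gen += ad_obs - ad_f
        rd_gen += rd_obs - rd_f
        rd_gen = min(max(rd_gen, 1e-3), ad_gen)
    return ad_gen, rd_gen


def make_standard_phantom(voxel_mm: float = 2.0, rng_seed: int = 0,
                          snr: float | None = 20.0) -> tuple:
    """The three-challenge phantom: crossing (different FA), sharp bend,
    1-into-3 split; each geometry in its own axial slab.

    The split is represented as three overlapping bundles sharing the trunk,
    so per-branch ground truth (and branch-level scoring) is well defined;
    trunk voxels carry three parallel tangents with fractions 1/3 each.
    """
    r = 2.5
    z_cross, z_bend, z_split = 5.0, 11.0, 17.0
    bundles = (
        BundleGeometry("cross_high",
                       [(-28, 0, z_cross), (28, 0, z_cross)], r,
                       HIGH_FA_AD, HIGH_FA_RD, ("CH_A", "CH_B")),
        BundleGeometry("cross_low",
                       [(0, -28, z_cross), (0, 28, z_cross)], r,
                       LOW_FA_AD, LOW_FA_RD, ("CL_A", "CL_B")),
        BundleGeometry("bend",
                       np.vstack([[(-24, -24, z_bend)],
                                  _arc((-0.5, -13.5), 10.5, -np.pi / 2, 0.0,
                                       z_bend),
                                  [(10, 24, z_bend)]]), r,
                       HIGH_FA_AD, HIGH_FA_RD, ("BD_A", "BD_B")),
        BundleGeometry("split_1",
                       [(-28, 0, z_split), (-4, 0, z_split),
                        (12, -26, z_split)], r,
                       HIGH_FA_AD, HIGH_FA_RD, ("SP_A", "SP1_B")),
        BundleGeometry("split_2",
                       [(-28, 0, z_split), (28, 0, z_split)], r,
                       HIGH_FA_AD, HIGH_FA_RD, ("SP_A", "SP2_B")),
        BundleGeometry("split_3",
                       [(-28, 0, z_split), (-4, 0, z_split),
                        (12, 26, z_split)], r,
                       HIGH_FA_AD, HIGH_FA_RD, ("SP_A", "SP3_B")),
    )
    nvox = int(round(64.0 / voxel_mm))
    nz = int(round(24.0 / voxel_mm))
    spec = PhantomSpec(shape=(nvox, nvox, nz), voxel_mm=voxel_mm,
                       bundles=bundles, snr=snr, rng_seed=rng_seed)
    return spec, rasterize(spec)


def make_mirrored_phantom(voxel_mm: float = 2.0, rng_seed: int = 0,
                          snr: float | None = 20.0,
                          x_offset_mm: float = 16.0,
                          ad: float = 1.08, rd: float = 0.46) -> tuple:
    """Two mirror-image straight bundles running craniocaudally (along z)
    at x = +-x_offset, emulating the corticospinal tracts about the
    midsagittal plane x = 0, so deviation can be read out per axial level.
    Defaults use the contralateral normal diffusivities (AD 1.08, RD 0.46).
    """
    nvox = int(round(64.0 / voxel_mm))
    ny = int(round(16.0 / voxel_mm))
    nz = int(round(56.0 / voxel_mm))
    z_lo, z_hi = 3.0, nz * voxel_mm - 3.0
    bundles = (
        BundleGeometry("left", [(-x_offset_mm, 0, z_lo),
                                (-x_offset_mm, 0, z_hi)], 2.5,
                       ad, rd, ("L_A", "L_B")),
        BundleGeometry("right", [(x_offset_mm, 0, z_lo),
                                 (x_offset_mm, 0, z_hi)], 2.5,
                       ad, rd, ("R_A", "R_B")),
    )
    spec = PhantomSpec(shape=(nvox, ny, nz), voxel_mm=voxel_mm,
                       bundles=bundles, snr=snr, rng_seed=rng_seed)
    return spec, rasterize(spec)


def make_single_bundle_phantom(voxel_mm: float = 2.0, rng_seed: int = 0,
                               snr: float | None = None,
                               ad: float = HIGH_FA_AD,
                               rd: float = HIGH_FA_RD,
                               extent_mm: float = 40.0) -> tuple:
    """One straight bundle along x, for oracles and sampler tests."""
    n = int(round(extent_mm / voxel_mm))
    nz = max(4, int(round(16.0 / voxel_mm)))
    half = extent_mm / 2.0 - voxel_mm
    z = voxel_mm * (nz // 2) + voxel_mm / 2.0
    bundles = (BundleGeometry("bundle", [(-half, 0, z), (half, 0, z)], 2.5,
                              ad, rd, ("A", "B")),)
    spec = PhantomSpec(shape=(n, n, nz), voxel_mm=voxel_mm, bundles=bundles,
                       snr=snr, rng_seed=rng_seed)
    return spec, rasterize(spec)
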