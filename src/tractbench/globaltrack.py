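"""Global tractography: simulated annealing over bonded fibre segments.

Fibres are modelled as a dynamic set of short oriented cylinder segments
(default length 3 mm, width 1 mm). A configuration is scored against the
measured diffusion data as a whole, and optimised by a Metropolis-Hastings
sampler under an exponentially decreasing temperature; at high temperature
segments are born diffusely, and as the temperature drops they align with
the data and polymerise into bonded chains, which are the reconstructed
fibres. Crossings are resolved because differently oriented segments can
coexist in one voxel while the curvature penalty keeps chains from jumping
between the two populations.

Energy model (a reimplementation; validated behaviourally on phantoms):

* data term: E_data = sum_{voxels, b>0 gradients} (M - P)^2, where
  M is the per-voxel anisotropic signal (b0-normalised signal minus its
  per-voxel minimum over gradients) and P the configuration's prediction.
  The unnormalised sum puts the cost of a ~20 degree segment
  misorientation a few multiples above the stop temperature, so the final
  cooling phase actually locks orientations in.
  Each segment deposits w/3 * exp(-b c (g.n)^2) at three quadrature points
  along its axis into the voxels containing them.
* bond term: for every bonded endpoint pair,
  spring * d^2 + curvature_penalty * (1 + u_a . u_b) - bond_reward,
  with d the endpoint gap and u the outward axis directions (collinear
  continuation gives u_a . u_b = -1, i.e. zero curvature cost). Bonding
  is rewarded when the geometry is good and penalised at sharp turns:
  at 90 degrees the curvature cost exceeds the reward by design, which is
  what suppresses cross-bundle chains at fibre crossings.

Birth/death moves use the reversible-jump ratio for a Poisson reference
measure with a configurable reference count, so the sampler has a proper
stationary distribution at fixed temperature (testable by a detailed-balance
audit on an enumerable toy state space).

The segment weight w defaults to 1/4 of the mask-averaged anisotropic
signal component; it behaves like an FA threshold (higher weight suppresses
segments in weakly anisotropic regions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .dwi import BSCALE, DWIVolume
from .fact import StreamlineSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GTParams:
    segment_weight: float | None = None    # None: 1/4 mean anisotropic signal
    n_iterations: int = 400_000
    t_start: float = 0.1
    t_stop: float = 0.001
    half_length_mm: float = 1.5            # cylinder length 3 mm
    width_mm: float = 1.0
    kernel_diffusivity: float = 1.0        # 1e-3 mm^2/s
    bond_radius_mm: float = 1.5
    spring: float = 0.006                  # per mm^2 endpoint gap
    curvature_penalty: float = 0.6
    bond_reward: float = 0.03
    proposal_probs: tuple = (0.225, 0.225, 0.3, 0.25)  # birth/death/move/bond
    move_sigma_mm: float = 0.4
    rotate_sigma: float = 0.15
    reference_count: float = 100.0         # Poisson reference measure mass
    #: birth orientations: mixture of uniform and Watson around the local
    #: principal eigenvector; the proposal density enters the acceptance
    #: ratio exactly, so this only speeds mixing, it does not bias the
    #: stationary distribution.
    birth_align_frac: float = 0.5
    birth_kappa: float = 8.0
    min_chain_segments: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        if not self.t_start > self.t_stop > 0:
            raise ValueError("need t_start > t_stop > 0")
        if abs(sum(self.proposal_probs) - 1.0) > 1e-9:
            raise ValueError("proposal probabilities must sum to 1")


class _IndexSet:
    """Set of ints with O(1) add/discard and uniform sampling."""

    def __init__(self):
        self.items = []
        self.pos = {}

    def __len__(self):
        return len(self.items)

    def __contains__(self, i):
        return i in self.pos

    def add(self, i):
        if i not in self.pos:
            self.pos[i] = len(self.items)
            self.items.append(i)

    def discard(self, i):
        p = self.pos.pop(i, None)
        if p is None:
            return
        last = self.items.pop()
        if p < len(self.items):
            self.items[p] = last
            self.pos[last] = p

    def sample(self, rng):
        return self.items[rng.integers(len(self.items))]


class SegmentConfiguration:
    """Dynamic set of bonded segments with incremental energy bookkeeping."""

    def __init__(self, shape, affine, gradients, mask, params: GTParams,
                 measured: np.ndarray | None = None,
                 v1grid: np.ndarray | None = None):
        self.shape = tuple(shape)
        self.affine = np.asarray(affine, dtype=float)
        self.inv = np.linalg.inv(self.affine)
        self.params = params
        self.mask = np.asarray(mask, dtype=bool)
        dw = gradients.bvals > 0
        self.gdirs = gradients.bvecs[dw]
        self.bc = gradients.bvals[dw] * BSCALE * params.kernel_diffusivity
        self.G = int(dw.sum())
        if measured is None:
            measured = np.zeros(self.shape + (self.G,))
        if measured.shape != self.shape + (self.G,):
            raise ValueError("measured anisotropic signal grid mismatch")
        self.M = measured
        self.P = np.zeros_like(self.M)
        self.weight = params.segment_weight if params.segment_weight else 1.0
        self.v1grid = v1grid                 # (X, Y, Z, 3) or None
        # Watson normalisation int exp(kappa t^2) dt over [0, 1]
        from scipy.special import hyp1f1
        self._watson_norm = float(hyp1f1(0.5, 1.5, params.birth_kappa))

        self.centers: list = []
        self.orients: list = []
        self.bonds: list = []        # per segment: [bond_ep0, bond_ep1]
        self.seg_dep: list = []      # per segment: dict voxel -> multiplicity
        self.seg_kvec: list = []
        self.alive = _IndexSet()
        self.free = _IndexSet()      # fully free (deletable) segments
        self._hash: dict = {}        # cell -> set of (seg, ep), free endpoints
        self.E_data = float((self.M ** 2).sum())
        self.E_bond = 0.0
        self.n_bonds = 0
        self.iteration = 0
        self.energy_history: list = []
        self._mask_vox = np.argwhere(self.mask)
        self.n_accepted = 0
        self.n_proposed = 0

    # -- geometry helpers ---------------------------------------------------

    def endpoint(self, i: int, ep: int) -> np.ndarray:
        s = 1.0 if ep == 1 else -1.0
        return self.centers[i] + s * self.params.half_length_mm * \
            self.orients[i]

    def _outward(self, i: int, ep: int) -> np.ndarray:
        return (1.0 if ep == 1 else -1.0) * self.orients[i]

    def _cell(self, pos) -> tuple:
        r = self.params.bond_radius_mm
        return (int(math.floor(pos[0] / r)), int(math.floor(pos[1] / r)),
                int(math.floor(pos[2] / r)))

    def _hash_add(self, i, ep):
        self._hash.setdefault(self._cell(self.endpoint(i, ep)),
                              set()).add((i, ep))

    def _hash_remove(self, i, ep):
        c = self._cell(self.endpoint(i, ep))
        s = self._hash.get(c)
        if s is not None:
            s.discard((i, ep))
            if not s:
                del self._hash[c]

    def _candidates(self, seg: int, pos: np.ndarray) -> list:
        """Free endpoints of other segments within the bond radius of pos."""
        r2 = self.params.bond_radius_mm ** 2
        cx, cy, cz = self._cell(pos)
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    s = self._hash.get((cx + dx, cy + dy, cz + dz))
                    if not s:
                        continue
                    for (j, ep) in s:
                        if j == seg:
                            continue
                        d = self.endpoint(j, ep) - pos
                        if float(d @ d) <= r2:
                            out.append((j, ep))
        return out

    # -- birth orientation proposal -----------------------------------------

    def _local_v1(self, vox):
        if self.v1grid is None:
            return None
        v1 = self.v1grid[vox[0], vox[1], vox[2]]
        n = np.linalg.norm(v1)
        return v1 / n if n > 1e-6 else None

    def orientation_density(self, orient: np.ndarray,
                            center: np.ndarray) -> float:
        """Birth-proposal orientation density w.r.t. the uniform measure."""
        vox = np.round(center @ self.inv[:3, :3].T
                       + self.inv[:3, 3]).astype(int)
        if np.any(vox < 0) or np.any(vox >= self.shape):
            return 1.0
        v1 = self._local_v1(vox)
        if v1 is None:
            return 1.0
        f = self.params.birth_align_frac
        t2 = float(orient @ v1) ** 2
        return (1.0 - f) + f * math.exp(self.params.birth_kappa * t2) / \
            self._watson_norm

    def draw_orientation(self, vox, rng) -> np.ndarray:
        """Uniform/Watson mixture around the local principal eigenvector."""
        v1 = self._local_v1(vox)
        k = self.params.birth_kappa
        if v1 is not None and rng.random() < self.params.birth_align_frac:
            for _ in range(500):      # rejection from the uniform envelope
                n = rng.normal(size=3)
                nn = np.linalg.norm(n)
                if nn < 1e-12:
                    continue
                n /= nn
                t2 = float(n @ v1) ** 2
                if rng.random() < math.exp(k * (t2 - 1.0)):
                    return n
        while True:
            n = rng.normal(size=3)
            nn = np.linalg.norm(n)
            if nn > 1e-12:
                return n / nn

    # -- signal bookkeeping -------------------------------------------------

    def _kernel(self, orient: np.ndarray) -> np.ndarray:
        cos2 = (self.gdirs @ orient) ** 2
        return (self.weight / 3.0) * np.exp(-self.bc * cos2)

    def _deposit(self, center, orient) -> dict:
        """Quadrature voxels (with multiplicity) for a segment."""
        dep = {}
        h = 0.6 * self.params.half_length_mm
        for t in (-h, 0.0, h):
            p = center + t * orient
            v = np.round(p @ self.inv[:3, :3].T + self.inv[:3, 3]).astype(int)
            if np.any(v < 0) or np.any(v >= self.shape):
                continue
            key = (int(v[0]), int(v[1]), int(v[2]))
            dep[key] = dep.get(key, 0) + 1
        return dep

    def _delta_data(self, dep: dict, kvec: np.ndarray,
                    sign: float) -> float:
        """Energy change for adding (sign=+1) / removing (sign=-1) deposits."""
        dE = 0.0
        for vox, m in dep.items():
            a = (sign * m) * kvec
            resid = self.P[vox] - self.M[vox]
            dE += float((a * (a + 2.0 * resid)).sum())
        return dE

    def _apply_deposit(self, dep: dict, kvec: np.ndarray, sign: float):
        for vox, m in dep.items():
            self.P[vox] += (sign * m) * kvec

    # -- bond energy --------------------------------------------------------

    def bond_energy(self, i, epi, j, epj) -> float:
        p = self.params
        d = self.endpoint(i, epi) - self.endpoint(j, epj)
        curv = 1.0 + float(self._outward(i, epi) @ self._outward(j, epj))
        return p.spring * float(d @ d) + p.curvature_penalty * curv \
            - p.bond_reward

    # -- direct construction (used by tests and audits) ---------------------

    def insert_segment(self, center, orient) -> int:
        """Insert a segment directly (bypassing the sampler)."""
        center = np.asarray(center, dtype=float)
        orient = np.asarray(orient, dtype=float)
        orient = orient / np.linalg.norm(orient)
        i = len(self.centers)
        dep = self._deposit(center, orient)
        kvec = self._kernel(orient)
        self.E_data += self._delta_data(dep, kvec, +1.0)
        self._apply_deposit(dep, kvec, +1.0)
        self.centers.append(center)
        self.orients.append(orient)
        self.bonds.append([None, None])
        self.seg_dep.append(dep)
        self.seg_kvec.append(kvec)
        self.alive.add(i)
        self.free.add(i)
        self._hash_add(i, 0)
        self._hash_add(i, 1)
        return i

    def _remove_segment(self, i: int):
        self.E_data += self._delta_data(self.seg_dep[i], self.seg_kvec[i],
                                        -1.0)
        self._apply_deposit(self.seg_dep[i], self.seg_kvec[i], -1.0)
        self._hash_remove(i, 0)
        self._hash_remove(i, 1)
        self.alive.discard(i)
        self.free.discard(i)
        self.centers[i] = None
        self.orients[i] = None
        self.seg_dep[i] = None
        self.seg_kvec[i] = None

    def create_bond(self, i, epi, j, epj):
        e = self.bond_energy(i, epi, j, epj)
        self.bonds[i][epi] = (j, epj)
        self.bonds[j][epj] = (i, epi)
        self._hash_remove(i, epi)
        self._hash_remove(j, epj)
        self.free.discard(i)
        self.free.discard(j)
        self.E_bond += e
        self.n_bonds += 1

    def break_bond(self, i, epi):
        j, epj = self.bonds[i][epi]
        e = self.bond_energy(i, epi, j, epj)
        self.bonds[i][epi] = None
        self.bonds[j][epj] = None
        self._hash_add(i, epi)
        self._hash_add(j, epj)
        if self.bonds[i][1 - epi] is None:
            self.free.add(i)
        if self.bonds[j][1 - epj] is None:
            self.free.add(j)
        self.E_bond -= e
        self.n_bonds -= 1

    # -- audits -------------------------------------------------------------

    def n_segments(self) -> int:
        return len(self.alive)

    def segment_arrays(self) -> tuple:
        idx = list(self.alive.items)
        c = np.array([self.centers[i] for i in idx]).reshape(-1, 3)
        o = np.array([self.orients[i] for i in idx]).reshape(-1, 3)
        return idx, c, o

    def energies_from_scratch(self) -> tuple:
        """(E_data, E_bond) recomputed from the current segment set."""
        P = np.zeros_like(self.P)
        for i in self.alive.items:
            for vox, m in self.seg_dep[i].items():
                P[vox] += m * self.seg_kvec[i]
        e_data = float(((self.M - P) ** 2).sum())
        e_bond = 0.0
        seen = set()
        for i in self.alive.items:
            for ep in (0, 1):
                b = self.bonds[i][ep]
                if b is None:
                    continue
                key = tuple(sorted([(i, ep), b]))
                if key in seen:
                    continue
                seen.add(key)
                e_bond += self.bond_energy(i, ep, b[0], b[1])
        return e_data, e_bond

    def audit(self, tol: float = 1e-6):
        ed, eb = self.energies_from_scratch()
        if abs(ed - self.E_data) > tol or abs(eb - self.E_bond) > tol:
            raise AssertionError(
                f"energy bookkeeping drifted: data {self.E_data} vs {ed}, "
                f"bond {self.E_bond} vs {eb}"
            )


def anisotropic_signal(dwi: DWIVolume, mask: np.ndarray) -> np.ndarray:
    """Per-voxel b0-normalised DWI signal minus its per-gradient minimum.

    Zero outside the mask; this is the data the segment model explains.
    """
    mask = np.asarray(mask, dtype=bool)
    dw = dwi.gradients.dwi_mask
    b0 = dwi.b0_mean()
    out = np.zeros(dwi.shape + (int(dw.sum()),))
    m = mask & (b0 > 0)
    snorm = dwi.signal[m][:, dw] / b0[m][:, None]
    out[m] = snorm - snorm.min(axis=1, keepdims=True)
    return out


def default_segment_weight(dwi: DWIVolume, mask: np.ndarray) -> float:
    """1/4 of the mask-averaged anisotropic signal component."""
    mask = np.asarray(mask, dtype=bool)
    dw = dwi.gradients.dwi_mask
    b0 = dwi.b0_mean()
    m = mask & (b0 > 0)
    snorm = dwi.signal[m][:, dw] / b0[m][:, None]
    aniso = snorm.mean(axis=1) - snorm.min(axis=1)
    return 0.25 * float(aniso.mean())


def predicted_signal(config: SegmentConfiguration, gradients) -> np.ndarray:
    """Full 4D predicted anisotropic signal over all gradient entries
    (b=0 entries get the unattenuated deposit w * overlap)."""
    b = gradients.bvals * BSCALE * config.params.kernel_diffusivity
    g = gradients.bvecs
    out = np.zeros(config.shape + (len(gradients),))
    for i in config.alive.items:
        n = config.orients[i]
        kvec = (config.weight / 3.0) * np.exp(-b * (g @ n) ** 2)
        for vox, m in config.seg_dep[i].items():
            out[vox] += m * kvec
    return out


def energy(config: SegmentConfiguration) -> tuple:
    """(E_data, E_bond) of the configuration, recomputed from scratch."""
    return config.energies_from_scratch()


def metropolis_step(config: SegmentConfiguration, params: GTParams,
                    temperature: float, rng: np.random.Generator) -> bool:
    """One proposal from {birth, death, move, bond-flip}; returns acceptance."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    config.n_proposed += 1
    p_birth, p_death, p_move, p_bond = params.proposal_probs
    u = rng.random()
    lam = params.reference_count
    T = temperature

    if u < p_birth:
        # --- birth: uniform position in a mask voxel, uniform orientation
        if len(config._mask_vox) == 0:
            return False
        vox = config._mask_vox[rng.integers(len(config._mask_vox))]
        offs = rng.uniform(-0.5, 0.5, 3)
        center = (vox + offs) @ config.affine[:3, :3].T + config.affine[:3, 3]
        orient = config.draw_orientation(vox, rng)
        dep = config._deposit(center, orient)
        kvec = config._kernel(orient)
        dE = config._delta_data(dep, kvec, +1.0)
        U = len(config.free)
        q_o = config.orientation_density(orient, center)
        alpha = math.exp(min(50.0, -dE / T)) * (p_death / p_birth) * \
            lam / ((U + 1) * q_o)
        if rng.random() < alpha:
            config.insert_segment(center, orient)
            config.n_accepted += 1
            return True
        return False

    if u < p_birth + p_death:
        # --- death of a fully free segment
        U = len(config.free)
        if U == 0:
            return False
        i = config.free.sample(rng)
        dE = config._delta_data(config.seg_dep[i], config.seg_kvec[i], -1.0)
        q_o = config.orientation_density(config.orients[i], config.centers[i])
        alpha = math.exp(min(50.0, -dE / T)) * (p_birth / p_death) * \
            U * q_o / lam
        if rng.random() < alpha:
            config._remove_segment(i)
            config.n_accepted += 1
            return True
        return False

    if u < p_birth + p_death + p_move:
        # --- rigid perturbation of one segment (symmetric proposal)
        if len(config.alive) == 0:
            return False
        i = config.alive.sample(rng)
        new_c = config.centers[i] + rng.normal(0.0, params.move_sigma_mm, 3)
        v = np.round(new_c @ config.inv[:3, :3].T
                     + config.inv[:3, 3]).astype(int)
        if np.any(v < 0) or np.any(v >= config.shape) or \
                not config.mask[v[0], v[1], v[2]]:
            return False
        new_o = config.orients[i] + rng.normal(0.0, params.rotate_sigma, 3)
        nrm = np.linalg.norm(new_o)
        if nrm < 1e-12:
            return False
        new_o /= nrm
        # bonded endpoints may not stretch beyond the bond radius
        old_c, old_o = config.centers[i], config.orients[i]
        old_bond_e = 0.0
        new_bond_e = 0.0
        r2 = params.bond_radius_mm ** 2
        for ep in (0, 1):
            b = config.bonds[i][ep]
            if b is None:
                continue
            old_bond_e += config.bond_energy(i, ep, b[0], b[1])
        config.centers[i], config.orients[i] = new_c, new_o
        stretched = False
        for ep in (0, 1):
            b = config.bonds[i][ep]
            if b is None:
                continue
            gap = config.endpoint(i, ep) - config.endpoint(b[0], b[1])
            if float(gap @ gap) > r2:
                stretched = True
                break
            new_bond_e += config.bond_energy(i, ep, b[0], b[1])
        config.centers[i], config.orients[i] = old_c, old_o
        if stretched:
            return False
        dep = config._deposit(new_c, new_o)
        kvec = config._kernel(new_o)
        dE = config._delta_data(config.seg_dep[i], config.seg_kvec[i], -1.0)
        # apply removal virtually for the add-side delta: combine exactly
        # by evaluating sequentially on P
        config._apply_deposit(config.seg_dep[i], config.seg_kvec[i], -1.0)
        dE += config._delta_data(dep, kvec, +1.0)
        dE += new_bond_e - old_bond_e
        alpha = math.exp(min(50.0, -dE / T))
        if rng.random() < alpha:
            for ep in (0, 1):
                if config.bonds[i][ep] is None:
                    config._hash_remove(i, ep)
            config.E_data += dE - (new_bond_e - old_bond_e)
            config.E_bond += new_bond_e - old_bond_e
            config._apply_deposit(dep, kvec, +1.0)
            config.centers[i], config.orients[i] = new_c, new_o
            config.seg_dep[i], config.seg_kvec[i] = dep, kvec
            for ep in (0, 1):
                if config.bonds[i][ep] is None:
                    config._hash_add(i, ep)
            config.n_accepted += 1
            return True
        # roll back the virtual removal
        config._apply_deposit(config.seg_dep[i], config.seg_kvec[i], +1.0)
        return False

    # --- bond flip
    if len(config.alive) == 0:
        return False
    i = config.alive.sample(rng)
    epi = int(rng.integers(2))
    bond = config.bonds[i][epi]
    if bond is not None:
        j, epj = bond
        dE = -config.bond_energy(i, epi, j, epj)
        # reverse move re-creates the bond: candidate counts after the break
        config.break_bond(i, epi)
        ki = len(config._candidates(i, config.endpoint(i, epi)))
        kj = len(config._candidates(j, config.endpoint(j, epj)))
        q_ratio = (1.0 / ki + 1.0 / kj) / 2.0
        alpha = math.exp(min(50.0, -dE / T)) * q_ratio
        if rng.random() < alpha:
            config.n_accepted += 1
            return True
        config.create_bond(i, epi, j, epj)
        return False
    pos = config.endpoint(i, epi)
    cands = config._candidates(i, pos)
    if not cands:
        return False
    ki = len(cands)
    j, epj = cands[rng.integers(ki)]
    kj = len(config._candidates(j, config.endpoint(j, epj)))
    dE = config.bond_energy(i, epi, j, epj)
    q_ratio = 2.0 / (1.0 / ki + 1.0 / kj)
    alpha = math.exp(min(50.0, -dE / T)) * q_ratio
    if rng.random() < alpha:
        config.create_bond(i, epi, j, epj)
        config.n_accepted += 1
        return True
    return False


def anneal(dwi: DWIVolume, mask: np.ndarray,
           params: GTParams = GTParams(),
           audit_interval: int | None = None) -> SegmentConfiguration:
    """Run the full cooling schedule T_k = t_start (t_stop/t_start)^(k/n).

    Returns the final configuration with its energy history (recorded every
    n/200 iterations). Reproducible for a fixed ``params.rng_seed``.
    """
    measured = anisotropic_signal(dwi, mask)
    if params.segment_weight is None:
        w = default_segment_weight(dwi, mask)
        params = GTParams(**{**params.__dict__, "segment_weight": w})
    from .tensor import eigendecompose, fit_tensor
    v1grid = eigendecompose(fit_tensor(dwi, mask)).v1
    config = SegmentConfiguration(dwi.shape, dwi.affine, dwi.gradients, mask,
                                  params, measured, v1grid=v1grid)
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_iterations
    if n < 1:
        return config
    ratio = params.t_stop / params.t_start
    record_every = max(1, n // 200)
    for k in range(n):
        T = params.t_start * ratio ** (k / n)
        metropolis_step(config, params, T, rng)
        config.iteration += 1
        if k % record_every == 0:
            config.energy_history.append(
                (k, T, config.E_data, config.E_bond, config.n_segments()))
        if audit_interval and (k + 1) % audit_interval == 0:
            config.audit()
    log.info("annealing done: %d segments, %d bonds, acceptance %.3f",
             config.n_segments(), config.n_bonds,
             config.n_accepted / max(1, config.n_proposed))
    return config


def extract_fibres(config: SegmentConfiguration,
                   min_chain_segments: int | None = None) -> StreamlineSet:
    """Trace maximal bond chains into polylines through segment endpoints.

    A chain of k segments yields k+1 points: the free endpoint of the first
    segment, the midpoints of each bonded endpoint pair, and the free
    endpoint of the last. Each endpoint has at most one bond, so chains are
    simple paths (cycles are emitted unclosed).
    """
    if min_chain_segments is None:
        min_chain_segments = config.params.min_chain_segments
    for i in config.alive.items:
        for ep in (0, 1):
            b = config.bonds[i][ep]
            if b is not None and config.bonds[b[0]][b[1]] != (i, ep):
                raise ValueError("bond symmetry violated")
    out = StreamlineSet(affine=config.affine)
    seen = set()
    for start in config.alive.items:
        if start in seen:
            continue
        # walk to one end of the chain (or back to start if a cycle)
        i, ep_in = start, 0
        visited = {start}
        while True:
            b = config.bonds[i][ep_in]
            if b is None:
                break
            nxt, ep = b
            if nxt in visited:   # cycle
                break
            visited.add(nxt)
            i, ep_in = nxt, 1 - ep
        # traverse from the far end through the chain
        chain = []
        ep_start = 1 - ep_in
        j, ep_out = i, ep_start
        while True:
            seen.add(j)
            chain.append((j, ep_out))
            b = config.bonds[j][ep_out]
            if b is None or b[0] in [c[0] for c in chain]:
                break
            j, ep_prev = b
            ep_out = 1 - ep_prev
        if len(chain) < min_chain_segments:
            continue
        pts = [config.endpoint(chain[0][0], 1 - chain[0][1])]
        for (a, ep_a), (b_, ep_b) in zip(chain[:-1], chain[1:]):
            pa = config.endpoint(a, ep_a)
            pb = config.endpoint(b_, 1 - ep_b)
            pts.append(0.5 * (pa + pb))
        last, ep_last = chain[-1]
        pts.append(config.endpoint(last, ep_last))
        out.streamlines.append(np.asarray(pts))
        out.seed_ids.append(chain[0][0])
    return out
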