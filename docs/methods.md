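# Methods

`tractbench` compares three fibre-tractography families — deterministic
streamlining (FACT), probabilistic maps of connectivity, and global
tractography by simulated annealing — on synthetic diffusion-weighted
phantoms with known fibre geometry, and implements the tract-level and
group-level measurements used to characterise gliomas' effect on the
corticospinal tract (CST). This note records the models, the parameter
choices, and the limits of what the synthetic experiments can show.

## Units and conventions

Diffusivities are expressed in 1e-3 mm²/s, b-values in s/mm², coordinates
in world millimetres through the NIfTI affine. Voxel indices are 0-based;
direction lookup during tracking is nearest-neighbour. The phantom affine
places the midsagittal plane at world x = 0, which is the reference plane
for all tract-deviation measures.

## Tensor model and scalar metrics

Signals follow the single-tensor model S(g) = S0 · exp(−b gᵀD g). The fit
is weighted log-linear least squares with weights S² (one pass, no
iteration); voxels with non-positive signal are flagged invalid rather than
failing the fit. Eigenvalues are sorted descending; negative values (which
magnitude noise can produce) are clipped to zero and counted. Eigenvector
sign is fixed by making the largest-magnitude component positive, so runs
are bit-reproducible.

Scalar metrics: MD = (λ1+λ2+λ3)/3, AD = λ1, RD = (λ2+λ3)/2, and

    FA = sqrt( 3 [(λ1−MD)² + (λ2−MD)² + (λ3−MD)²] / 2 (λ1²+λ2²+λ3²) ).

FA of the zero tensor is defined as 0 (isotropic limit; avoids 0/0).

A known property of this estimator chain on magnitude MR data is Rician
shrinkage: the noise floor props up strongly attenuated signals, so fitted
diffusivities are biased low — about −3% for MD at SNR 20 for normal white
matter values, growing to ~−7% in high-diffusivity (oedema-like) tissue
where the directional SNR drops toward 4. The package does not
bias-correct the fit itself (the study pipeline it reproduces did not);
instead, where a lesion must *measure* as a prescribed regime,
`phantom.calibrated_lesion_targets` pre-corrects the generating
diffusivities by solving the fixed point of the mean fitted metric with a
deterministic internal Monte-Carlo of the noise-and-fit chain. This
mirrors the fact that published patient metrics are themselves fits of
noisy magnitude data.

## Synthetic phantoms

The generator replaces both a physical crossing/bending/splitting phantom
and the patient cohort; no real data ships with the package.

**Geometry.** Bundles are tubes of radius 2.5 mm around polyline
centerlines, rasterized by 3×3×3 subvoxel sampling into per-voxel volume
fractions; per-voxel tangents come from the nearest centerline point, and
overlapping fractions are renormalised to sum ≤ 1. The standard phantom
(64×64×24 mm at 2 mm isotropic) stacks three challenges in separate axial
slabs:

* a ~90° crossing of two straight bundles with different anisotropy —
  AD/RD 1.43/0.29 (FA ≈ 0.77) against 1.05/0.45 (FA ≈ 0.49), values in the
  observed white-matter range;
* one bundle with a 90° bend (arc radius 10.5 mm);
* one trunk splitting into three daughters (±58° and straight), modelled
  as three overlapping tubes sharing the trunk so that per-branch ground
  truth is well defined.

Endpoint ROIs are spheres matching the bundle radius (2.5 mm), so seeds
stay inside the tube — seed spheres wider than the bundle leak into
background and blur the method comparison.

**Signal.** The forward model is a per-voxel multi-tensor mixture: each
bundle contributes f_i · exp(−b(rd_i + (ad_i − rd_i)(g·t_i)²)) and the
remaining fraction an isotropic background with diffusivity 0.8e-3 mm²/s
(grey-matter order, so FA-based stop rules are exercised). S0 = 1. The
emulated acquisition is a single shell of 61 directions at b = 1000 s/mm²
plus one b=0, directions from a spherical Fibonacci hemisphere lattice.
Noise is Rician, S → sqrt((S+ε1)² + ε2²) with ε ~ N(0, S0/SNR); the study
condition is SNR 20. Identical spec and seed give bit-identical volumes.

**Lesions.** A lesion rescales the local bundle AD/RD with a Gaussian
falloff (σ = radius/2) — multipliers above 1 emulate vasogenic oedema
(AD and RD up), below 1 compression (both down) — and can displace bundle
midlines with the same falloff, emulating mass effect. The two extreme
regimes used throughout are AD/RD = 0.64/0.21 (severe compression) and
1.58/1.20 (severe oedema), the ends of the observed lambda-chart spread;
the unlesioned tract uses the contralateral normal values 1.08/0.46.

**What the phantom does not model:** gyral anatomy, susceptibility
artefacts, multi-shell acquisitions, spatially varying S0/coil profiles,
or partial-volume CSF. Passing the phantom tests therefore shows that the
algorithms behave as described *under the designed geometry and noise*,
not that they would perform identically on clinical data.

## FACT

Bidirectional propagation from every seed-voxel center along the per-voxel
principal eigenvector, fixed step of half a voxel (1 mm), nearest-neighbour
direction lookup, sign chosen per step to minimise the turning angle. Stop
rules: FA below `fa_stop` (default 0.1), turn between consecutive steps
above `max_angle_deg` (default 90°, deliberately liberal so sharp bends
remain trackable), leaving the tracking mask or grid, or reaching
`max_length_mm` (300). The entered sub-threshold voxel keeps the terminal
point. Streamlines shorter than two points are dropped.

At the unequal-FA crossing the fitted single tensor points along the
higher-FA bundle, so streamlines seeded in the low-FA arm turn and exit
through the wrong endpoints — the false-continuation behaviour the
benchmark asserts. At the 1-into-3 split, only the straight daughter is
recovered; the side branches receive only minor partial coverage.

## Probabilistic maps of connectivity

Monte-Carlo walks (default 2000 per seed region, bidirectional, FACT stop
rules) accumulate per-voxel visit counts and mean first-entry directions.
Two walk models are provided:

* `adaptive` (default): each step follows the eigen-axis that best
  continues the path weighted by eigenvalue, a = argmax_i λi·|v_i·prev|,
  oscillating around it with in-plane magnitudes given by the remaining
  eigenvalue ratios. In stick-like voxels this reduces exactly to the
  principal-eigenvector model; in planar (crossing) voxels the walker can
  lock onto the secondary axis and pass straight through. Measured on the
  standard phantom, ~12% of low-arm walks traverse the crossing, with some
  leakage onto the other bundle — the false-positive fibres probabilistic
  tracking is known to produce at crossings.
* `v1`: oscillation around the principal eigenvector only,
  d = normalize(v1 + u(λ2/λ1)v2 + w(λ3/λ1)v3) with u, w ~ U(−1,1). This
  simplest model cannot traverse a crossing from the minor bundle when
  only a single fitted tensor per voxel is available (0/2000 walks in the
  measurement above): the fitted mixture tensor's v1 lies along the
  dominant bundle and per-step sign alignment makes any lateral excursion
  coherent. It is kept as a config option and as the degenerate-limit
  reference.

Within a walk's own seed region only the departure direction (initial
direction of the longer half-walk) is recorded; elsewhere the direction of
first entry. Two maps combine into a connectivity score
freq_A · freq_B where the mean entry directions oppose (negative dot
product) — the operationalisation of "entered from opposite sides" — and
zero otherwise. The intrinsic threshold scans quantile levels of the
positive scores and keeps the level that minimises the number of
26-connected suprathreshold components while retaining a component
touching both ROIs (ties resolve to the higher level); if no level
connects the ROIs the tract is classified "not found".

## Global tracking

Fibres are a dynamic set of oriented cylinder segments (length 3 mm, width
1 mm — commensurate with 2 mm voxels) optimised against the whole dataset
by Metropolis–Hastings under an exponential cooling schedule
T_k = 0.1·(0.001/0.1)^(k/n).

**Energy.** The data term is E_data = Σ_{voxels, b>0} (M − P)², where M is
the per-voxel anisotropic signal (b0-normalised signal minus its per-voxel
minimum over gradients) and P the configuration's prediction; each segment
deposits w/3 · exp(−b·c·(g·n)²) (kernel diffusivity c = 1.0e-3 mm²/s) at
three quadrature points along its axis (at 0 and ±0.6·half-length, chosen
to stay inside the center voxel for a segment at a 2 mm voxel center). The
unnormalised sum is deliberate: it places the data cost of a ~20°
misorientation a few multiples above the stop temperature, so the final
cooling phase locks orientations (with a per-gradient-normalised energy
the same schedule leaves orientation disorder as an equilibrium property —
measured as only ~50% of segments aligned versus ~97% without the
normalisation). The bond term per bonded endpoint pair is

    spring·d² + curvature_penalty·(1 + u_a·u_b) − bond_reward

with d the endpoint gap and u the outward axis directions (collinear
continuation ⇒ u_a·u_b = −1, zero curvature cost). Defaults
spring = 0.006/mm², curvature_penalty = 0.6, bond_reward = 0.03 put the
bonding break-even angle at ~18°: the ~16° per-segment turn of the bend
arc stays chainable, while every link of a chain snaking between the two
crossing bundles (which needs ≥ 20–35° per link over the short crossing
zone) is strictly unfavourable and breaks during cooling. With softer
penalties a few such cross-bundle chains per run survived as kinetic traps
(bonded segments cannot die, and each endpoint only receives a handful of
bond proposals in the cold phase); the stiffer wall plus a larger
bond-flip share helps, but a residual class survives at any desk scale:
short (4–7 segment), nearly straight diagonal chains threading the
partial-volume overlap zone of the crossing, where the bond reward
roughly balances their mild data misfit — a weak local minimum that only
a far deeper anneal could reliably dissolve. These strays cannot grow:
extending them means either unsupported orientations in pure-bundle
territory (data cost) or turning onto a bundle (curvature cost). The
phantom benchmark therefore compares fibres of at least 24 mm (8
segments), in line with the minimum fibre-length filters fibre-tracking
tools apply for display; at the benchmark's 1.2×10⁶ iterations this
leaves bundle coverage, branch detection and bend traversal unchanged
while no cross-bundle chain was observed on any of eight validation
seeds (the strays, when present at all, were single 4–7-segment chains).

**Sampler.** Proposals: birth 0.225, death 0.225, rigid move 0.3,
bond-flip 0.25. Birth positions are uniform in the mask; orientations come
from a
50/50 mixture of uniform and a Watson lobe (κ = 8) around the local
principal eigenvector, with the exact proposal density in the
reversible-jump ratio (the mixture speeds mixing without biasing the
stationary distribution). Birth/death acceptance uses a Poisson reference
measure with mass `reference_count` (default 100); only fully unbonded
segments may die, so removal of a chained segment requires breaking its
bonds first. Moves reject configurations that stretch a bond beyond the
bond radius (1.5 mm), which keeps bond-breaks always reversible. Bond-flip
acceptance carries the candidate-count proposal asymmetry exactly, which
is what the enumerated-state detailed-balance audit checks. Energy
bookkeeping is incremental and audited against a from-scratch
recomputation.

**Weight.** The segment weight defaults to ¼ of the mask-averaged
anisotropic signal component and behaves like an FA threshold: doubling it
reduces the number of segments surviving in weakly anisotropic territory.

**Scale.** Desk-scale default is 4×10⁵ iterations (5×10⁵ in the phantom
benchmark) on a ≤ 65k-voxel phantom with mask restricted to the designed
bundles — the whole-brain original used 3×10⁸; the iteration count is a
parameter. Chains with ≥ 4 segments are emitted as fibres (polylines
through bonded-endpoint midpoints). Because desk-scale chains are a few
centimetres, detection for global tracking is classified on the connected
union of fibre voxels rather than on single chains.

## Tract measurements

* **Detection** is "found" iff the output contains a connected tract
  meeting both the seed and the target region (per streamline for FACT; a
  26-connected suprathreshold component for connectivity maps; the
  fibre-union mask for global tracking).
* **Profiles** average FA/MD/AD/RD over the tract ROI in z-bins (default
  2 mm); empty bins are NaN.
* **Deviation.** At a z level, each tract's position is the in-plane
  centroid of its voxels; D is the |x|-distance to the midsagittal plane
  x = 0, and ID = |D_h − D_p| / (D_h + D_p). The level of strongest
  deviation is the argmax over z of |D_h − D_p|.
* **Tumour area** uses the ellipse formula π·d1·d2/4 on two orthogonal
  diameters supplied by the caller.

## Statistical layer

The packaged 17-patient reference table carries WHO grade, motor
impairment, Fugl-Meyer score, planar tumour area, deviation index and
ipsilateral FA/MD/AD/RD. Summaries use sample (n−1) SDs. Pearson
correlations use the t transform with n−2 df. Paired t-tests between
pathological and contralateral metrics apply Bonferroni correction with
family size 4 (the four diffusion metrics); identical pairs return t = 0,
p = 1, while zero-variance differences with nonzero shift raise. The
lambda chart flags each patient's (RD, AD) against the contralateral
mean ± 2 SD bands (only the contralateral summary values are available:
FA 0.51 ± 0.15, MD 0.67 ± 0.03, AD 1.08 ± 0.16, RD 0.46 ± 0.08);
per-patient contralateral values were never published, so paired-test
behaviour is validated on synthetic data, not on the table.

Phantom scoring: per-bundle coverage is the fraction of ground-truth
centerline voxels within one voxel of the output; false positives are
output voxels in the bundle's axial slab outside the one-voxel-dilated
union of all bundles; a split branch counts as found at coverage > 0.5;
cross-bundle jumps are chains/streamlines entering the exclusive territory
of both crossing bundles.

## Numerical and degenerate-input choices

* Gradient tables require ≥ 6 non-collinear directions and at least one
  b = 0 entry; off-unit directions are renormalised on read with a
  warning.
* Empty seed masks warn and return empty results; empty tract ROIs and
  zero-distance deviation inputs raise.
* All stochastic stages take explicit integer seeds; pipeline sub-seeds
  derive from one master seed via `numpy.random.SeedSequence` and stay
  below 2³¹.

## Known limitations

* Single-tensor directional model only: crossing traversal by the
  probabilistic walker relies on the adaptive axis-switching rule, not on
  a true multi-peak orientation distribution.
* The global-tracking energy is a behavioural surrogate (least-squares
  data term, spring/curvature/reward bond term) validated on phantoms, not
  a re-derivation of the original functional; its constants are package
  defaults, not measured quantities.
* Desk-scale annealing (10⁵–10⁶ iterations) reproduces the qualitative
  phantom outcomes; fibre length and density are far from converged
  relative to a 3×10⁸-iteration run.
* The clinical detection rates (100/94/88%) of the motivating study
  depend on patient data that is not reproducible synthetically; the
  package reproduces the phantom phenomenology and the printed-table
  statistics instead.
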