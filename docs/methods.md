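# Methods

This note documents the models, algorithms, parameters and numerical
choices behind `osteofabric`, and what the synthetic phantoms do and do
not establish about real data.

## Segmentation

A calibrated density volume (mgHA/cm³, isotropic voxels) is smoothed with
a separable Gaussian truncated at ±`support` voxels per axis and
renormalized to unit sum (defaults σ = 0.2 voxels, support = 1, i.e. a
3×3×3 kernel — the scanner-vendor style noise filter), then thresholded at
439.0 mgHA/cm³. Boundaries are handled by edge replication so no bone or
marrow is fabricated outside the scanned field. The comparison is
inclusive (a voxel exactly at the threshold is bone); the choice is
arbitrary at float precision and is recorded in the mask provenance.
Whether the vendor filter normalizes before or after truncation is not
documented anywhere we know of; unit-sum-after-truncation is assumed, and
the unit tests pin the kernel against direct evaluation of
exp(−d²/2σ²) over the 3³ offsets.

## Regions and compartments

Analysis regions are contiguous axial slice segments, half-open
`[start, start + n)` with 0-based indexing and `n = ceil(length_mm ×
1000 / voxel_size_um)` — ceil because 2.48 mm at 12 µm is 206.67 voxels
and the standard segment is 207 slices. Adjacent segments therefore
partition their union exactly.

Compartments are split per axial slice:

1. background 4-connected to the slice border is *exterior*;
2. bone 8-connected to the exterior (the cortical ring plus any
   periosteal bone attached to or beyond it) is **cortical**;
3. the filled interior of that ring is the **endosteal envelope**; bone
   inside it is **trabecular**. The envelope (marrow + trabeculae) is the
   total-volume reference for trabecular BV/TV and Conn.D.

Slices with no bone inside the envelope are disambiguated topologically:
bone enclosing two or more comparable cells, or enclosing nothing while a
disk closing (radius 10 voxels by default) at least half-again fills its
silhouette, is a shell-less porous lattice and is classified
all-trabecular with a logged warning; bone enclosing one dominant cavity
(or compact bone) is cortical. The masks are disjoint and cover all bone
on every input, and the procedure is invariant under in-plane 90°
rotations.

Limitations: trabeculae fused to the cortex are absorbed into it (the
generator keeps a marrow clearance, and real µCT practice faces the same
ambiguity), and a breached cortex opens the cavity to the exterior, which
makes those slices genuinely ambiguous — the same difficulty that leads
practitioners to include both compartments in anisotropy measurements on
tumor-destroyed bone.

## Morphometry

BV/TV is an exact voxel-count ratio scaled by the voxel volume; no
surface smoothing enters. The Euler characteristic is computed on the
cubical complex of the bone voxels (each bone voxel contributes its
closed unit cube; shared vertices/edges/faces counted once): χ = V − E +
F − C, equivalent to β0 − β1 + β2 with 26-connected bone in 6-connected
background. The implementation is ~15 lines of shifted boolean
reductions; tests cross-check it against an independent library
implementation on random masks. Connectivity density uses the standard
estimator Conn.D = (1 − χ)/TV, which assumes one connected component and
no enclosed cavities; negative raw values (fragmented structures) are
clamped to 0 with a log note rather than reported, since a negative
density would silently poison downstream group comparisons. No
largest-component purification is applied: tumor-lysed structures
legitimately fragment, and purification would hide exactly the effect
under study.

## Fabric tensor and degree of anisotropy

**Directions.** A deterministic spherical-Fibonacci lattice of `n`
hemisphere directions (default 256, minimum 9 to overdetermine the
6-parameter fit); antipodally unique, second moment within 0.02 of I/3
from n ≈ 128.

**Surface-projection MIL** (production path). The binary field is meshed
by marching cubes at level 0.5 (vertices in µm). For direction ω,
MIL(ω) = 2·BV / Σₜ aₜ|nₜ·ω| — the stereological relation between bone
volume and projected bone-surface area. BV is the voxel-count volume.
Faces created where the ROI truncates bone are not bone surface: the mask
is edge-replicated 3 voxels outward before meshing so cut structure
continues straight out, and every triangle beyond the ROI boundary planes
is flagged and excluded from projection sums. Pre-mesh Gaussian smoothing
is available but off by default: only the *projected* area enters the MIL
relation, which the raw level-set mesh estimates without bias, while
smoothing closes narrow marrow gaps in dense structures and destroys real
surface.

**Test-line MIL** (oracle). A grid of parallel rays (spacing 2 voxels)
marches through the bounding box at 0.5-voxel steps, sampling the binary
field by trilinear interpolation thresholded at 0.5 — the same midpoint
surface convention as the mesh. Single-sample bone/marrow runs are below
the ray resolution (grazing-incidence flicker) and are suppressed before
crossing counting; nearest-voxel sampling without this suppression
overcounts crossings by ~25% on oblique rays through voxelized spheres.
MIL = total in-bone length / interior marrow→bone crossings; rays
entering through ROI faces contribute length but no boundary crossing.
On a voxelized ball of radius 12 the estimator reads 16.01 voxels against
the analytic 4R/3 = 16.

**Cap.** Directions with vanishing projected area or no crossings (e.g.
along the plates of a plate lattice, or along a perfect cylinder) have
unbounded intercepts; MIL is capped at the bounding-box diagonal in both
estimators.

**Tensor fit.** The 6 unique entries of symmetric M are fit by linear
least squares to n·M·n = MIL(n)⁻² over the sampled directions; principal
MILs are Lᵢ = mᵢ^(−1/2) from the eigendecomposition, principal directions
carry a deterministic sign convention (first nonzero component positive),
and **DA = L1/L3** — the ratio of principal MILs exactly, *not* the
eigenvalue ratio of M (which would be DA²); vendor conventions differ and
this disambiguation matters when comparing absolute values. When MILs
were measured with a cap, eigenvalues below cap⁻² claim intercepts longer
than the specimen and are floored there (this also absorbs least-squares
jitter that would otherwise make a translation-invariant structure's
smallest eigenvalue marginally negative); without a cap a non-positive-
definite fit raises.

On translation-invariant structures (plates, perfect cylinders) the
longest MIL is cap-dominated, so absolute DA values there scale with the
ROI diagonal; all claims about such structures are ordering claims
(anisotropic ≫ isotropic, principal axis matches construction), never
absolute magnitudes. Whole-bone masks (cortical + trabecular) are the
default input in pipeline use.

## Phantoms

Bone voxels are written at 700 mgHA/cm³ on a 0 background so the 439.0
threshold cleanly bisects the phases before noise; the generators model
structure, not acquisition physics (no beam hardening, rings, partial
volume, or projection simulation). Additive Gaussian density noise
(typical σ 30–50 mgHA/cm³) exercises the filter+threshold stage; at these
levels the mask is recovered exactly, so passing tests demonstrate the
pipeline's correctness on its own terms, *not* segmentation robustness on
real scans.

* **Plates** — periodic parallel plates; BV/TV = t/(t+s) exactly when the
  axis length is a multiple of the period.
* **Isotropic Boolean** — union of spheres (default radius 6 voxels) at
  Poisson-random centers in a radius-padded box; intensity is iterated
  until the achieved voxel fraction is within ±0.02 of target. The MIL
  ellipsoid of this structure is a sphere, making it the DA ≈ 1
  calibration reference.
* **Cortical cylinder** — hollow tube along an axis; one independent loop
  (χ = 0).
* **Metaphysis-like** — cortical shell (wall 3 voxels) around a trabecular
  honeycomb of thin vertical plates (thickness 2, grid spacing 14 voxels,
  ±1 voxel jitter per line), the dominant motif of load-bearing
  metaphyseal trabeculae; strongly anisotropic along the bone axis with
  one loop per enclosed channel. Plates are chopped into 8-slice
  structural elements, and compartment ground truth plus the element
  label volume are recorded.

**Tumor model.** Osteolysis removes a fraction of the structural
*elements* (whole segments, not voxels), fragmenting struts and opening
loops the way tumor permeation does — voxel-wise thinning would leave
connectivity intact. Optionally a 70° angular window is cut through the
shell (cortical breach). Woven bone is deposited as randomly oriented
spicules — capsules of radius 2–4 voxels and length 10–30, orientation
uniform on the sphere — outside the cortex until the target fraction of
the periosteal band (8 voxels wide) is bone. The spicule geometry is a
stand-in for real woven-bone texture, chosen to guarantee no preferred
direction in expectation; its parameters are conventions of this
generator, not biological claims. All generators are bit-reproducible
under their seed.

## Statistics

Mann-Whitney U (midrank ties) is exact by enumeration when
min(n_x, n_y) ≤ 8 without cross-sample ties, otherwise the tie-corrected
normal approximation with continuity correction; Wilcoxon signed-rank
(zeros dropped, W = smaller signed-rank sum) is exact for n ≤ 15 without
tied magnitudes. The branch taken is recorded in each result. Dunn's
follow-up uses pooled-midrank z statistics with tie correction and the
classical Bonferroni family-wise factor over k(k−1)/2 comparisons, capped
at 1. Pearson r takes its two-sided p from the t transform with n − 2 df.
All tests are two-sided. The tests pin the exact branches against full
enumeration (all C(n+m, n) labelings; all 2ⁿ sign patterns).

## Study orchestration

One result row per (sample, region) carries trabecular BV/TV, χ, Conn.D
(trabecular compartment, endosteal-envelope TV), whole-bone DA with
principal MILs, and full provenance (configuration hash, per-sample seed,
version). Per-sample seeds are `(global_seed + crc32(sample_id)) mod 2³¹`
so adding a sample never perturbs the others; reruns with the same
configuration and seed are bit-identical. A failing sample is logged into
a machine-readable failure record and the run continues.

The bundled demo study uses (120, 72, 72)-voxel phantoms at 12 µm with
the honeycomb confined to the proximal half, 0.6 mm (50-slice) regions in
each zone, 5 control vs 5 tumor samples (lysis 0.7, woven 0.5, no
breach — breached slices are outside the validated domain of the
compartment heuristic, see above), noise σ = 40 mgHA/cm³ and 128
directions. Trabecular metrics are compared in the metaphysis — the
diaphysis has no trabecular compartment to compare — and DA in both
regions.

## Validation conditions and problem sizes

The acceptance checks run at desk scale, chosen to exercise every stage
at meaningful resolution: MIL estimator cross-validation on 128³ phantoms
over 64 directions (≤10% median relative disagreement); isotropy/
anisotropy calibration at 96³ with 256 directions (isotropic DA ≤ 1.15);
tumor-degradation sweeps on 96×64×64 phantoms averaged over 5 seeds.
The degradation sweeps hold the other tumor parameter at a moderate
baseline (woven 0.3 during the lysis sweep, lysis 0.5 during the woven
sweep) because the pathology is concurrent by nature; a pure-lysis sweep
on a shell+lattice composite is non-monotone at extreme lysis for a
geometric reason worth stating: as the trabeculae vanish, the highly
anisotropic cortical shell dominates the measurement and DA turns back
up — exactly why pure cortical diaphyses read the highest DA of all.

## Known limitations

* Absolute DA on translation-invariant structures is ROI-cap-dominated
  (see above); only orderings are asserted.
* The compartment heuristic is validated on shell+lattice geometries with
  marrow clearance; fused trabeculae and breached cortices are ambiguous.
* Conn.D inherits the β0 = 1, β2 = 0 assumptions of its estimator.
* Phantom noise is additive white Gaussian on a two-level density field;
  real µCT noise is structured and the phases overlap, so segmentation
  performance on real scans is out of scope here.
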