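"""Synthetic microCT bone phantoms with known ground truth.

Generators emulate the structural regimes a murine osteosarcoma study has
to distinguish:

* organized anisotropic bone — periodic plate lattices, hollow cortical
  cylinders along a principal axis, and a composite "metaphysis-like"
  phantom (cortical shell around an oriented rod-and-brace trabecular
  lattice);
* tumor-induced osteolysis — removal of whole trabecular structural
  elements, which fragments struts and degrades connectivity the way tumor
  permeation does (voxel-wise erosion would not);
* disorganized periosteal osteogenesis — randomly oriented short spicules
  deposited on the outer cortical surface (woven-bone analog);
* an isotropic Boolean reference (union of Poisson-placed spheres), the
  structure whose MIL ellipsoid is a sphere;
* additive Gaussian density noise.

Bone voxels are written at 700 mgHA/cm^3 against a 0 background so that the
standard segmentation threshold of 439.0 mgHA/cm^3 cleanly bisects the two
phases before noise; the generators model structure, not beam physics.

Every generator is deterministic under its seed (bit-identical reruns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .volume import DensityVolume

__all__ = [
    "PhantomTruth",
    "TumorParams",
    "make_plate_phantom",
    "make_isotropic_boolean",
    "make_cortical_cylinder",
    "make_metaphysis_like",
    "apply_tumor",
    "add_noise",
    "BONE_DENSITY",
    "BG_DENSITY",
]

BONE_DENSITY = 700.0  # mgHA/cm^3 written into bone voxels
BG_DENSITY = 0.0      # mgHA/cm^3 background (marrow / soft tissue)


@dataclass
class PhantomTruth:
    """Ground truth recorded at construction time, for testing downstream stages.

    Attributes
    ----------
    true_bvtv : float
        Exact bone voxel fraction of the emitted volume.
    principal_axis : ndarray or None
        Unit vector of the dominant structural direction (None if isotropic
        or direction is a plane rather than an axis).
    plate_normal : ndarray or None
        For plate phantoms, the unit normal of the plates (the direction of
        the *shortest* mean intercept length).
    betti1 : int or None
        Number of independent loops, when known analytically.
    component_count : int or None
        Number of connected components, when known analytically.
    bone_mask : ndarray or None
        Exact bone voxels of the noiseless phantom.
    cortical_mask, trabecular_mask : ndarray or None
        Compartment ground truth for composite phantoms (disjoint; their
        union is bone_mask).
    element_labels : ndarray or None
        int32 label per voxel; >0 labels a trabecular structural element
        (rod segment or brace) that osteolysis can remove as a unit.
    meta : dict
        Geometry needed by :func:`apply_tumor` (cylinder center, radii,
        periosteal band, axis).
    """

    true_bvtv: float
    principal_axis: Optional[np.ndarray] = None
    plate_normal: Optional[np.ndarray] = None
    betti1: Optional[int] = None
    component_count: Optional[int] = None
    bone_mask: Optional[np.ndarray] = None
    cortical_mask: Optional[np.ndarray] = None
    trabecular_mask: Optional[np.ndarray] = None
    element_labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_bvtv <= 1.0):
            raise ValueError(f"true_bvtv must be in [0,1], got {self.true_bvtv}")
        for name in ("principal_axis", "plate_normal"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                n = np.linalg.norm(v)
                if not math.isclose(n, 1.0, rel_tol=1e-9, abs_tol=1e-9):
                    raise ValueError(f"{name} must be unit-norm, |v|={n}")
                setattr(self, name, v)


@dataclass
class TumorParams:
    """Osteosarcoma-analog perturbation parameters.

    lysis_fraction : fraction of trabecular structural elements removed.
    woven_fraction : target bone fraction of the periosteal band filled with
        randomly oriented spicules.
    breach : whether to cut a window through the cortical shell (cortical
        transgression).
    seed : RNG seed; identical seeds give bit-identical volumes.
    """

    lysis_fraction: float = 0.0
    woven_fraction: float = 0.0
    breach: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lysis_fraction", "woven_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


def _densify(mask: np.ndarray, bone_density: float, bg_density: float) -> np.ndarray:
    vals = np.full(mask.shape, bg_density, dtype=np.float64)
    vals[mask] = bone_density
    return vals


def make_plate_phantom(
    shape: tuple[int, int, int],
    voxel_size: float = 12.0,
    plate_thickness: int = 2,
    plate_spacing: int = 2,
    normal_axis: int = 0,
    bone_density: float = BONE_DENSITY,
    bg_density: float = BG_DENSITY,
) -> tuple[DensityVolume, PhantomTruth]:
    """Periodic parallel plates perpendicular to ``normal_axis``.

    BV/TV is plate_thickness/(plate_thickness+plate_spacing) exactly when the
    axis length is a multiple of the period; the longest MIL lies in the
    plate plane.
    """
    if plate_thickness < 1 or plate_spacing < 1:
        raise ValueError("plate_thickness and plate_spacing must be >= 1")
    if bone_density <= bg_density:
        raise ValueError("bone_density must exceed bg_density")
    period = plate_thickness + plate_spacing
    if shape[normal_axis] < period:
        raise ValueError(
            f"shape[{normal_axis}]={shape[normal_axis]} smaller than one period {period}"
        )
    idx = np.arange(shape[normal_axis])
    pattern = (idx % period) < plate_thickness
    reshape = [1, 1, 1]
    reshape[normal_axis] = -1
    mask = np.broadcast_to(pattern.reshape(reshape), shape).copy()
    normal = np.zeros(3)
    normal[normal_axis] = 1.0
    n_plates = int(np.sum(pattern[1:] & ~pattern[:-1])) + int(pattern[0])
    truth = PhantomTruth(
        true_bvtv=float(mask.mean()),
        plate_normal=normal,
        betti1=0,
        component_count=n_plates,
        bone_mask=mask,
    )
    return DensityVolume(_densify(mask, bone_density, bg_density), voxel_size), truth


def make_isotropic_boolean(
    shape: tuple[int, int, int],
    voxel_size: float = 12.0,
    sphere_radius: float = 6.0,
    target_bvtv: float = 0.3,
    seed: int = 0,
    bone_density: float = BONE_DENSITY,
    bg_density: float = BG_DENSITY,
    tol: float = 0.02,
    max_iter: int = 10,
) -> tuple[DensityVolume, PhantomTruth]:
    """Boolean model: union of spheres at Poisson-random centers.

    The sphere intensity is adjusted iteratively until the achieved voxel
    fraction is within ``tol`` of ``target_bvtv``. No preferred direction.
    """
    if not (0.0 < target_bvtv < 1.0):
        raise ValueError(f"target_bvtv must be in (0,1), got {target_bvtv}")
    if sphere_radius < 2:
        raise ValueError("sphere_radius must be >= 2")
    shape = tuple(int(s) for s in shape)
    if min(shape) < 2 * sphere_radius:
        raise ValueError("volume too small for the given sphere_radius")
    r = float(sphere_radius)
    v_sphere = 4.0 / 3.0 * math.pi * r**3
    lam = -math.log1p(-target_bvtv) / v_sphere
    pad = r
    lo = -pad
    hi = np.asarray(shape, dtype=float) + pad
    box_vol = float(np.prod(hi - lo))
    rr = int(math.ceil(r))
    zz, yy, xx = np.mgrid[-rr : rr + 1, -rr : rr + 1, -rr : rr + 1]
    ball_offsets = np.argwhere(zz**2 + yy**2 + xx**2 <= r**2) - rr

    achieved = None
    for it in range(max_iter):
        rng = np.random.default_rng([seed, it])
        n_spheres = rng.poisson(lam * box_vol)
        centers = rng.uniform(lo, hi, size=(n_spheres, 3))
        mask = np.zeros(shape, dtype=bool)
        for c in np.rint(centers).astype(int):
            pts = c[None, :] + ball_offsets
            ok = np.all((pts >= 0) & (pts < shape), axis=1)
            pts = pts[ok]
            mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        achieved = float(mask.mean())
        if abs(achieved - target_bvtv) <= tol:
            break
        if achieved in (0.0, 1.0):
            lam *= 2.0 if achieved == 0.0 else 0.5
        else:
            lam *= math.log1p(-target_bvtv) / math.log1p(-achieved)
    else:
        raise RuntimeError(
            f"could not reach target BV/TV {target_bvtv} (achieved {achieved}) "
            f"with sphere_radius={sphere_radius} in {max_iter} iterations"
        )
    truth = PhantomTruth(true_bvtv=achieved, principal_axis=None, bone_mask=mask)
    return DensityVolume(_densify(mask, bone_density, bg_density), voxel_size), truth


def _cylinder_mask(
    shape: tuple[int, int, int],
    outer_radius: float,
    inner_radius: float,
    axis: int,
) -> np.ndarray:
    cross_axes = [a for a in range(3) if a != axis]
    n1, n2 = shape[cross_axes[0]], shape[cross_axes[1]]
    c1, c2 = (n1 - 1) / 2.0, (n2 - 1) / 2.0
    i1, i2 = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    d = np.sqrt((i1 - c1) ** 2 + (i2 - c2) ** 2)
    ring = d <= outer_radius
    if inner_radius > 0:
        ring &= d >= inner_radius
    expand = [slice(None)] * 3
    expand[axis] = None
    order = np.argsort([axis] + cross_axes)
    full = np.broadcast_to(
        np.expand_dims(ring, 0), (shape[axis], n1, n2)
    ).transpose(order)
    return np.ascontiguousarray(full)


def make_cortical_cylinder(
    shape: tuple[int, int, int],
    voxel_size: float = 12.0,
    outer_radius: float = 24.0,
    inner_radius: float = 18.0,
    axis: int = 0,
    bone_density: float = BONE_DENSITY,
    bg_density: float = BG_DENSITY,
) -> tuple[DensityVolume, PhantomTruth]:
    """Hollow diaphyseal-cortex tube along ``axis`` (inner_radius=0: solid rod)."""
    if inner_radius < 0 or outer_radius <= inner_radius:
        raise ValueError("need 0 <= inner_radius < outer_radius")
    cross = [shape[a] for a in range(3) if a != axis]
    if outer_radius > min(cross) / 2.0:
        raise ValueError("cylinder does not fit in the cross-section")
    mask = _cylinder_mask(shape, outer_radius, inner_radius, axis)
    direction = np.zeros(3)
    direction[axis] = 1.0
    hollow = inner_radius > 0
    truth = PhantomTruth(
        true_bvtv=float(mask.mean()),
        principal_axis=direction,
        betti1=1 if hollow else 0,
        component_count=1,
        bone_mask=mask,
        meta={
            "axis": axis,
            "outer_radius": float(outer_radius),
            "inner_radius": float(inner_radius),
        },
    )
    return DensityVolume(_densify(mask, bone_density, bg_density), voxel_size), truth


def make_metaphysis_like(
    shape: tuple[int, int, int] = (120, 72, 72),
    voxel_size: float = 12.0,
    outer_radius: Optional[float] = None,
    wall_thickness: float = 3.0,
    trab_spacing: int = 14,
    trab_thickness: float = 2.0,
    segment_length: int = 8,
    lattice_slices: Optional[tuple[int, int]] = None,
    periosteal_band: float = 8.0,
    seed: int = 0,
    bone_density: float = BONE_DENSITY,
    bg_density: float = BG_DENSITY,
) -> tuple[DensityVolume, PhantomTruth]:
    """Cortical shell plus a longitudinally oriented trabecular honeycomb.

    The interior lattice is a grid of thin *vertical plates* (a 2D grid of
    lines extruded along the long axis), the dominant motif of load-bearing
    metaphyseal trabeculae: strongly anisotropic along the bone axis, with
    one independent loop per enclosed channel. Each plate is chopped into
    ``segment_length``-slice structural elements so osteolysis (see
    :func:`apply_tumor`) fragments struts and opens loops realistically.
    Compartment ground truth (cortical vs trabecular) and the element label
    volume are recorded in the returned PhantomTruth.

    ``lattice_slices`` restricts the trabecular lattice to an axial range
    (half-open), mimicking a metaphysis over a trabecula-free diaphysis.
    """
    nz, ny, nx = (int(s) for s in shape)
    if outer_radius is None:
        outer_radius = min(ny, nx) / 2.0 - periosteal_band - 2.0
    inner_radius = outer_radius - wall_thickness
    if inner_radius <= trab_thickness + 4:
        raise ValueError("shell leaves no room for an interior lattice")
    if outer_radius + periosteal_band > min(ny, nx) / 2.0:
        raise ValueError("periosteal band does not fit in the cross-section")
    z0, z1 = lattice_slices if lattice_slices is not None else (0, nz)
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"invalid lattice_slices {lattice_slices}")

    shell = _cylinder_mask((nz, ny, nx), outer_radius, inner_radius, axis=0)

    rng = np.random.default_rng(seed)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    next_label = 1

    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    # plates never touch the shell: a small marrow clearance separates them
    interior2d = (yy - cy) ** 2 + (xx - cx) ** 2 <= (inner_radius - 2.0) ** 2
    half_t = trab_thickness / 2.0
    zs = np.arange(z0, z1)
    seg_of_z = (zs - z0) // max(1, int(segment_length))
    seg_ids = np.unique(seg_of_z)

    lines: list[np.ndarray] = []
    for coord, c0 in ((yy, cy), (xx, cx)):
        for g in np.arange(c0 % trab_spacing, max(ny, nx), trab_spacing):
            pos = g + rng.integers(-1, 2)
            line2d = (np.abs(coord - pos) <= half_t) & interior2d
            if line2d.any():
                lines.append(line2d)
    for line2d in lines:
        for si in seg_ids:
            zsel = zs[seg_of_z == si]
            sub = labels[zsel[0] : zsel[-1] + 1]
            sub[:, line2d] = next_label
            next_label += 1

    trabecular = labels > 0
    # the shell wins where the two would overlap (they should not, by margin)
    trabecular &= ~shell
    labels[~trabecular] = 0
    bone = shell | trabecular

    axis_vec = np.array([1.0, 0.0, 0.0])
    truth = PhantomTruth(
        true_bvtv=float(bone.mean()),
        principal_axis=axis_vec,
        bone_mask=bone,
        cortical_mask=shell,
        trabecular_mask=trabecular,
        element_labels=labels,
        meta={
            "axis": 0,
            "center": (cy, cx),
            "outer_radius": float(outer_radius),
            "inner_radius": float(inner_radius),
            "periosteal_band": float(periosteal_band),
            "lattice_slices": (int(z0), int(z1)),
        },
    )
    return DensityVolume(_densify(bone, bone_density, bg_density), voxel_size), truth


def _spicule_points(center, direction, half_len, radius, shape):
    """Voxel indices of a capsule (cylinder with hemispherical caps)."""
    lo = np.maximum(np.floor(center - half_len - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + half_len + radius).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3).astype(float)
    rel = pts - center
    t = np.clip(rel @ direction, -half_len, half_len)
    closest = np.outer(t, direction)
    d2 = np.sum((rel - closest) ** 2, axis=1)
    return pts[d2 <= radius**2].astype(int)


def apply_tumor(
    vol: DensityVolume, truth: PhantomTruth, params: TumorParams
) -> DensityVolume:
    """Perturb a composite phantom the way an osteolytic/osteogenic tumor does.

    * removes ``lysis_fraction`` of the trabecular structural elements
      (whole rod segments / braces, chosen at random) — fragmentation, not
      thinning;
    * if ``breach``, zeroes a window through the cortical shell;
    * deposits randomly oriented spicules (radius 2-4 voxels, length 10-30)
      outside the cortex until ``woven_fraction`` of the periosteal band is
      bone.

    Deterministic under ``params.seed``. With all-zero parameters the output
    equals the input.
    """
    if truth.element_labels is None or truth.cortical_mask is None:
        raise ValueError("apply_tumor requires a phantom with compartment ground truth")
    out = vol.copy()
    vals = out.values
    bone_density = float(vals[truth.bone_mask].max()) if truth.bone_mask.any() else BONE_DENSITY
    bg = BG_DENSITY
    rng = np.random.default_rng(params.seed)
    shape = np.asarray(vals.shape)

    # osteolysis: remove whole structural elements
    ids = np.unique(truth.element_labels)
    ids = ids[ids > 0]
    n_remove = int(round(params.lysis_fraction * len(ids)))
    if params.lysis_fraction >= 1.0:
        n_remove = len(ids)
    if n_remove > 0 and len(ids) > 0:
        removed = rng.choice(ids, size=n_remove, replace=False)
        kill = np.isin(truth.element_labels, removed) & truth.trabecular_mask
        vals[kill] = bg

    # cortical breach: angular window through the shell, middle of the volume
    if params.breach:
        cy, cx = truth.meta["center"]
        nz = vals.shape[0]
        zlo, zhi = nz // 3, nz // 3 + max(2, nz // 6)
        yy, xx = np.meshgrid(
            np.arange(vals.shape[1]), np.arange(vals.shape[2]), indexing="ij"
        )
        ang = np.arctan2(yy - cy, xx - cx)
        window2d = np.abs(ang) < math.radians(35.0)
        win = np.zeros(vals.shape, dtype=bool)
        win[zlo:zhi] = window2d
        vals[win & truth.cortical_mask] = bg

    # periosteal woven bone: random spicules in the band outside the cortex
    if params.woven_fraction > 0:
        cy, cx = truth.meta["center"]
        r_out = truth.meta["outer_radius"]
        band_w = truth.meta["periosteal_band"]
        yy, xx = np.meshgrid(
            np.arange(vals.shape[1]), np.arange(vals.shape[2]), indexing="ij"
        )
        d2d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        band2d = (d2d > r_out) & (d2d <= r_out + band_w)
        outside2d = d2d > r_out
        band = np.broadcast_to(band2d, vals.shape)
        outside = np.broadcast_to(outside2d, vals.shape)
        band_count = int(band.sum())
        target = params.woven_fraction * band_count
        max_spicules = 100000
        for _ in range(max_spicules):
            if np.count_nonzero((vals >= bone_density / 2) & band) >= target:
                break
            # sample a center in the band (uniform over the annulus)
            rad = math.sqrt(rng.uniform(r_out**2, (r_out + band_w) ** 2))
            theta = rng.uniform(0, 2 * math.pi)
            cz = rng.uniform(0, vals.shape[0] - 1)
            center = np.array([cz, cy + rad * math.sin(theta), cx + rad * math.cos(theta)])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            half_len = rng.uniform(5.0, 15.0)
            radius = rng.uniform(2.0, 4.0)
            pts = _spicule_points(center, direction, half_len, radius, shape)
            if len(pts) == 0:
                continue
            keep = outside[pts[:, 0], pts[:, 1], pts[:, 2]]
            pts = pts[keep]
            vals[pts[:, 0], pts[:, 1], pts[:, 2]] = bone_density
        else:
            raise RuntimeError("woven-bone deposition did not converge")
    return out


def add_noise(vol: DensityVolume, sigma_density: float, seed: int = 0) -> DensityVolume:
    """Add zero-mean Gaussian density noise (mgHA/cm^3); sigma 0 is identity."""
    if sigma_density < 0:
        raise ValueError("sigma_density must be >= 0")
    if sigma_density == 0:
        return vol.copy()
    rng = np.random.default_rng(seed)
    noisy = vol.values + rng.normal(0.0, sigma_density, size=vol.values.shape)
    return DensityVolume(noisy, vol.voxel_size)
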