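"""Axial regions of interest and cortical/trabecular compartment splitting.

A long-bone study analyzes fixed-length axial segments (e.g. a 2.48 mm
metaphyseal segment = 207 slices at 12 um voxels) and applies different
compartment rules per metric: bone volume fraction and connectivity density
are computed on the trabecular compartment only, while the degree of
anisotropy includes cortical and trabecular bone together.

Slice segments are half-open [start, start+n) with 0-based indexing and
ceil rounding of length to slices. Compartments are split per slice: bone
reachable from the exterior background without crossing marrow — the
cortical ring plus any periosteal bone attached to or outside it — is
cortical; the filled interior of that ring is the endosteal envelope and
bone inside it is trabecular. Slices whose bone is an interior-spread
porous lattice rather than a peripheral ring degrade gracefully to
all-trabecular.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.ndimage import (
    binary_closing,
    binary_dilation,
    binary_fill_holes,
    label as ndi_label,
)
from skimage.morphology import disk

from .volume import BinaryVolume, DensityVolume

__all__ = [
    "RegionSpec",
    "CompartmentMasks",
    "slices_for_length",
    "extract_segment",
    "split_compartments",
]

log = logging.getLogger(__name__)

TRABECULAR_ONLY = "trabecular_only"
WHOLE_BONE = "whole_bone"


@dataclass
class RegionSpec:
    """Axial analysis segment: [start_slice, start_slice + n) along axis 0."""

    name: str
    start_slice: int
    length_mm: float
    compartment_mode: str = TRABECULAR_ONLY

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("length_mm must be > 0")
        if self.start_slice < 0:
            raise ValueError("start_slice must be >= 0")
        if self.compartment_mode not in (TRABECULAR_ONLY, WHOLE_BONE):
            raise ValueError(f"unknown compartment_mode {self.compartment_mode!r}")


@dataclass
class CompartmentMasks:
    """Disjoint cortical/trabecular split covering all bone in the segment.

    ``endosteal`` is the region enclosed by the endosteum (marrow +
    trabecular bone); it is the total-volume reference for trabecular
    BV/TV and connectivity density.
    """

    cortical: np.ndarray
    trabecular: np.ndarray
    endosteal: np.ndarray


def slices_for_length(length_mm: float, voxel_size: float) -> int:
    """Number of axial slices covering ``length_mm`` at ``voxel_size`` um.

    Rounds up (2.48 mm at 12 um -> ceil(206.67) = 207 slices).
    """
    if length_mm <= 0 or voxel_size <= 0:
        raise ValueError("length_mm and voxel_size must be > 0")
    exact = length_mm * 1000.0 / voxel_size
    return int(math.ceil(exact - 1e-9))


def extract_segment(
    obj: Union[DensityVolume, BinaryVolume], spec: RegionSpec
) -> Union[DensityVolume, BinaryVolume]:
    """Crop the half-open axial segment defined by ``spec`` (same type out)."""
    n = slices_for_length(spec.length_mm, obj.voxel_size)
    stop = spec.start_slice + n
    if stop > obj.shape[0]:
        raise ValueError(
            f"segment {spec.name!r} [{spec.start_slice}, {stop}) exceeds "
            f"volume extent {obj.shape[0]}"
        )
    sl = slice(spec.start_slice, stop)
    if isinstance(obj, DensityVolume):
        return DensityVolume(obj.values[sl].copy(), obj.voxel_size)
    prov = dict(obj.provenance)
    prov["segment"] = {"name": spec.name, "start": spec.start_slice, "stop": stop}
    return BinaryVolume(obj.mask[sl].copy(), obj.voxel_size, prov)


def _close2d(mask2d: np.ndarray, footprint: np.ndarray, radius: int) -> np.ndarray:
    pad = radius + 1
    padded = np.pad(mask2d, pad)
    closed = binary_closing(padded, structure=footprint)
    return closed[pad:-pad, pad:-pad]


_EIGHT = np.ones((3, 3), dtype=bool)
# a slice with no bone inside its envelope is lattice-like (all-trabecular)
# rather than cortical when its bone encloses several comparable cells, or
# encloses nothing yet closing at least half-again fills its silhouette; a
# cortex ring encloses one dominant cavity (small periosteal pockets aside)
# and closing adds little to a compact rod
_POROSITY_MIN = 1.5
_DOMINANT_HOLE = 0.6


def _split_slice(
    b2: np.ndarray, footprint: np.ndarray, radius: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One-slice compartment split; returns (endosteal, trabecular, fallback)."""
    # exterior background: 4-connected components touching the border
    bg_lbl, _ = ndi_label(~b2)
    border = np.zeros_like(b2)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    outer_ids = np.unique(bg_lbl[border & ~b2])
    outer = np.isin(bg_lbl, outer_ids[outer_ids > 0])
    # cortical candidate: bone components (8-conn) touching the exterior
    bone_lbl, _ = ndi_label(b2, structure=_EIGHT)
    touch = np.unique(bone_lbl[binary_dilation(outer, structure=_EIGHT) & b2])
    cort = np.isin(bone_lbl, touch[touch > 0])
    endo = binary_fill_holes(cort) & ~cort
    trab = b2 & endo
    if trab.any():
        return endo, trab, False
    # no bone inside the envelope: compact/annular cortex vs shell-less lattice
    hole_lbl, n_holes = ndi_label(endo)
    if n_holes == 0:
        filled = binary_fill_holes(_close2d(b2, footprint, radius))
        if filled.sum() >= _POROSITY_MIN * b2.sum():
            return filled, b2.copy(), True
    elif n_holes >= 2:
        sizes = np.bincount(hole_lbl.ravel())[1:]
        if sizes.max() < _DOMINANT_HOLE * sizes.sum():
            filled = binary_fill_holes(_close2d(b2, footprint, radius))
            return filled, b2.copy(), True
    return endo, trab, False


def split_compartments(
    bmask: BinaryVolume, closing_radius: int = 10
) -> CompartmentMasks:
    """Split a bone mask into cortical shell and interior trabeculae.

    Per axial slice: bone connected to the exterior background (the
    cortical ring and any periosteal bone attached to or beyond it) is
    cortical; the filled interior of that ring is the endosteal envelope,
    and bone inside the envelope is trabecular. Slices without any bone
    inside the envelope are kept all-cortical if their bone forms a
    compact or annular shape, or reclassified all-trabecular (with a
    logged warning) if it is a shell-less porous lattice. The two masks
    are disjoint and cover all bone on every input.
    """
    bone = bmask.mask
    if not bone.any():
        raise ValueError("split_compartments requires a non-empty bone mask")
    footprint = disk(closing_radius)
    cortical = np.zeros_like(bone)
    trabecular = np.zeros_like(bone)
    endosteal = np.zeros_like(bone)
    n_fallback = 0
    for z in range(bone.shape[0]):
        b2 = bone[z]
        if not b2.any():
            continue
        endo, trab, fellback = _split_slice(b2, footprint, closing_radius)
        n_fallback += int(fellback)
        cortical[z] = b2 & ~trab
        trabecular[z] = trab
        endosteal[z] = endo
    if n_fallback:
        log.warning(
            "split_compartments: %d slice(s) had no closed cortex; "
            "classified as all-trabecular",
            n_fallback,
        )
    return CompartmentMasks(cortical=cortical, trabecular=trabecular, endosteal=endosteal)
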