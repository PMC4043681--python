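"""Shared fixtures: small phantoms, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import osteofabric as of
from osteofabric.preprocess import segment_bone

VOX = 12.0  # um, the standard scan resolution emulated throughout


@pytest.fixture(scope="session")
def plate_phantom():
    vol, truth = of.make_plate_phantom(
        (64, 64, 64), VOX, plate_thickness=2, plate_spacing=2, normal_axis=0
    )
    return vol, truth


@pytest.fixture(scope="session")
def boolean_phantom():
    vol, truth = of.make_isotropic_boolean(
        (64, 64, 64), VOX, sphere_radius=6, target_bvtv=0.3, seed=11
    )
    return vol, truth


@pytest.fixture(scope="session")
def hollow_cylinder():
    vol, truth = of.make_cortical_cylinder(
        (48, 48, 48), VOX, outer_radius=18, inner_radius=14, axis=0
    )
    return vol, truth


@pytest.fixture(scope="session")
def metaphysis_phantom():
    vol, truth = of.make_metaphysis_like((72, 64, 64), VOX, seed=3)
    return vol, truth


@pytest.fixture(scope="session")
def plate_mask(plate_phantom):
    return segment_bone(plate_phantom[0])


@pytest.fixture(scope="session")
def boolean_mask(boolean_phantom):
    return segment_bone(boolean_phantom[0])


@pytest.fixture(scope="session")
def cylinder_mask(hollow_cylinder):
    return segment_bone(hollow_cylinder[0])


@pytest.fixture(scope="session")
def metaphysis_mask(metaphysis_phantom):
    return segment_bone(metaphysis_phantom[0])


@pytest.fixture(scope="session")
def voxel_sphere_mask():
    """Voxelized ball of radius 12 voxels: analytic MIL = 4R/3 everywhere."""
    radius, n = 12, 48
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = (n - 1) / 2
    ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return of.BinaryVolume(ball, 1.0), radius
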