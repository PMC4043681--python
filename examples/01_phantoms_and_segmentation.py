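"""Generate synthetic bone phantoms and segment them.

Builds the four phantom families (plates, Boolean spheres, cortical
cylinder, metaphysis-like composite), adds acquisition-like density noise,
and recovers the bone mask with the standard Gaussian-filter + 439.0
mgHA/cm^3 threshold segmentation.
"""

import numpy as np

import osteofabric as of
from osteofabric.preprocess import segment_bone

plate, plate_truth = of.make_plate_phantom(
    (64, 64, 64), voxel_size=12.0, plate_thickness=2, plate_spacing=2, normal_axis=0
)
boolean, bool_truth = of.make_isotropic_boolean(
    (64, 64, 64), voxel_size=12.0, sphere_radius=6, target_bvtv=0.3, seed=1
)
cylinder, cyl_truth = of.make_cortical_cylinder(
    (64, 48, 48), voxel_size=12.0, outer_radius=18, inner_radius=14
)
meta, meta_truth = of.make_metaphysis_like((72, 64, 64), voxel_size=12.0, seed=2)

for name, truth in [
    ("plates", plate_truth),
    ("boolean", bool_truth),
    ("cylinder", cyl_truth),
    ("metaphysis", meta_truth),
]:
    print(f"{name:11s} true BV/TV = {truth.true_bvtv:.4f}")
# True BV/TV is the exact bone voxel fraction the generator wrote; the plate
# value is the analytic thickness/(thickness+spacing) ratio.

noisy = of.add_noise(meta, sigma_density=50.0, seed=3)
mask = segment_bone(noisy)  # Gaussian sigma=0.2/support=1, threshold 439.0
errors = int((mask.mask != meta_truth.bone_mask).sum())
print(f"\nsegmentation after sigma=50 mgHA/cm^3 noise: {errors} voxel errors "
      f"of {mask.mask.size}")
# Bone is written at 700 against 0 background, so the 439.0 threshold sits
# ~5 noise SDs from both phases and the mask is recovered essentially exactly.
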