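"""The full serial update on a five-image phantom: the flagship run.

Builds the biomechanical model once from image 1, models the shift with
FEM, the first resection with FEM (no discontinuity yet), later resections
with XFEM (discontinuity from the prior image's cavity), warps each image
toward its successor, and validates with modified Hausdorff tables.
Takes a couple of minutes on one CPU.
"""

import warnings

import numpy as np
from scipy import ndimage

from brainshift_xfem import PhantomSpec, generate_case, ground_truth_error, run_case
from brainshift_xfem.image_warping import mesh_displacement_to_voxel_field

spec = PhantomSpec(seed=1)
timeline, truth = generate_case(spec)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_case(timeline)

for line in result.log:
    print(line)

print("\nper-interval ground-truth recovery near the tracked boundary:")
brain1 = timeline.labels[0].region_mask("whole_brain")
for k in range(len(result.increments)):
    pred, _ = mesh_displacement_to_voxel_field(
        result.model.mesh, result.increments[k], timeline.images[0])
    region = "whole_brain" if timeline.interval_types[k] == "shift" else "healthy_brain"
    m = timeline.labels[k].region_mask(region)
    bnd = m & ~ndimage.binary_erosion(m)
    dist = ndimage.distance_transform_edt(~bnd, sampling=timeline.labels[k].spacing)
    stats = ground_truth_error(pred, truth[k], (dist <= 6.0) & brain1)
    print(f"  interval {k + 1}: mean {stats['mean']:.3f} mm, max {stats['max']:.2f} mm")

print("\npairwise modified Hausdorff (whole-brain mask), rigid -> nonrigid:")
for row in result.tables["pairwise"]:
    if row["scope"] == "whole_brain":
        print(f"  {row['interval']:<14} {row['H_rigid']:.3f} -> {row['H_nonrigid']:.3f} mm")
# A mean recovery error well below the voxel size and a Hausdorff decrease
# on every interval means the model captured the deformation the phantom
# actually underwent.
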