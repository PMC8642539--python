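"""Full imaging route on one synthetic organoid: render, surface, measure.

A 100 µm-radius organoid with 60 tumor cells (exponential depths, mean
15 µm) is rendered as an 85-section confocal stack (3 µm z-step), padded
with 50 blank slices, surfaced twice (the second pass avoids the artificial
closure at the stack top), and each detected tumor cell's signed distance
to the surface is compared with the planted ground truth.
"""

import numpy as np
from scipy.spatial import cKDTree

from glioquant import geometry as geo
from glioquant.synth3d import DepthLaw, ImagingParams, generate_scene, \
    render_stack

scene = generate_scene(100.0, None, 60, DepthLaw.exponential(15.0), seed=42)
stack = geo.pad_stack(render_stack(scene, ImagingParams()), n_blank=50)
print(f"stack: {stack.shape} voxels, total z = {stack.total_z_um:.0f} um")

mesh1 = geo.reconstruct_surface(stack)                 # pass 1
mesh2 = geo.outside_mask_resurface(stack, mesh1)       # pass 2 (watertight)
spots = geo.detect_spots(stack)                        # 10 um blob detection
table = geo.shortest_distance(spots, mesh2)

dist, idx = cKDTree(scene.tumor_positions).query(spots.positions)
err = table["distance_um"].to_numpy() - scene.tumor_true_depth[idx]
vol, area = geo.mesh_volume(mesh2), geo.mesh_area(mesh2)

print(f"detected {len(spots)} / {len(scene.tumor_positions)} tumor cells")
print(f"depth RMSE vs ground truth: {np.sqrt((err ** 2).mean()):.2f} um")
print(f"volume {vol:.3e} um^3 (sphere: {4 / 3 * np.pi * 1e6:.3e}), "
      f"area {area:.3e} um^2 (sphere: {4 * np.pi * 1e4:.3e})")
print("\nPositive distances are inside the organoid; the RMSE is well "
      "below the 3 um optical section spacing's diagonal.")
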