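"""Recover a known smooth warp by elastic image registration.

An atlas shell image is warped by a closed-form 3 mm sinusoidal
deformation; the registration must find the displacement field that maps
the warped (patient) image back onto the atlas.
"""

import numpy as np

import fibermap as fm
from fibermap.elastic import RegistrationConfig, dice_overlap, register, warp_image_by_field

mesh = fm.make_shell_mesh(fm.ShellSpec(radii=(8.0, 8.0, 8.0)), target_edge=1.2)
img = fm.voxelize(mesh, spacing=0.6)
warp = fm.SyntheticWarp.smooth(amplitude=3.0, seed=1)
patient = fm.warp_image(img, warp)

u = register(img, patient, RegistrationConfig(alpha=0.1, levels=4))

centers = patient.voxel_centers().reshape(-1, 3)
u_true = (warp.invert(centers, tol=1e-4) - centers).reshape(patient.dims + (3,))
occ = patient.values > 0.5
err = np.linalg.norm(u.u[occ] - u_true[occ], axis=1)
print(f"grid {img.dims}, occupied voxels {occ.sum()}")
print(f"mean |u - u_true| over the wall: {err.mean():.3f} mm (voxel = 0.6 mm)")
print(f"Dice before {dice_overlap(img, patient):.3f} -> after "
      f"{dice_overlap(warp_image_by_field(img, u, patient), patient):.3f}")
# A mean error well below one voxel and Dice near 1 mean the unknown
# deformation was recovered, not just the image overlap improved.
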