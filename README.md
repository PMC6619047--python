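# fibermap

Atlas-based mapping of atrial fiber orientations by elastic image
registration.

## The problem

Patient-specific electromechanical models of the human atria need the
local myofiber direction: electrical conduction is several times faster
along fibers than across them, and active contraction pulls along them.
The atrial wall (≈2 mm thick) is far below in-vivo diffusion-MRI
resolution, so fibers cannot be measured in patients. `fibermap`
implements the registration-based alternative: a single *atlas* atrial
geometry carries expert-defined fiber bundles; for each patient the atlas
shell is deformed onto the patient shell and the fibers are carried along
with the deformation.

## The method

Given an atlas and a patient geometry (tetrahedral shell meshes with
tagged endocardial/epicardial surfaces and 13 corresponding landmarks):

1. **Global alignment** — a least-squares rigid fit of the landmark pairs
   (Kabsch/SVD), refined by affine iterative-closest-point over all mesh
   nodes.
2. **Elastic registration** — both shells are rasterized to binary
   occupancy images `I_a`, `I_p` (0.6 mm voxels) and a displacement field
   u on the patient grid minimizes

       J(u) = ½ ∫ (I_a(x + u(x)) − I_p(x))² dx + α S(u),   α = 0.1,

   with S a linearized elastic potential. The minimization is
   Gauss–Newton with Armijo backtracking inside a 4-level Gaussian
   multiresolution pyramid.
3. **Fiber mapping** — the voxel displacement is interpolated to mesh
   nodes by inverse-distance weighting; the per-node deformation gradient
   F (affine part × Jacobian of u) reorients each atlas fiber, by default
   with the *preservation of principal directions* rule f′ = F f / ‖F f‖
   (the finite-strain rule f′ = R f, F = RU, is also available). Fibers
   are transferred to the patient surface by sign-aware IDW and projected
   onto the surface tangent plane.
4. **Harmonic lift** — each Cartesian component of the surface field is
   extended into the wall volume as a discrete harmonic function (P1
   finite elements, Dirichlet data on endo/epi), then renormalized.

A desk-scale anisotropic eikonal surrogate (Dijkstra over mesh edges with
an elliptic conduction metric, v_long/v_trans = √10) checks that mapped
and defined fibers produce similar activation patterns.

Fiber agreement is measured sign-agnostically: err = 1 − |f_mappedᵀ f_defined|.

## Worked example

Everything runs on synthetic fixtures: thin ellipsoidal shells with
analytic tangential fiber fields and closed-form warps, so every stage
has an exact oracle.

```python
import numpy as np
import fibermap as fm

atlas_spec = fm.ShellSpec(radii=(10.0, 10.0, 10.0), thickness=2.0)
patient_spec = fm.ShellSpec(radii=(11.0, 9.5, 10.5),
                            bumps=[fm.Bump((1, 1, 0.3), 1.5, 0.5)])

atlas_mesh = fm.make_shell_mesh(atlas_spec, target_edge=0.9)
patient_mesh = fm.make_shell_mesh(patient_spec, target_edge=0.9)
atlas_fibers, _ = fm.analytic_fibers(atlas_mesh, "circumferential", atlas_spec)
patient_truth, _ = fm.analytic_fibers(patient_mesh, "circumferential", patient_spec)

atlas = fm.GeometryBundle(atlas_mesh, fm.shell_landmarks(atlas_spec), atlas_fibers)
patient = fm.GeometryBundle(patient_mesh, fm.shell_landmarks(patient_spec),
                            patient_truth)
volume_fibers, report = fm.run_pipeline(atlas, patient)
print(report["stages"][2]["dice_after_registration"])
print(report["fiber_error"]["mean"], report["fiber_error"]["p95"])
```

prints (on this fixture pair)

```
0.9509765368986761
0.01961092304550237 0.06233634301159625
```

i.e. after registration the warped atlas shell overlaps the patient shell
with Dice 0.95, and the mapped surface fibers deviate from the patient's
analytically defined fibers by a mean sign-agnostic error of 0.02 (95th
percentile 0.065) — errors concentrate where the field direction changes
fastest (the poles of the circumferential field), mirroring the behavior
at fiber-bundle boundaries on real atria.

Short narrative scripts in `examples/` exercise each capability
(`01_synthetic_shells.py`, `02_registration.py`, `03_fiber_mapping.py`,
`04_harmonic_lift.py`, `05_activation.py`), and the `fibermap` CLI wraps
the same functions (`fibermap synth`, `voxelize`, `align`, `register`,
`lift`, `activate`, `pipeline`).

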