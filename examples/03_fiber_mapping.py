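"""Full atlas-to-patient fiber mapping with a known answer.

The patient shell is a stretched, bumped, rigidly displaced version of
the spherical atlas; both carry the analytic circumferential field, so
the mapped fibers can be scored against ground truth.
"""

import numpy as np

import fibermap as fm

atlas_spec = fm.ShellSpec(radii=(10.0, 10.0, 10.0))
patient_spec = fm.ShellSpec(radii=(11.0, 9.5, 10.5),
                            bumps=[fm.Bump((1, 1, 0.3), 1.5, 0.5)])
atlas_mesh = fm.make_shell_mesh(atlas_spec, 0.9)
patient_mesh = fm.make_shell_mesh(patient_spec, 0.9)
atlas_fibers, _ = fm.analytic_fibers(atlas_mesh, "circumferential", atlas_spec)
patient_truth, _ = fm.analytic_fibers(patient_mesh, "circumferential", patient_spec)

atlas = fm.GeometryBundle(atlas_mesh, fm.shell_landmarks(atlas_spec), atlas_fibers)
patient = fm.GeometryBundle(patient_mesh, fm.shell_landmarks(patient_spec),
                            patient_truth)

volume_fibers, report = fm.run_pipeline(atlas, patient)

for stage in report["stages"]:
    extras = {k: v for k, v in stage.items() if k != "stage"}
    print(f"{stage['stage']}: {extras}")
fe = report["fiber_error"]
print(f"fiber error vs ground truth: mean {fe['mean']:.4f}, "
      f"p95 {fe['p95']:.4f} over {fe['n']} surface nodes")
# err = 1 - |f_mapped . f_defined|: 0 is perfect agreement, 1 orthogonal.
# A mean of ~0.02 means the mapped field is within a few degrees almost
# everywhere; the residual concentrates where the field direction turns.
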