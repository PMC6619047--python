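import numpy as np
import pytest
from hypothesis import settings

import fibermap as fm

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def shell_spec():
    return fm.ShellSpec(radii=(8.0, 8.0, 8.0), thickness=2.0)


@pytest.fixture(scope="session")
def shell_mesh(shell_spec):
    return fm.make_shell_mesh(shell_spec, target_edge=1.2)


@pytest.fixture(scope="session")
def shell_image(shell_mesh):
    return fm.voxelize(shell_mesh, spacing=0.6)


@pytest.fixture(scope="session")
def slab_mesh():
    return fm.make_slab_mesh(size=(20.0, 20.0, 4.0), h=1.0)


def rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@pytest.fixture(scope="session")
def fixture_pair():
    """Atlas sphere vs bumped/stretched patient shell with a rigid offset.

    The patient carries its own analytically defined circumferential
    fibers, which serve as ground truth for the mapped fibers.
    """
    atlas_spec = fm.ShellSpec(radii=(10.0, 10.0, 10.0))
    patient_spec = fm.ShellSpec(
        radii=(11.0, 9.5, 10.5), bumps=[fm.Bump((1.0, 1.0, 0.3), 1.5, 0.5)]
    )
    atlas_mesh = fm.make_shell_mesh(atlas_spec, 0.9)
    patient_mesh = fm.make_shell_mesh(patient_spec, 0.9)
    atlas_fibers, _ = fm.analytic_fibers(atlas_mesh, "circumferential", atlas_spec)
    patient_fibers, _ = fm.analytic_fibers(patient_mesh, "circumferential", patient_spec)

    R = rotation_z(np.deg2rad(12.0))
    t = np.array([4.0, -3.0, 2.0])
    patient_mesh = fm.TetMesh(patient_mesh.nodes @ R.T + t, patient_mesh.tets,
                              dict(patient_mesh.surface_tags))
    patient_lm = fm.shell_landmarks(patient_spec)
    patient_lm = fm.LandmarkSet(patient_lm.names, patient_lm.points @ R.T + t)
    patient_fibers = fm.FiberField(patient_fibers.vectors @ R.T)

    atlas = fm.GeometryBundle(atlas_mesh, fm.shell_landmarks(atlas_spec), atlas_fibers)
    patient = fm.GeometryBundle(patient_mesh, patient_lm, patient_fibers)
    return atlas, patient


@pytest.fixture(scope="session")
def pipeline_result(fixture_pair):
    """The end-to-end run is expensive; share it across tests."""
    atlas, patient = fixture_pair
    volume_field, report = fm.run_pipeline(atlas, patient)
    return volume_field, report
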