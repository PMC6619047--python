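import numpy as np
import pytest
from hypothesis import given, strategies as st

import fibermap as fm
from fibermap.core import ContentError, DisplacementField, FiberField
from fibermap.mapping import (
    deformation_gradient_at_nodes,
    fiber_error,
    idw_field_at_points,
    idw_interpolate,
    project_tangential,
    reorient_fiber,
    surface_normals,
    transfer_fibers,
)

ROT = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])


# ----------------------------------------------------------------- IDW

def test_idw_exact_hit_returns_voxel_value():
    rng = np.random.default_rng(0)
    u = DisplacementField((0, 0, 0), (1, 1, 1), rng.normal(size=(4, 4, 4, 3)))
    out = idw_field_at_points(u, np.array([[2.0, 1.0, 3.0]]))
    assert np.allclose(out[0], u.u[2, 1, 3], atol=1e-12)


def test_idw_constant_field_everywhere():
    u = DisplacementField((0, 0, 0), (1, 1, 1),
                          np.broadcast_to([1.0, -2.0, 0.5], (4, 4, 4, 3)).copy())
    pts = np.array([[0.3, 1.7, 2.2], [3.0, 0.1, 0.9]])
    assert np.allclose(idw_field_at_points(u, pts), [1.0, -2.0, 0.5], atol=1e-12)


def test_idw_midpoint_of_two_sources_is_mean():
    src = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    vals = np.array([[1.0, 0, 0], [0.0, 1.0, 0]])
    out = idw_interpolate(src, vals, np.array([[1.0, 0, 0]]), k=2)
    assert np.allclose(out[0], [0.5, 0.5, 0.0], atol=1e-12)


def test_idw_out_of_domain_rejected():
    u = DisplacementField((0, 0, 0), (1, 1, 1), np.zeros((4, 4, 4, 3)))
    with pytest.raises(ContentError):
        idw_field_at_points(u, np.array([[10.0, 0, 0]]))


# -------------------------------------------------- deformation gradient

def test_gradient_identity_and_rotation():
    u = DisplacementField((0, 0, 0), (1, 1, 1), np.zeros((5, 5, 5, 3)))
    nodes = np.array([[2.0, 2.0, 2.0], [1.2, 3.1, 0.7]])
    F, warn = deformation_gradient_at_nodes(fm.AffineTransform.identity(), u, nodes)
    assert np.allclose(F, np.eye(3), atol=1e-12) and not warn
    F, _ = deformation_gradient_at_nodes(fm.AffineTransform(ROT, [0, 0, 0]), u, nodes)
    assert np.allclose(F, ROT, atol=1e-12)


def test_gradient_matches_analytic_warp_jacobian(shell_image, shell_mesh):
    warp = fm.SyntheticWarp.smooth(amplitude=3.0, seed=1)
    u = DisplacementField(shell_image.origin, shell_image.spacing,
                          warp(shell_image.voxel_centers()))
    F, warn = deformation_gradient_at_nodes(fm.AffineTransform.identity(), u,
                                            shell_mesh.nodes)
    F_true = fm.true_deformation_gradient(warp, shell_mesh.nodes)
    err = np.linalg.norm(F - F_true, axis=(1, 2))
    assert err.max() < 0.05
    assert not warn


# --------------------------------------------------------- reorientation

@pytest.mark.parametrize("strategy", ["finite_strain", "principal_directions"])
def test_reorient_identity_and_rotation(strategy):
    f = np.array([0.0, 1.0, 0.0])
    assert np.allclose(reorient_fiber(f, np.eye(3), strategy), f, atol=1e-12)
    out = reorient_fiber(f, ROT, strategy)
    assert np.allclose(out, ROT @ f, atol=1e-12)


def test_reorient_shear_closed_forms():
    """Simple shear F = [[1,1,0],[0,1,0],[0,0,1]], f = e_y: PPD follows the
    sheared direction; finite strain applies the polar rotation
    R = [[2,1],[-1,2]]/sqrt(5) of the in-plane block."""
    F = np.array([[1.0, 1, 0], [0, 1, 0], [0, 0, 1]])
    f = np.array([0.0, 1.0, 0.0])
    ppd = reorient_fiber(f, F, "principal_directions")
    assert np.allclose(ppd, np.array([1.0, 1.0, 0.0]) / np.sqrt(2), atol=1e-10)
    fs = reorient_fiber(f, F, "finite_strain")
    assert np.allclose(fs, np.array([1.0, 2.0, 0.0]) / np.sqrt(5), atol=1e-10)
    assert not np.allclose(fs, ppd)


@given(st.integers(0, 500))
def test_reorient_sign_agnostic(seed):
    rng = np.random.default_rng(seed)
    f = rng.normal(size=3)
    f /= np.linalg.norm(f)
    F = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
    if np.linalg.det(F) <= 0.05:
        return
    for strategy in ("finite_strain", "principal_directions"):
        a = reorient_fiber(f, F, strategy)
        b = reorient_fiber(-f, F, strategy)
        assert np.isclose(abs(a @ b), 1.0, atol=1e-9)
        assert np.isclose(np.linalg.norm(a), 1.0, atol=1e-9)


def test_reorient_degenerate_rejected():
    F = np.diag([1.0, 1e-16, 1.0])
    with pytest.raises(ContentError):
        reorient_fiber(np.array([0.0, 1.0, 0.0]), F, "principal_directions")


# -------------------------------------------------------------- transfer

def test_transfer_exact_hit_copies_fiber():
    src = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
    fib = FiberField(np.tile([1.0, 0, 0], (4, 1)))
    out, flags = transfer_fibers(src, fib, src[:2], k=3)
    assert np.allclose(np.abs(out.vectors @ np.array([1.0, 0, 0])), 1.0, atol=1e-12)
    assert not flags.any()


def test_transfer_uniform_field_stays_uniform(shell_mesh):
    src = shell_mesh.nodes[shell_mesh.surface_tags["endo"]]
    fib = FiberField(np.tile([0.0, 0, 1.0], (len(src), 1)))
    qry = src + 0.05
    out, _ = transfer_fibers(src, fib, qry)
    assert np.allclose(np.abs(out.vectors[:, 2]), 1.0, atol=1e-12)


def test_transfer_resolves_antipodal_representatives():
    f = np.array([1.0, 0, 0])
    src = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
    fib = FiberField(np.stack([f, -f, f]))
    out, flags = transfer_fibers(src, fib, np.array([[0.3, 0.3, 0.0]]), k=3)
    assert np.isclose(abs(out.vectors[0] @ f), 1.0, atol=1e-12)
    assert not flags[0]


# ------------------------------------------- projection, normals, error

def test_project_tangential_cases():
    f, n = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
    out, flag = project_tangential(f, n)
    assert np.allclose(out, f) and not flag
    out, flag = project_tangential(np.array([1.0, 0, 1.0]) / np.sqrt(2), n)
    assert np.allclose(out, [1.0, 0, 0], atol=1e-12)
    _, flag = project_tangential(n, n)
    assert flag


def test_surface_normals_radial_on_sphere(shell_mesh):
    for tag in ("endo", "epi"):
        idx = shell_mesh.surface_tags[tag]
        normals = surface_normals(shell_mesh, tag)[idx]
        radial = shell_mesh.nodes[idx]
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        assert np.abs(np.linalg.norm(normals, axis=1) - 1).max() < 1e-9
        assert np.linalg.norm(normals - radial, axis=1).max() < 1e-1
        assert np.median(np.linalg.norm(normals - radial, axis=1)) < 1e-2


def test_fiber_error_reference_values():
    f = np.array([1.0, 0, 0])
    assert fiber_error(f, f) == 0.0
    assert fiber_error(f, -f) == 0.0
    assert fiber_error(f, np.array([0.0, 1, 0])) == 1.0
    f45 = np.array([1.0, 1.0, 0]) / np.sqrt(2)
    assert np.isclose(fiber_error(f, f45), 1 - np.sqrt(2) / 2, atol=1e-12)
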