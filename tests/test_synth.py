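import numpy as np
import pytest

import fibermap as fm
from fibermap.core import ContentError
from fibermap.synth import ResolutionError, verify_diffeomorphic


def test_shell_surfaces_at_analytic_radii():
    spec = fm.ShellSpec(radii=(15.0, 15.0, 15.0), thickness=2.0)
    mesh = fm.make_shell_mesh(spec, target_edge=0.9)
    r = np.linalg.norm(mesh.nodes, axis=1)
    eps = 0.9
    assert np.all(np.abs(r[mesh.surface_tags["endo"]] - 15.0) < eps)
    assert np.all(np.abs(r[mesh.surface_tags["epi"]] - 17.0) < eps)


def test_shell_volume_close_to_analytic():
    spec = fm.ShellSpec(radii=(15.0, 15.0, 15.0), thickness=2.0)
    mesh = fm.make_shell_mesh(spec, target_edge=0.9)
    exact = 4.0 / 3.0 * np.pi * (17.0**3 - 15.0**3)
    assert abs(mesh.tet_volumes().sum() - exact) / exact < 0.05
    assert mesh.tet_volumes(signed=True).min() > 0


def test_edge_must_resolve_thickness(shell_spec):
    with pytest.raises(ResolutionError):
        fm.make_shell_mesh(shell_spec, target_edge=2.5)


def test_orifice_rim_within_cone():
    d = np.array([0.0, 0.0, 1.0])
    spec = fm.ShellSpec(radii=(10.0, 10, 10), orifices=[fm.Orifice(d, 0.4, "svc")])
    mesh = fm.make_shell_mesh(spec, 1.2)
    rim = mesh.surface_tags["rim:svc"]
    assert rim.size > 0
    u = mesh.nodes[rim] / np.linalg.norm(mesh.nodes[rim], axis=1, keepdims=True)
    ang = np.arccos(np.clip(u @ d, -1, 1))
    assert np.all(ang < 0.4 + 0.25)  # rim ring sits at the cone boundary


def test_overlapping_orifices_rejected():
    with pytest.raises(ContentError):
        fm.ShellSpec(radii=(10, 10, 10), orifices=[
            fm.Orifice((0, 0, 1), 0.5), fm.Orifice((0.1, 0, 1), 0.5)])


def test_fibers_unit_and_tangential(shell_mesh, shell_spec):
    for style in ("circumferential", "helical", "two-layer"):
        fib, flags = fm.analytic_fibers(shell_mesh, style, shell_spec, helix_angle=0.5)
        assert np.allclose(np.linalg.norm(fib.vectors, axis=1), 1.0, atol=1e-9)
        n = shell_mesh.nodes / np.linalg.norm(shell_mesh.nodes, axis=1, keepdims=True)
        dots = np.abs(np.sum(fib.vectors * n, axis=1))
        assert dots[~flags].max() < 1e-6


def test_helical_zero_angle_is_circumferential(shell_mesh, shell_spec):
    a, _ = fm.analytic_fibers(shell_mesh, "circumferential", shell_spec)
    b, _ = fm.analytic_fibers(shell_mesh, "helical", shell_spec, helix_angle=0.0)
    assert np.allclose(a.vectors, b.vectors, atol=1e-12)


def test_two_layer_endo_perpendicular_to_epi(shell_spec):
    field = fm.AnalyticFiberField(shell_spec, "two-layer")
    u = np.array([[1.0, 0, 0], [0, 1, 0], [0.5, 0.5, 0.7071]])
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    endo = field(shell_spec.center + u * 8.0)
    epi = field(shell_spec.center + u * 10.0)
    assert np.all(np.abs(np.sum(endo * epi, axis=1)) < 1e-9)


def test_zero_warp_is_identity(shell_mesh):
    w = fm.SyntheticWarp.translation([0, 0, 0])
    out = fm.warp_mesh(shell_mesh, w)
    assert np.array_equal(out.nodes, shell_mesh.nodes)


def test_translation_warp_shifts_image_by_one_voxel(shell_image):
    h = shell_image.spacing[0]
    w = fm.SyntheticWarp.translation([h, 0, 0])
    out = fm.warp_image(shell_image, w)
    expected = np.roll(shell_image.values, 1, axis=0)
    expected[0] = 0.0
    assert np.allclose(out.values, expected, atol=1e-9)


def test_warped_tets_stay_positive(shell_mesh):
    w = fm.SyntheticWarp.smooth(amplitude=3.0, seed=2)
    out = fm.warp_mesh(shell_mesh, w)
    assert out.tet_volumes(signed=True).min() > 0


def test_true_deformation_gradient_affine_and_identity():
    B = np.array([[0.02, 0.01, 0], [0, -0.03, 0.01], [0.005, 0, 0.015]])
    w = fm.SyntheticWarp.affine(B, [1, 2, 3])
    F = fm.true_deformation_gradient(w, np.array([5.0, -3.0, 2.0]))
    assert np.allclose(F, np.eye(3) + B, atol=1e-14)
    wid = fm.SyntheticWarp.translation([4, 5, 6])
    assert np.allclose(fm.true_deformation_gradient(wid, np.zeros(3)), np.eye(3))


def test_sinusoid_jacobian_matches_finite_differences():
    w = fm.SyntheticWarp.smooth(amplitude=2.0, seed=5)
    x0 = np.array([1.0, -2.0, 0.5])
    J = w.jacobian(x0)
    h = 1e-6
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        fd = (w(x0 + e) - w(x0 - e)) / (2 * h)
        assert np.allclose(J[:, j], fd, atol=1e-6)


def test_smooth_warps_are_diffeomorphic():
    for seed in (0, 1, 2):
        w = fm.SyntheticWarp.smooth(amplitude=3.0, seed=seed)
        assert verify_diffeomorphic(w, [-20, -20, -20], [20, 20, 20], n=32)


def test_nonaffine_warp_has_no_affine_part_at_center():
    for seed in (0, 3, 7):
        w = fm.SyntheticWarp.smooth_nonaffine(3.0, seed=seed)
        assert np.linalg.norm(w(np.zeros(3))) < 1e-12
        assert np.linalg.norm(w.jacobian(np.zeros(3))) < 1e-12
        assert verify_diffeomorphic(w, [-20, -20, -20], [20, 20, 20])


def test_landmarks_correspond_across_specs():
    a = fm.shell_landmarks(fm.ShellSpec(radii=(8, 8, 8)))
    b = fm.shell_landmarks(fm.ShellSpec(radii=(10, 9, 11)))
    assert a.names == b.names and len(a) == 13
    # same direction from center for corresponding points
    ua = a.points / np.linalg.norm(a.points, axis=1, keepdims=True)
    ub = b.points / np.linalg.norm(b.points, axis=1, keepdims=True)
    assert np.allclose(ua, ub, atol=1e-9)


def test_slab_mesh_structure():
    slab = fm.make_slab_mesh((10, 10, 4), h=1.0)
    assert slab.tet_volumes(signed=True).min() > 0
    assert np.isclose(slab.tet_volumes().sum(), 400.0)
    assert np.allclose(slab.nodes[slab.surface_tags["endo"]][:, 2], 0.0)
    assert np.allclose(slab.nodes[slab.surface_tags["epi"]][:, 2], 4.0)
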