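import numpy as np
import pytest

import fibermap as fm
from fibermap.core import ContentError, DisplacementField
from fibermap.elastic import (
    RegistrationConfig,
    build_pyramid,
    dice_overlap,
    elastic_operator,
    elastic_potential,
    gauss_newton_level,
    invert_displacement,
    prolong,
    register,
    ssd,
    warp_image_by_field,
    _flatten_u,
)


def _img(values, origin=(0, 0, 0), spacing=(1, 1, 1)):
    return fm.BinaryImage3D(origin, spacing, values)


# ---------------------------------------------------------------- SSD

def test_ssd_identical_images_zero(shell_image):
    u = DisplacementField.zeros_like(shell_image)
    # interpolation at exact voxel centers leaves only float rounding
    assert ssd(shell_image, u, shell_image) < 1e-20


def test_ssd_single_voxel_difference_is_half_voxel_volume():
    a = np.zeros((6, 6, 6))
    b = a.copy()
    b[3, 3, 3] = 1.0
    for sp in (1.0, 0.6):
        ia, ib = _img(a, spacing=[sp] * 3), _img(b, spacing=[sp] * 3)
        u = DisplacementField.zeros_like(ib)
        assert np.isclose(ssd(ia, u, ib), 0.5 * sp**3, rtol=1e-12)


def test_ssd_grid_mismatch_rejected(shell_image):
    other = _img(np.zeros((4, 4, 4)))
    u = DisplacementField.zeros_like(other)
    with pytest.raises(ContentError):
        ssd(shell_image, u, shell_image)


def test_ssd_nonnegative(shell_image):
    rng = np.random.default_rng(0)
    u = DisplacementField(shell_image.origin, shell_image.spacing,
                          rng.normal(scale=0.5, size=shell_image.dims + (3,)))
    assert ssd(shell_image, u, shell_image) >= 0.0


# ------------------------------------------------------- elastic energy

def test_elastic_zero_for_translation_and_rotation():
    n, h = 9, 0.7
    x = np.stack(np.meshgrid(*[np.arange(n) * h] * 3, indexing="ij"), axis=-1)
    const = np.broadcast_to(np.array([1.0, -2.0, 3.0]), (n, n, n, 3)).copy()
    W = np.array([[0, 1, -0.5], [-1, 0, 2], [0.5, -2, 0]])  # antisymmetric
    rigid = x @ W.T + np.array([1.0, 2.0, 3.0])
    for u in (np.zeros((n, n, n, 3)), const, rigid):
        S = elastic_potential(DisplacementField((0, 0, 0), (h, h, h), u))
        assert abs(S) < 1e-20


def test_elastic_convergence_order_on_sinusoid():
    """Discrete energy of u = (sin(pi x / L), 0, 0) converges to
    pi^2 L / 2 at observed order >= 1.9 over three refinements."""
    L = 10.0
    exact = np.pi**2 * L / 2
    errs, hs = [], []
    for n in (17, 33, 65):
        h = L / (n - 1)
        x = np.arange(n) * h
        u = np.zeros((n, n, n, 3))
        u[..., 0] = np.sin(np.pi * x[:, None, None] / L)
        S = elastic_potential(DisplacementField((0, 0, 0), (h, h, h), u))
        errs.append(abs(S - exact))
        hs.append(h)
    order = np.polyfit(np.log(hs), np.log(errs), 1)[0]
    assert order >= 1.9


def test_elastic_operator_matches_dense_evaluation():
    rng = np.random.default_rng(4)
    n, h = 8, 0.5
    u = rng.normal(size=(n, n, n, 3))
    f = DisplacementField((0, 0, 0), (h, h, h), u)
    H = elastic_operator((n, n, n), (h, h, h), mu=1.0, lam=0.3)
    U = _flatten_u(u)
    assert np.isclose(0.5 * U @ (H @ U), elastic_potential(f, 1.0, 0.3), rtol=1e-10)
    assert (H != H.T).nnz == 0  # symmetric


# ------------------------------------------------------------- pyramid

def test_pyramid_single_level_is_original(shell_image):
    pyr = build_pyramid(shell_image, 1)
    assert len(pyr) == 1 and pyr[0] is shell_image


def test_pyramid_dims_halve(shell_image):
    pyr = build_pyramid(shell_image, 4)
    for fine, coarse in zip(pyr, pyr[1:]):
        assert coarse.dims == tuple(-(-d // 2) for d in fine.dims)
        assert np.allclose(coarse.spacing, 2 * fine.spacing)


def test_pyramid_preserves_blob_mass():
    """The smoothing kernel is normalized: the integral of a centered blob
    is preserved within 2% per level despite the 8x coarser sampling."""
    n = 33
    x = np.arange(n) - n // 2
    r = np.sqrt(x[:, None, None]**2 + x[None, :, None]**2 + x[None, None, :]**2)
    blob = (r < 10).astype(float)
    pyr = build_pyramid(_img(blob), 3)
    masses = [p.values.sum() * p.voxel_volume for p in pyr]
    for a, b in zip(masses, masses[1:]):
        assert abs(b - a) / a < 0.02


def test_prolong_exact_on_constant_and_linear_fields():
    coarse_img = _img(np.zeros((9, 9, 9)), spacing=(2, 2, 2))
    fine_img = _img(np.zeros((17, 17, 17)), spacing=(1, 1, 1))
    cx = coarse_img.voxel_centers()
    const = np.broadcast_to([1.0, 2.0, -3.0], cx.shape).copy()
    lin = cx @ np.array([[0.1, 0.2, 0.0], [0.0, -0.1, 0.3], [0.2, 0.0, 0.1]]).T
    fx = fine_img.voxel_centers()
    for u_c, expected in ((const, np.broadcast_to([1.0, 2.0, -3.0], fx.shape)),
                          (lin, fx @ np.array([[0.1, 0.2, 0.0], [0.0, -0.1, 0.3],
                                               [0.2, 0.0, 0.1]]).T)):
        out = prolong(DisplacementField(coarse_img.origin, coarse_img.spacing, u_c),
                      fine_img)
        assert out.matches_grid(fine_img)
        assert np.allclose(out.u, expected, atol=1e-12)


# -------------------------------------------------------- Gauss-Newton

def test_gauss_newton_self_is_stationary(shell_image):
    cfg = RegistrationConfig(max_gn_iter=5)
    u0 = DisplacementField.zeros_like(shell_image)
    u, info = gauss_newton_level(shell_image, shell_image, u0, cfg)
    assert np.abs(u.u).max() < 0.1 * shell_image.spacing.min()
    assert info["converged"]


def test_gauss_newton_recovers_two_voxel_shift(shell_image):
    h = shell_image.spacing[0]
    shift = np.array([2 * h, 0.0, 0.0])
    moved = fm.warp_image(shell_image, fm.SyntheticWarp.translation(shift))
    cfg = RegistrationConfig(max_gn_iter=30)
    u0 = DisplacementField.zeros_like(moved)
    u, info = gauss_newton_level(shell_image, moved, u0, cfg)
    occ = moved.values > 0.5
    mean_u = u.u[occ].mean(axis=0)
    # registration maps the fixed (shifted) image back into the moving one
    assert np.linalg.norm(mean_u - (-shift)) < 0.25 * np.linalg.norm(shift)
    hist = info["objective"]
    assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))


def test_register_self_residual_tiny(shell_image):
    u = register(shell_image, shell_image, RegistrationConfig(max_gn_iter=10))
    empty = fm.BinaryImage3D(shell_image.origin, shell_image.spacing,
                             np.zeros(shell_image.dims))
    scale = ssd(shell_image, DisplacementField.zeros_like(shell_image), empty)
    assert ssd(shell_image, u, shell_image) < 1e-6 * scale


def test_register_translation_equivariance(shell_mesh):
    img = fm.voxelize(shell_mesh, spacing=0.9, padding=6)
    shift_vox = np.array([2, 1, 0])
    rolled = np.roll(img.values, shift_vox, axis=(0, 1, 2))
    a_img = img
    b_img = fm.BinaryImage3D(img.origin, img.spacing, rolled)
    warp = fm.SyntheticWarp.smooth(amplitude=1.5, seed=3)
    a_fix = fm.warp_image(a_img, warp)
    b_fix = fm.BinaryImage3D(img.origin, img.spacing,
                             np.roll(a_fix.values, shift_vox, axis=(0, 1, 2)))
    cfg = RegistrationConfig(levels=2, max_gn_iter=10)
    ua = register(a_img, a_fix, cfg)
    ub = register(b_img, b_fix, cfg)
    occ = a_fix.values > 0.5
    diff = np.roll(ua.u, shift_vox, axis=(0, 1, 2))[np.roll(occ, shift_vox, axis=(0, 1, 2))] \
        - ub.u[np.roll(occ, shift_vox, axis=(0, 1, 2))]
    assert np.abs(diff).max() < 0.05


def test_warp_recovery_error_monotone_in_amplitude(shell_image):
    cfg = RegistrationConfig(levels=3, max_gn_iter=15)
    errors = []
    for amp in (0.75, 1.5, 3.0):
        warp = fm.SyntheticWarp.smooth(amplitude=amp, seed=11)
        fixed = fm.warp_image(shell_image, warp)
        u = register(shell_image, fixed, cfg)
        centers = fixed.voxel_centers().reshape(-1, 3)
        u_gt = (warp.invert(centers, tol=1e-4) - centers).reshape(fixed.dims + (3,))
        occ = fixed.values > 0.5
        errors.append(float(np.linalg.norm(u.u[occ] - u_gt[occ], axis=1).mean()))
    assert errors[0] <= errors[1] <= errors[2]


def test_invert_displacement_round_trip(shell_image):
    warp = fm.SyntheticWarp.smooth(amplitude=2.0, seed=9)
    centers = shell_image.voxel_centers()
    u = DisplacementField(shell_image.origin, shell_image.spacing, warp(centers))
    u_inv = invert_displacement(u, tol=1e-6)
    # composing forward and inverse displacements returns near zero (checked
    # away from the boundary where sampling clamps)
    inner = (slice(4, -4),) * 3
    phi_inv = centers + u_inv.u
    from fibermap._grid import sample_vector
    back = sample_vector(u.u, u.origin, u.spacing, phi_inv, mode="nearest")
    total = (phi_inv + back - centers)[inner]
    assert np.abs(total).max() < 5e-3


def test_dice_overlap_basics(shell_image):
    assert dice_overlap(shell_image, shell_image) == 1.0
    empty = fm.BinaryImage3D(shell_image.origin, shell_image.spacing,
                             np.zeros(shell_image.dims))
    assert dice_overlap(shell_image, empty) == 0.0
    assert warp_image_by_field(shell_image,
                               DisplacementField.zeros_like(shell_image),
                               shell_image).values.max() <= 1.0
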