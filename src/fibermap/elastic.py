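"""Elastic image registration: SSD + elastic potential, Gauss-Newton,
multiresolution.

The registration finds a displacement field u on the fixed-image grid such
that the moving image sampled at phi(x) = x + u(x) matches the fixed image.
The objective is

    J(u) = D(u) + alpha * S(u)

with D the midpoint-rule sum-of-squared-differences and S a linearized
(Navier-type) elastic energy

    S(u) = sum_x w(x) [ mu/4 * sum_ij (d_i u_j + d_j u_i)^2
                        + lambda/2 * (div u)^2 ] * voxelVolume,

discretized with central differences (second-order one-sided stencils at
the grid boundary) and trapezoidal quadrature weights w.  S vanishes
exactly on infinitesimal rigid fields.  Each Gauss-Newton step solves the
sparse SPD system (J^T J + alpha H) delta = -(grad D + alpha H u) by
Jacobi-preconditioned conjugate gradients and is safeguarded by Armijo
backtracking, so the objective is non-increasing across accepted steps.
A Gaussian image pyramid (sigma = 1 voxel, subsample by 2) provides the
coarse-to-fine schedule; binary images are pre-smoothed at every level so
the image gradient carries information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter
from scipy.sparse.linalg import LinearOperator, cg

from .core import BinaryImage3D, ContentError, DisplacementField
from ._grid import sample_trilinear, sample_vector

__all__ = [
    "RegistrationConfig",
    "ssd",
    "elastic_potential",
    "elastic_operator",
    "build_pyramid",
    "prolong",
    "gauss_newton_level",
    "register",
    "invert_displacement",
    "dice_overlap",
    "warp_image_by_field",
]


@dataclass
class RegistrationConfig:
    """Tunable parameters of the elastic registration.

    alpha : regularization weight (0.1).
    levels : multiresolution levels (4).
    mu, lam : Lame-type weights of the elastic potential (1, 0).
    max_gn_iter : Gauss-Newton iterations per level (30).
    tol : relative objective-decrease convergence threshold (1e-4).
    max_halvings : Armijo step halvings before giving up (10).
    cg_tol, cg_maxiter : inner conjugate-gradient controls.
    smooth_sigma : Gaussian pre-smoothing of the images, in voxels (1).
    """

    alpha: float = 0.1
    levels: int = 4
    mu: float = 1.0
    lam: float = 0.0
    max_gn_iter: int = 30
    tol: float = 1e-4
    max_halvings: int = 10
    cg_tol: float = 1e-8
    cg_maxiter: int = 200
    smooth_sigma: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ContentError("alpha must be positive")
        if self.levels < 1:
            raise ContentError("need at least one pyramid level")


# ----------------------------------------------------------------------
# similarity
# ----------------------------------------------------------------------

def ssd(I_moving: BinaryImage3D, u: DisplacementField, I_fixed: BinaryImage3D) -> float:
    """Midpoint-rule SSD: 0.5 * sum (I_m(phi(x)) - I_f(x))^2 * voxelVolume.

    The moving image is sampled trilinearly at phi(x) = x + u(x) in world
    coordinates (0 outside its domain); x runs over the fixed grid, which
    must coincide with the grid of u.
    """
    if not u.matches_grid(I_fixed):
        raise ContentError("displacement grid must match the fixed image grid")
    phi = I_fixed.voxel_centers() + u.u
    mov = sample_trilinear(I_moving.values, I_moving.origin, I_moving.spacing, phi)
    r = mov - I_fixed.values
    return 0.5 * float(np.sum(r * r)) * I_fixed.voxel_volume


# ----------------------------------------------------------------------
# elastic potential
# ----------------------------------------------------------------------

_EDGE3 = np.array([-1.5, 2.0, -0.5])
_EDGE4 = np.array([-11.0 / 6.0, 3.0, -1.5, 1.0 / 3.0])


def _diff_matrix(n: int, h: float) -> sp.csr_matrix:
    """1-D derivative: central interior, one-sided edges.

    Edge rows use the third-order 4-point stencil where the grid allows,
    so the edge error stays subordinate to the interior O(h^2) term.
    """
    if n == 1:
        return sp.csr_matrix((1, 1))
    D = sp.lil_matrix((n, n))
    if n == 2:
        D[0, :] = [-1, 1]
        D[1, :] = [-1, 1]
    else:
        for i in range(1, n - 1):
            D[i, i - 1], D[i, i + 1] = -0.5, 0.5
        edge = _EDGE4 if n >= 4 else _EDGE3
        for j, c in enumerate(edge):
            D[0, j] = c
            D[-1, n - 1 - j] = -c
    return (D / h).tocsr()


def _axis_derivative_dense(arr: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Dense counterpart of ``_diff_matrix`` applied along one axis."""
    n = arr.shape[axis]
    if n == 1:
        return np.zeros_like(arr)
    a = np.moveaxis(arr, axis, 0)
    out = np.empty_like(a)
    if n == 2:
        out[:] = (a[1] - a[0]) / h
    else:
        out[1:-1] = (a[2:] - a[:-2]) / (2 * h)
        edge = _EDGE4 if n >= 4 else _EDGE3
        lo = sum(c * a[j] for j, c in enumerate(edge))
        hi = -sum(c * a[n - 1 - j] for j, c in enumerate(edge))
        out[0] = lo / h
        out[-1] = hi / h
    return np.moveaxis(out, 0, axis)


def _axis_derivative_ops(dims, spacing):
    """Sparse d/dx_i on the C-order flattened scalar grid, i = 0, 1, 2."""
    eye = [sp.identity(n, format="csr") for n in dims]
    Ds = [_diff_matrix(n, h) for n, h in zip(dims, spacing)]
    return [
        sp.kron(sp.kron(Ds[0], eye[1]), eye[2]).tocsr(),
        sp.kron(sp.kron(eye[0], Ds[1]), eye[2]).tocsr(),
        sp.kron(sp.kron(eye[0], eye[1], format="csr"), Ds[2]).tocsr(),
    ]


def _quad_weights(dims) -> np.ndarray:
    """Trapezoidal product weights, flattened C-order."""
    ws = []
    for n in dims:
        w = np.ones(n)
        if n > 1:
            w[0] = w[-1] = 0.5
        ws.append(w)
    return (ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]).ravel()


_H_CACHE: dict = {}


def elastic_operator(dims, spacing, mu: float = 1.0, lam: float = 0.0) -> sp.csr_matrix:
    """Sparse Hessian H of the elastic potential: S(u) = 0.5 * U^T H U.

    U is the component-major flattening [u_x; u_y; u_z] of the grid field.
    The operator is cached per (dims, spacing, mu, lam).
    """
    key = (tuple(int(n) for n in dims), tuple(round(float(h), 12) for h in spacing),
           float(mu), float(lam))
    if key in _H_CACHE:
        return _H_CACHE[key]
    D = _axis_derivative_ops(dims, spacing)
    n = int(np.prod(dims))
    w = _quad_weights(dims) * float(np.prod(spacing))
    W = sp.diags(w)
    Z = sp.csr_matrix((n, n))

    def block_row(mats):
        return sp.hstack(mats, format="csr")

    terms = []
    for i in range(3):  # mu * (d_i u_i)^2
        row = [Z, Z, Z]
        row[i] = D[i]
        terms.append((mu, block_row(row)))
    for i in range(3):  # mu/2 * (d_i u_j + d_j u_i)^2, i<j
        for j in range(i + 1, 3):
            row = [Z, Z, Z]
            row[j] = D[i]
            row[i] = D[j]
            terms.append((mu / 2.0, block_row(row)))
    terms.append((lam / 2.0, block_row([D[0], D[1], D[2]])))  # divergence

    H = sp.csr_matrix((3 * n, 3 * n))
    for c, L in terms:
        if c != 0.0:
            H = H + (2.0 * c) * (L.T @ W @ L)
    H = H.tocsr()
    if len(_H_CACHE) > 16:
        _H_CACHE.clear()
    _H_CACHE[key] = H
    return H


def _flatten_u(u: np.ndarray) -> np.ndarray:
    return np.concatenate([u[..., c].ravel() for c in range(3)])


def _unflatten_u(U: np.ndarray, dims) -> np.ndarray:
    n = int(np.prod(dims))
    return np.stack([U[c * n:(c + 1) * n].reshape(dims) for c in range(3)], axis=-1)


def elastic_potential(u: DisplacementField, mu: float = 1.0, lam: float = 0.0) -> float:
    """Linearized elastic energy of a grid displacement field.

    Zero exactly for constant translations and infinitesimal rotations;
    converges to the continuum integral at second order under refinement.
    """
    dims = u.dims
    vol = float(np.prod(u.spacing))
    w = _quad_weights(dims).reshape(dims)
    grads = [
        [_axis_derivative_dense(u.u[..., c], u.spacing[i], i) for i in range(3)]
        for c in range(3)
    ]
    # grads[j][i] = d_i u_j
    acc = np.zeros(dims)
    for i in range(3):
        for j in range(3):
            acc += 0.25 * mu * (grads[j][i] + grads[i][j]) ** 2
    div = grads[0][0] + grads[1][1] + grads[2][2]
    acc += 0.5 * lam * div * div
    return float(np.sum(w * acc)) * vol


# ----------------------------------------------------------------------
# pyramid
# ----------------------------------------------------------------------

def build_pyramid(image: BinaryImage3D, levels: int) -> list[BinaryImage3D]:
    """Gaussian pyramid, fine to coarse; level 0 is the original image.

    Each coarser level smooths the previous one (normalized Gaussian,
    sigma = 1 voxel) and subsamples by 2 per axis, doubling the voxel size.
    """
    out = [image]
    for _ in range(1, levels):
        prev = out[-1]
        sm = gaussian_filter(prev.values, sigma=1.0, mode="nearest")
        vals = sm[::2, ::2, ::2]
        out.append(BinaryImage3D(prev.origin.copy(), prev.spacing * 2.0,
                                 np.clip(vals, 0.0, 1.0)))
    return out


def prolong(u_coarse: DisplacementField, fine: BinaryImage3D) -> DisplacementField:
    """Trilinear interpolation of a displacement field onto a finer grid.

    Displacements are physical (mm), so only the sampling locations change;
    linear fields are reproduced exactly inside the coarse-grid hull.
    """
    pts = fine.voxel_centers()
    u = sample_vector(u_coarse.u, u_coarse.origin, u_coarse.spacing, pts, mode="nearest")
    return DisplacementField(fine.origin.copy(), fine.spacing.copy(), u)


# ----------------------------------------------------------------------
# Gauss-Newton
# ----------------------------------------------------------------------

def gauss_newton_level(I_moving: BinaryImage3D, I_fixed: BinaryImage3D,
                       u_init: DisplacementField, config: RegistrationConfig,
                       ) -> tuple[DisplacementField, dict]:
    """Minimize D + alpha*S on a single grid level.

    Returns the updated field and an info dict with the per-iteration
    objective values and a ``converged`` flag (False when the line search
    could no longer decrease the objective).
    """
    if not u_init.matches_grid(I_fixed):
        raise ContentError("u grid must match the fixed image grid")
    dims = I_fixed.dims
    vol = I_fixed.voxel_volume
    sig = config.smooth_sigma
    sm_mov = gaussian_filter(I_moving.values, sigma=sig, mode="nearest") if sig > 0 else I_moving.values
    sm_fix = gaussian_filter(I_fixed.values, sigma=sig, mode="nearest") if sig > 0 else I_fixed.values
    eo = 2 if min(I_moving.dims) > 2 else 1
    gm = np.stack(np.gradient(sm_mov, *I_moving.spacing, edge_order=eo), axis=-1)
    centers = I_fixed.voxel_centers()
    H = elastic_operator(dims, I_fixed.spacing, config.mu, config.lam)

    def residual(U):
        phi = centers + _unflatten_u(U, dims)
        mov = sample_trilinear(sm_mov, I_moving.origin, I_moving.spacing, phi)
        return (mov - sm_fix).ravel(), phi

    def objective(U):
        r, phi = residual(U)
        return 0.5 * float(r @ r) * vol + 0.5 * float(U @ (H @ U)), r, phi

    U = _flatten_u(u_init.u)
    obj, r, phi = objective(U)
    history = [obj]
    converged = True
    n = int(np.prod(dims))
    for _ in range(config.max_gn_iter):
        g = sample_vector(gm, I_moving.origin, I_moving.spacing, phi).reshape(n, 3)
        gradD = np.concatenate([(r * g[:, c]) for c in range(3)]) * vol
        rhs = -(gradD + H @ U)
        gg = np.einsum("nc,nd->ncd", g, g) * vol  # per-voxel 3x3 blocks

        def matvec(v, gg=gg):
            V = v.reshape(3, n).T
            jv = np.einsum("ncd,nd->nc", gg, V).T.ravel()
            return jv + H @ v

        diag = np.concatenate([gg[:, c, c] for c in range(3)]) + H.diagonal()
        diag = np.maximum(diag, 1e-12 * max(diag.max(), 1e-30))
        A = LinearOperator((3 * n, 3 * n), matvec=matvec)
        M = LinearOperator((3 * n, 3 * n), matvec=lambda v: v / diag)
        delta, _ = cg(A, rhs, rtol=config.cg_tol, maxiter=config.cg_maxiter, M=M)
        if np.max(np.abs(delta)) < 1e-6 * float(np.min(I_fixed.spacing)):
            break  # at a stationary point: nothing left to move
        descent = float(rhs @ delta)
        if not np.isfinite(descent) or descent <= 0:
            break
        step = 1.0
        accepted = False
        for _ in range(config.max_halvings + 1):
            cand = U + step * delta
            new_obj, new_r, new_phi = objective(cand)
            if new_obj <= obj - 1e-4 * step * descent:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # distinguish a genuine stall from numerical exhaustion of a
            # level that already made good progress
            if len(history) > 1 and history[-1] <= history[0] * (1 - config.tol):
                break
            converged = False
            break
        rel = (obj - new_obj) / max(abs(history[0]), 1e-30)
        U, obj, r, phi = cand, new_obj, new_r, new_phi
        history.append(obj)
        if rel < config.tol:
            break
    u_out = DisplacementField(u_init.origin.copy(), u_init.spacing.copy(),
                              _unflatten_u(U, dims))
    return u_out, {"objective": history, "converged": converged}


def register(I_moving: BinaryImage3D, I_fixed: BinaryImage3D,
             config: RegistrationConfig | None = None,
             return_info: bool = False):
    """Full coarse-to-fine registration of the moving onto the fixed image.

    Builds the Gaussian pyramid of both images, runs Gauss-Newton at each
    level starting from the prolonged coarser result, and returns the
    displacement field on the finest (fixed) grid.
    """
    config = config or RegistrationConfig()
    pyr_m = build_pyramid(I_moving, config.levels)
    pyr_f = build_pyramid(I_fixed, config.levels)
    u = DisplacementField.zeros_like(pyr_f[-1])
    info = {"levels": []}
    for lvl in range(config.levels - 1, -1, -1):
        u, lvl_info = gauss_newton_level(pyr_m[lvl], pyr_f[lvl], u, config)
        lvl_info["level"] = lvl
        info["levels"].append(lvl_info)
        if not lvl_info["converged"]:
            warnings.warn(f"registration level {lvl}: line search stalled; "
                          "continuing with partial result")
        if lvl > 0:
            u = prolong(u, pyr_f[lvl - 1])
    if return_info:
        return u, info
    return u


# ----------------------------------------------------------------------
# utilities
# ----------------------------------------------------------------------

def invert_displacement(field: DisplacementField, tol: float = 1e-3,
                        max_iter: int = 100) -> DisplacementField:
    """Displacement of the inverse map phi^{-1}, on the same grid.

    Solved per voxel center y by fixed-point iteration x <- y - u(x)
    (u sampled trilinearly, edge-clamped), to ``tol`` mm.
    """
    y = np.stack(np.meshgrid(
        *[field.origin[d] + field.spacing[d] * np.arange(field.dims[d]) for d in range(3)],
        indexing="ij"), axis=-1)
    x = y.copy()
    for _ in range(max_iter):
        x_new = y - sample_vector(field.u, field.origin, field.spacing, x, mode="nearest")
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return DisplacementField(field.origin.copy(), field.spacing.copy(), x - y)


def dice_overlap(a: BinaryImage3D, b: BinaryImage3D, threshold: float = 0.5) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of two same-grid occupancy images."""
    if not a.same_grid(b):
        raise ContentError("images must share a grid for Dice overlap")
    A = a.values > threshold
    B = b.values > threshold
    denom = A.sum() + B.sum()
    return 2.0 * float(np.logical_and(A, B).sum()) / float(denom) if denom else 1.0


def warp_image_by_field(I_moving: BinaryImage3D, u: DisplacementField,
                        I_fixed: BinaryImage3D) -> BinaryImage3D:
    """Resample the moving image onto the fixed grid through phi = id + u."""
    if not u.matches_grid(I_fixed):
        raise ContentError("displacement grid must match the fixed image grid")
    phi = I_fixed.voxel_centers() + u.u
    vals = sample_trilinear(I_moving.values, I_moving.origin, I_moving.spacing, phi)
    return BinaryImage3D(I_fixed.origin.copy(), I_fixed.spacing.copy(),
                         np.clip(vals, 0.0, 1.0))
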