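"""Node interpolation, deformation gradients, and fiber reorientation/transfer.

After registration, the voxel displacement field is carried to mesh nodes
by inverse-distance weighting (IDW) of the nearest voxel centers.  The
per-node deformation gradient combines the affine linear part with the
Jacobian of the displacement field and reorients the atlas fibers, either
by the rotation of its polar decomposition (finite strain) or by the full
gradient followed by renormalization (preservation of principal
directions).  Reoriented fibers are transferred to the patient surface by
IDW over the nearest deformed-atlas nodes with explicit handling of the
f = -f sign ambiguity, then projected onto the surface tangent plane.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    AffineTransform,
    ContentError,
    DisplacementField,
    FiberField,
    TetMesh,
    normalize_rows,
)

__all__ = [
    "idw_interpolate",
    "idw_field_at_points",
    "deformation_gradient_at_nodes",
    "reorient_fiber",
    "transfer_fibers",
    "project_tangential",
    "surface_normals",
    "fiber_error",
    "fill_from_nearest",
]

_EXACT_HIT = 1e-9


def idw_interpolate(src_points, src_values, query_points, k: int = 8, p: float = 2.0):
    """Inverse-distance-weighted average over the k nearest source points.

    value(q) = sum w_i v_i / sum w_i with w_i = 1/d_i^p; a query closer
    than 1e-9 to a source point returns that point's value exactly.
    """
    if k < 1:
        raise ContentError("k must be >= 1")
    src_points = np.atleast_2d(np.asarray(src_points, dtype=float))
    src_values = np.asarray(src_values, dtype=float)
    query = np.atleast_2d(np.asarray(query_points, dtype=float))
    k = min(k, len(src_points))
    tree = cKDTree(src_points)
    d, j = tree.query(query, k=k)
    d = np.atleast_2d(d.reshape(len(query), k))
    j = np.atleast_2d(j.reshape(len(query), k))
    vals = src_values[j]  # (Q, k, C...) or (Q, k)
    exact = d[:, 0] < _EXACT_HIT
    w = 1.0 / np.maximum(d, _EXACT_HIT) ** p
    wsum = w.sum(axis=1)
    if src_values.ndim == 1:
        out = (w * vals).sum(axis=1) / wsum
        out[exact] = src_values[j[exact, 0]]
    else:
        out = np.einsum("qk,qk...->q...", w, vals) / wsum.reshape((-1,) + (1,) * (vals.ndim - 2))
        out[exact] = src_values[j[exact, 0]]
    return out


def idw_field_at_points(field: DisplacementField, points, k: int = 8, p: float = 2.0):
    """IDW interpolation of a grid vector field at world-coordinate points.

    Points must lie within the (padded) grid: at most one voxel beyond the
    outermost voxel centers.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    lo = field.origin - field.spacing
    hi = field.origin + field.spacing * np.asarray(field.dims)
    if np.any(points < lo) or np.any(points > hi):
        raise ContentError("points fall outside the displacement grid")
    centers = np.stack(np.meshgrid(
        *[field.origin[d] + field.spacing[d] * np.arange(field.dims[d]) for d in range(3)],
        indexing="ij"), axis=-1).reshape(-1, 3)
    return idw_interpolate(centers, field.u.reshape(-1, 3), points, k=k, p=p)


def displacement_jacobian(field: DisplacementField) -> np.ndarray:
    """du/dx on the voxel grid by central differences, shape dims + (3, 3).

    Entry [..., i, j] is d u_i / d x_j.
    """
    eo = 2 if min(field.dims) > 2 else 1
    J = np.empty(field.dims + (3, 3))
    for i in range(3):
        g = np.gradient(field.u[..., i], *field.spacing, edge_order=eo)
        for j in range(3):
            J[..., i, j] = g[j]
    return J


def deformation_gradient_at_nodes(affine: AffineTransform, u: DisplacementField,
                                  nodes, k: int = 8, p: float = 2.0,
                                  order: str = "affine@elastic"):
    """Per-node deformation gradient combining affine and elastic parts.

    The Jacobian of u is computed by central differences on the voxel grid
    and IDW-interpolated to the nodes; then

        F = A (I + du/dx)   (order="affine@elastic", the default), or
        F = (I + du/dx) A   (order="elastic@affine": the chain rule when
                             the affine was applied to the points before
                             the elastic map).

    Nodes where det F <= 0 fall back to F = A and are reported.

    Returns
    -------
    F : (N, 3, 3) array
    warn_nodes : list of node indices where the fallback was taken.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    J = displacement_jacobian(u).reshape(-1, 9)
    field = DisplacementField(u.origin, u.spacing, u.u)
    # reuse the IDW machinery on the 9 Jacobian components
    centers = np.stack(np.meshgrid(
        *[field.origin[d] + field.spacing[d] * np.arange(field.dims[d]) for d in range(3)],
        indexing="ij"), axis=-1).reshape(-1, 3)
    Jn = idw_interpolate(centers, J, nodes, k=k, p=p).reshape(-1, 3, 3)
    G = np.eye(3) + Jn
    if order == "affine@elastic":
        F = np.einsum("ij,njk->nik", affine.A, G)
    elif order == "elastic@affine":
        F = np.einsum("nij,jk->nik", G, affine.A)
    else:
        raise ContentError(f"unknown composition order {order!r}")
    det = np.linalg.det(F)
    warn_nodes = np.nonzero(det <= 0)[0]
    F[warn_nodes] = affine.A
    return F, list(warn_nodes)


def reorient_fiber(f, F, strategy: str = "principal_directions"):
    """Reorient unit fibers by a deformation gradient.

    finite_strain : f' = R f with F = R U the polar decomposition (R from
        the SVD of F with determinant-sign correction).
    principal_directions : f' = F f / ||F f||, the default rule here,
        which keeps the stretch-induced direction change.

    Both accept a single fiber/gradient or stacked arrays.
    """
    f = np.atleast_2d(np.asarray(f, dtype=float))
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    F = F.reshape(-1, 3, 3)
    if len(f) == 1 and len(F) > 1:
        f = np.repeat(f, len(F), axis=0)
    if strategy == "principal_directions":
        out = np.einsum("nij,nj->ni", F, f)
        nrm = np.linalg.norm(out, axis=1)
        if np.any(nrm < 1e-12):
            raise ContentError("degenerate mapping: F f vanished")
        out = out / nrm[:, None]
    elif strategy == "finite_strain":
        U, _, Vt = np.linalg.svd(F)
        d = np.sign(np.linalg.det(np.einsum("nij,njk->nik", U, Vt)))
        U[:, :, 2] *= d[:, None]
        R = np.einsum("nij,njk->nik", U, Vt)
        out = np.einsum("nij,nj->ni", R, f)
    else:
        raise ContentError(f"unknown reorientation strategy {strategy!r}")
    return out[0] if single and len(out) == 1 else out


def transfer_fibers(deformed_atlas_nodes, atlas_fibers: FiberField,
                    patient_surface_nodes, k: int = 8, p: float = 2.0,
                    ) -> tuple[FiberField, np.ndarray]:
    """IDW transfer of fibers from deformed-atlas nodes to patient nodes.

    For each patient node the k nearest deformed-atlas fibers are gathered;
    the sign ambiguity is resolved by flipping every neighbor fiber into
    the hemisphere of the nearest neighbor's fiber before averaging.
    Queries coincident with an atlas node (within 1e-9 mm) copy that
    node's fiber.  Nodes whose average cancels below 1e-6 are flagged and
    filled from the nearest resolved patient node.

    Returns the patient-surface fiber field and the flag array.
    """
    src = np.atleast_2d(np.asarray(deformed_atlas_nodes, dtype=float))
    qry = np.atleast_2d(np.asarray(patient_surface_nodes, dtype=float))
    if len(src) == 0 or len(qry) == 0:
        raise ContentError("empty node sets")
    fib = np.asarray(atlas_fibers.vectors, dtype=float)
    if not atlas_fibers.defined_mask.all():
        keep = atlas_fibers.defined_mask
        src, fib = src[keep], fib[keep]
    k = min(k, len(src))
    tree = cKDTree(src)
    d, j = tree.query(qry, k=k)
    d = d.reshape(len(qry), k)
    j = j.reshape(len(qry), k)
    neigh = fib[j]  # (Q, k, 3)
    ref = neigh[:, 0:1, :]
    sign = np.where(np.sum(neigh * ref, axis=2, keepdims=True) < 0, -1.0, 1.0)
    neigh = neigh * sign
    w = 1.0 / np.maximum(d, _EXACT_HIT) ** p
    avg = np.einsum("qk,qkc->qc", w, neigh) / w.sum(axis=1)[:, None]
    exact = d[:, 0] < _EXACT_HIT
    avg[exact] = fib[j[exact, 0]]
    nrm = np.linalg.norm(avg, axis=1)
    flagged = nrm < 1e-6
    out = np.zeros_like(avg)
    out[~flagged] = avg[~flagged] / nrm[~flagged, None]
    if flagged.any():
        out = fill_from_nearest(qry, out, ~flagged)
    return FiberField(out), flagged


def project_tangential(f, node_normals):
    """Project unit fibers onto the tangent plane of unit surface normals.

    f' = normalize(f - (f.n) n).  Fibers within 1e-6 of the normal are
    degenerate: they are flagged and returned as zero rows for the caller
    to fill (see ``fill_from_nearest``).
    """
    f = np.atleast_2d(np.asarray(f, dtype=float))
    n = np.atleast_2d(np.asarray(node_normals, dtype=float))
    tang = f - np.sum(f * n, axis=1, keepdims=True) * n
    nrm = np.linalg.norm(tang, axis=1)
    flagged = nrm < 1e-6
    out = np.zeros_like(tang)
    out[~flagged] = tang[~flagged] / nrm[~flagged, None]
    return (out[0], bool(flagged[0])) if len(out) == 1 and np.asarray(f).ndim == 1 else (out, flagged)


def fill_from_nearest(positions, vectors, valid_mask):
    """Replace invalid rows by the value at the nearest valid position."""
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if valid_mask.all():
        return vectors
    if not valid_mask.any():
        raise ContentError("no valid entries to fill from")
    positions = np.asarray(positions, dtype=float)
    out = np.array(vectors, dtype=float, copy=True)
    tree = cKDTree(positions[valid_mask])
    _, j = tree.query(positions[~valid_mask])
    out[~valid_mask] = out[valid_mask][j]
    return out


def surface_normals(mesh: TetMesh, tag: str, outward: bool = True) -> np.ndarray:
    """Per-node unit normals of a tagged surface.

    Area-weighted average of incident boundary-triangle normals, oriented
    by the sign of normal . (node - shell centroid) (outward for closed
    shells).  Returns an (N_mesh, 3) array that is zero off the surface.
    """
    if tag not in mesh.surface_tags:
        raise ContentError(f"mesh has no surface tag {tag!r}")
    tag_nodes = mesh.surface_tags[tag]
    on_tag = np.zeros(len(mesh.nodes), dtype=bool)
    on_tag[tag_nodes] = True
    faces = mesh.boundary_faces()
    faces = faces[np.all(on_tag[faces], axis=1)]
    if len(faces) == 0:
        raise ContentError(f"surface {tag!r} has no boundary faces")
    x = mesh.nodes[faces]
    fn = 0.5 * np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])  # area-weighted
    normals = np.zeros((len(mesh.nodes), 3))
    np.add.at(normals, faces.ravel(), np.repeat(fn, 3, axis=0))
    normals = normalize_rows(normals)
    centroid = mesh.nodes.mean(axis=0)
    sgn = np.sign(np.sum(normals * (mesh.nodes - centroid), axis=1))
    sgn[sgn == 0] = 1.0
    if not outward:
        sgn = -sgn
    normals *= sgn[:, None]
    return normals


def fiber_error(f_mapped, f_defined) -> np.ndarray:
    """Sign-agnostic angular mismatch: err = 1 - |f_mapped . f_defined|.

    0 for parallel or antiparallel fibers, 1 for orthogonal ones.
    """
    a = np.atleast_2d(np.asarray(f_mapped, dtype=float))
    b = np.atleast_2d(np.asarray(f_defined, dtype=float))
    err = 1.0 - np.abs(np.sum(a * b, axis=1))
    return float(err[0]) if err.shape == (1,) and np.asarray(f_mapped).ndim == 1 else err
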