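"""Binary occupancy images from tetrahedral meshes.

The registration operates on binary voxel images of the shells (0.6 mm
voxels by default).  A voxel is set iff its center lies inside some tet;
an optional morphological dilation reproduces the slight wall thickening
that a binary rasterization of a thin wall exhibits.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .core import BinaryImage3D, ContentError, TetMesh

__all__ = ["voxelize", "point_in_tets"]

_BARY_TOL = 1e-9


def _tet_inverses(mesh: TetMesh):
    x = mesh.nodes[mesh.tets]
    T = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=-1)
    return x[:, 0], np.linalg.inv(T)


def _inside_one(p, x0, Tinv):
    """Inclusive barycentric test of points p against a single tet."""
    lam = (p - x0) @ Tinv.T
    return (lam.min(axis=1) >= -_BARY_TOL) & (lam.sum(axis=1) <= 1 + _BARY_TOL)


def point_in_tets(points: np.ndarray, mesh: TetMesh, brute_force: bool = False) -> np.ndarray:
    """Boolean per point: does it lie inside any tetrahedron?

    The accelerated path gathers candidate points per tet from a KD-tree
    ball query around the tet centroid; it is exactly equivalent to the
    all-tets brute-force scan.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x0, Tinv = _tet_inverses(mesh)
    out = np.zeros(len(points), dtype=bool)
    if brute_force:
        for t in range(len(mesh.tets)):
            todo = ~out
            if not todo.any():
                break
            out[todo] |= _inside_one(points[todo], x0[t], Tinv[t])
        return out
    verts = mesh.nodes[mesh.tets]
    centroids = verts.mean(axis=1)
    radii = np.linalg.norm(verts - centroids[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(points)
    for t, (c, r) in enumerate(zip(centroids, radii)):
        cand = tree.query_ball_point(c, r + 1e-9)
        if not cand:
            continue
        cand = np.asarray(cand)
        cand = cand[~out[cand]]
        if len(cand):
            out[cand[_inside_one(points[cand], x0[t], Tinv[t])]] = True
    return out


def voxelize(mesh: TetMesh, spacing: float = 0.6, padding: int = 8,
             dilate: int = 1, origin=None, dims=None) -> BinaryImage3D:
    """Rasterize a tet mesh to a binary occupancy image.

    Parameters
    ----------
    spacing : isotropic voxel size in mm (default 0.6).
    padding : empty voxels added around the mesh bounding box (default 8).
    dilate : morphological dilation radius in voxels applied after the
        inside test (default 1; models the slightly thickened binary wall).
    origin, dims : force a specific grid (both or neither), e.g. to put an
        atlas and a patient shell on one common image cube.
    """
    if spacing <= 0:
        raise ContentError("spacing must be positive")
    mesh.validate()
    lo, hi = mesh.bounds
    if dilate == 0:
        h = np.linalg.norm(mesh.nodes[mesh.tets][:, 1:] - mesh.nodes[mesh.tets][:, :1],
                           axis=2).max()
        if spacing > h:
            warnings.warn("spacing exceeds element size with dilate=0; wall may disconnect")
    sp = np.full(3, float(spacing))
    if origin is not None or dims is not None:
        if origin is None or dims is None:
            raise ContentError("origin and dims must be given together")
        origin = np.asarray(origin, dtype=float).reshape(3)
        dims = np.asarray(dims, dtype=int).reshape(3)
    else:
        n_inner = np.ceil((hi - lo) / sp).astype(int) + 1
        origin = lo - padding * sp
        dims = n_inner + 2 * padding
    occ = np.zeros(dims, dtype=bool)

    x0, Tinv = _tet_inverses(mesh)
    verts = mesh.nodes[mesh.tets]
    blo = np.floor((verts.min(axis=1) - origin) / sp).astype(int)
    bhi = np.ceil((verts.max(axis=1) - origin) / sp).astype(int)
    blo = np.clip(blo, 0, dims - 1)
    bhi = np.clip(bhi, 0, dims - 1)
    for t in range(len(mesh.tets)):
        sl = tuple(slice(blo[t, d], bhi[t, d] + 1) for d in range(3))
        sub = occ[sl]
        if sub.all():
            continue
        axes = [origin[d] + sp[d] * np.arange(blo[t, d], bhi[t, d] + 1) for d in range(3)]
        centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        inside = _inside_one(centers, x0[t], Tinv[t]).reshape(sub.shape)
        occ[sl] = sub | inside
    if dilate > 0:
        occ = binary_dilation(occ, iterations=int(dilate))
    return BinaryImage3D(origin, sp, occ.astype(float))
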