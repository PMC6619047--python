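"""Harmonic lifting of surface fiber data into the wall volume.

Each Cartesian component of the surface fiber field is extended into the
mesh interior as a discrete harmonic function (linear tetrahedral finite
elements, Dirichlet data on the endo/epi nodes, natural zero-flux
conditions on any other boundary such as orifice rims); the lifted vector
is then renormalized per node.  Because fibers are sign-agnostic, the
boundary data are first made locally sign-consistent by a breadth-first
sweep, which prevents antipodal representatives from cancelling in the
interior.  Also implements the atlas-style region-based fiber definition
(constant direction per surface region, projected tangentially).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, cg

from .core import ContentError, FiberField, RegionFiberSpec, TetMesh, normalize_rows
from .mapping import fill_from_nearest, project_tangential, surface_normals

__all__ = ["assign_region_fibers", "harmonic_lift", "stiffness_matrix", "make_signs_consistent"]

_DIRECT_LIMIT = 200_000  # unknowns; direct sparse LU below, CG above


def stiffness_matrix(mesh: TetMesh) -> sp.csr_matrix:
    """P1 finite-element Laplace stiffness matrix (symmetric PSD)."""
    x = mesh.nodes[mesh.tets]
    T = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=1)
    vol = np.abs(np.linalg.det(T)) / 6.0
    Tinv = np.linalg.inv(T)  # rows of Tinv.T are grad lambda_{1,2,3}
    g = np.empty((len(mesh.tets), 4, 3))
    g[:, 1:, :] = np.transpose(Tinv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    K_loc = np.einsum("tid,tjd,t->tij", g, g, vol)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix((K_loc.ravel(), (rows, cols)),
                      shape=(len(mesh.nodes), len(mesh.nodes)))
    return K.tocsr()


def make_signs_consistent(mesh: TetMesh, vectors: np.ndarray,
                          node_mask: np.ndarray) -> np.ndarray:
    """Flip f -> -f along a BFS over mesh edges so neighbors agree in sign.

    Only nodes selected by ``node_mask`` participate; each is flipped, if
    needed, to lie in the hemisphere of the already-visited neighbor that
    discovered it.
    """
    vectors = np.array(vectors, dtype=float, copy=True)
    idx = np.nonzero(node_mask)[0]
    pos = -np.ones(len(mesh.nodes), dtype=np.int64)
    pos[idx] = np.arange(len(idx))
    e = pos[mesh.edges()]
    e = e[(e >= 0).all(axis=1)]
    both = np.vstack([e, e[:, ::-1]])
    A = sp.csr_matrix((np.ones(len(both)), (both[:, 0], both[:, 1])),
                      shape=(len(idx), len(idx)))
    indptr, indices = A.indptr, A.indices
    visited = np.zeros(len(idx), dtype=bool)
    for start in range(len(idx)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        while stack:
            i = stack.pop()
            for jn in indices[indptr[i]:indptr[i + 1]]:
                if not visited[jn]:
                    visited[jn] = True
                    if vectors[idx[jn]] @ vectors[idx[i]] < 0:
                        vectors[idx[jn]] = -vectors[idx[jn]]
                    stack.append(jn)
    return vectors


def harmonic_lift(mesh: TetMesh, dirichlet: FiberField,
                  sign_sweep: bool = True, return_raw: bool = False):
    """Extend surface fibers into the volume by componentwise Laplace solves.

    Parameters
    ----------
    dirichlet : fiber field over all mesh nodes whose ``defined_mask``
        marks the Dirichlet (endo/epi) nodes; values elsewhere are ignored.
    sign_sweep : make the boundary data sign-consistent first (recommended).
    return_raw : also return the pre-normalization components and flags.

    Returns the lifted, renormalized fiber field on all nodes (and, with
    ``return_raw``, the raw harmonic components plus the flags of interior
    nodes whose lifted vector cancelled below 1e-6 and was filled from the
    nearest resolved node).  The lifted field restricted to Dirichlet
    nodes equals the input data exactly; each raw component satisfies the
    discrete maximum principle on well-shaped meshes.
    """
    if len(dirichlet) != len(mesh.nodes):
        raise ContentError("dirichlet field must cover all mesh nodes")
    fixed = np.asarray(dirichlet.defined_mask, dtype=bool)
    if not fixed.any():
        raise ContentError("no Dirichlet nodes: the harmonic system is singular")
    data = dirichlet.vectors
    if sign_sweep:
        data = make_signs_consistent(mesh, data, fixed)
    K = stiffness_matrix(mesh)
    free = ~fixed
    v = np.array(data, dtype=float, copy=True)
    v[free] = 0.0
    nf = int(free.sum())
    if nf:
        Kff = K[free][:, free].tocsc()
        rhs = -K[free][:, fixed] @ data[fixed]
        if nf <= _DIRECT_LIMIT:
            lu = splu(Kff)
            sol = np.column_stack([lu.solve(rhs[:, c]) for c in range(3)])
        else:
            sol = np.empty((nf, 3))
            for c in range(3):
                sol[:, c], info = cg(Kff, rhs[:, c], rtol=1e-10, maxiter=5000)
                if info != 0:
                    raise ContentError("harmonic CG solve did not converge")
        v[free] = sol
    nrm = np.linalg.norm(v, axis=1)
    flagged = nrm < 1e-6
    unit = np.zeros_like(v)
    unit[~flagged] = v[~flagged] / nrm[~flagged, None]
    if flagged.any():
        unit = fill_from_nearest(mesh.nodes, unit, ~flagged)
    out = FiberField(unit)
    if return_raw:
        return out, v, flagged
    return out


def assign_region_fibers(mesh: TetMesh, spec: RegionFiberSpec, tag: str) -> FiberField:
    """Constant fiber direction per region on a tagged surface.

    ``spec.node_labels`` is aligned with ``mesh.surface_tags[tag]``.  Each
    node receives its region's direction, projected onto the surface
    tangent plane and normalized; nodes where the direction is (near)
    normal to the surface are filled from the nearest resolved node of the
    same surface.  Returns a field over all mesh nodes whose mask marks
    the tagged surface.
    """
    if tag not in mesh.surface_tags:
        raise ContentError(f"mesh has no surface tag {tag!r}")
    nodes = mesh.surface_tags[tag]
    labels = spec.node_labels
    if len(labels) != len(nodes):
        raise ContentError("node_labels must align with the tagged node set")
    missing = sorted({str(l) for l in labels if l not in spec.directions})
    if missing:
        raise ContentError(f"regions without a direction: {missing}")
    raw = np.stack([spec.directions[l] for l in labels])
    normals = surface_normals(mesh, tag)[nodes]
    proj, flags = project_tangential(raw, normals)
    if np.asarray(flags).any():
        proj = fill_from_nearest(mesh.nodes[nodes], proj, ~np.asarray(flags))
    vectors = np.zeros((len(mesh.nodes), 3))
    mask = np.zeros(len(mesh.nodes), dtype=bool)
    vectors[nodes] = proj
    mask[nodes] = True
    return FiberField(vectors, mask)
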