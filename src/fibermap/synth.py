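"""Synthetic shell geometries, analytic fiber fields and ground-truth warps.

The generators emulate the geometry this pipeline is built for: thin
(≈2 mm) closed atrial-like shells meshed with tetrahedra, with smooth
shape variation between an "atlas" and a "patient", optional orifices
(vein/valve stand-ins) and bumps (appendage stand-ins).  Everything is
closed-form and seeded, so every downstream stage has an exact oracle:
fibers can be evaluated at arbitrary points and warps carry their own
analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import trimesh

from .core import BinaryImage3D, ContentError, FiberField, LandmarkSet, TetMesh, normalize_rows
from ._grid import sample_trilinear

__all__ = [
    "ShellSpec",
    "Orifice",
    "Bump",
    "SyntheticWarp",
    "make_shell_mesh",
    "make_slab_mesh",
    "AnalyticFiberField",
    "analytic_fibers",
    "shell_landmarks",
    "warp_mesh",
    "warp_image",
    "true_deformation_gradient",
    "verify_diffeomorphic",
]


class ResolutionError(ValueError):
    """Requested element size cannot resolve the shell thickness."""


@dataclass
class Orifice:
    direction: tuple
    angular_radius: float  # radians
    name: str = "orifice"


@dataclass
class Bump:
    direction: tuple
    amplitude: float  # mm, radial
    angular_width: float  # radians (Gaussian sigma on the sphere)


@dataclass
class ShellSpec:
    """Closed two-surface shell: ellipsoidal endocardium extruded outward.

    ``radii`` are the endocardial semi-axes in mm; ``thickness`` is the
    wall thickness (2 mm is the conventional atrial value).
    """

    center: tuple = (0.0, 0.0, 0.0)
    radii: tuple = (15.0, 15.0, 15.0)
    thickness: float = 2.0
    orifices: list = dc_field(default_factory=list)
    bumps: list = dc_field(default_factory=list)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(3)
        if self.thickness <= 0 or np.any(self.radii <= self.thickness):
            raise ContentError("need radii > thickness > 0")
        for a, b in [(x, y) for i, x in enumerate(self.orifices) for y in self.orifices[i + 1:]]:
            da = normalize_rows(np.asarray(a.direction, float)[None])[0]
            db = normalize_rows(np.asarray(b.direction, float)[None])[0]
            if np.arccos(np.clip(da @ db, -1, 1)) < a.angular_radius + b.angular_radius:
                raise ContentError("orifices overlap")

    # generalized endocardial radius along unit direction u (incl. bumps)
    def endo_radius(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        base = 1.0 / np.sqrt(np.sum((u / self.radii) ** 2, axis=-1))
        r = base.copy()
        for b in self.bumps:
            d = normalize_rows(np.asarray(b.direction, float)[None])[0]
            ang = np.arccos(np.clip(u @ d, -1, 1))
            r = r + b.amplitude * np.exp(-((ang / b.angular_width) ** 2))
        return r


def _ellipsoid_normal(spec: ShellSpec, points: np.ndarray) -> np.ndarray:
    return normalize_rows((points - spec.center) / spec.radii**2)


def make_shell_mesh(spec: ShellSpec, target_edge: float = 0.9) -> TetMesh:
    """Structured tetrahedral shell mesh with tagged endo/epi/rim node sets.

    The endocardial surface is an icosphere mapped onto the (bumped)
    ellipsoid; the wall is extruded along the ellipsoid normal in
    ``ceil(thickness/target_edge)`` layers of prisms, each split into three
    tets with globally consistent diagonals.
    """
    if target_edge >= spec.thickness:
        raise ResolutionError("target_edge must be smaller than the wall thickness")
    r_mean = float(np.mean(spec.radii)) + 0.5 * spec.thickness
    sub = int(np.clip(np.ceil(np.log2(1.0515 * r_mean / target_edge)), 1, 6))
    base = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    dirs = np.asarray(base.vertices, dtype=float)
    dirs = normalize_rows(dirs)
    faces = np.asarray(base.faces, dtype=np.int64)

    # remove orifice columns; remember rim base-vertices per orifice
    keep = np.ones(len(faces), dtype=bool)
    removed_sets = {}
    centroids = normalize_rows(dirs[faces].mean(axis=1))
    for o in spec.orifices:
        d = normalize_rows(np.asarray(o.direction, float)[None])[0]
        ang = np.arccos(np.clip(centroids @ d, -1, 1))
        inside = ang < o.angular_radius
        removed_sets[o.name] = inside
        keep &= ~inside

    layers = max(1, int(np.ceil(spec.thickness / target_edge)))
    nb = len(dirs)
    endo_pts = spec.center + dirs * spec.endo_radius(dirs)[:, None]
    normals = _ellipsoid_normal(spec, endo_pts)
    # node (layer l, base v) -> index l*nb + v
    all_nodes = np.concatenate(
        [endo_pts + (l / layers) * spec.thickness * normals for l in range(layers + 1)]
    )

    tets = []
    kept_faces = faces[keep]
    for tri in kept_faces:
        v = np.sort(tri)  # global ordering makes prism diagonals conform
        for l in range(layers):
            b = v + l * nb
            t = v + (l + 1) * nb
            tets.append([b[0], b[1], b[2], t[0]])
            tets.append([b[1], b[2], t[0], t[1]])
            tets.append([b[2], t[0], t[1], t[2]])
    tets = np.array(tets, dtype=np.int64)

    used_base = np.unique(kept_faces)
    tags = {
        "endo": used_base.copy(),
        "epi": used_base + layers * nb,
    }
    for o in spec.orifices:
        rem = faces[removed_sets[o.name]]
        if len(rem):
            rim_base = np.intersect1d(np.unique(rem), used_base)
            rim = np.concatenate([rim_base + l * nb for l in range(layers + 1)])
            tags[f"rim:{o.name}"] = rim

    # prune unused nodes and remap
    used = np.unique(tets)
    remap = -np.ones(len(all_nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = TetMesh(
        all_nodes[used],
        remap[tets],
        {k: remap[v[np.isin(v, used)]] for k, v in tags.items()},
    )
    return mesh.oriented().validate()


def make_slab_mesh(size=(10.0, 10.0, 4.0), h: float = 1.0, origin=(0.0, 0.0, 0.0)) -> TetMesh:
    """Structured slab of cubes, each Kuhn-split into 6 tets.

    Face node sets are tagged ``endo`` (z=0), ``epi`` (z=max) and
    ``face:{x0,x1,y0,y1}``.
    """
    origin = np.asarray(origin, dtype=float)
    n = np.maximum(1, np.round(np.asarray(size, float) / h).astype(int))
    axes = [origin[d] + h * np.arange(n[d] + 1) for d in range(3)]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    shape = G.shape[:3]
    nodes = G.reshape(-1, 3)

    def nid(i, j, k):
        return (i * shape[1] + j) * shape[2] + k

    I, J, K = np.meshgrid(*(np.arange(m) for m in n), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    c = [nid(I + di, J + dj, K + dk) for di, dj, dk in
         [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]]
    # Kuhn split: 6 tets around the (0,0,0)-(1,1,1) diagonal
    paths = [(0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7), (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7)]
    tets = np.concatenate([np.stack([c[a], c[b], c[d], c[e]], axis=1) for a, b, d, e in paths])

    idx = np.arange(len(nodes)).reshape(shape)
    tags = {
        "endo": idx[:, :, 0].ravel(),
        "epi": idx[:, :, -1].ravel(),
        "face:x0": idx[0].ravel(),
        "face:x1": idx[-1].ravel(),
        "face:y0": idx[:, 0].ravel(),
        "face:y1": idx[:, -1].ravel(),
    }
    return TetMesh(nodes, tets, tags).oriented().validate()


# ----------------------------------------------------------------------
# analytic fiber fields
# ----------------------------------------------------------------------

class AnalyticFiberField:
    """Closed-form tangential fiber field on a shell; evaluable anywhere.

    Styles
    ------
    ``circumferential``
        f = normalize(z x n), tangent circles around the z axis.
    ``helical``
        circumferential rotated by ``helix_angle`` towards the meridian.
    ``two-layer``
        helix angle grows linearly from 0 (endo) to 90 deg (epi), so the
        endocardial and epicardial fields are orthogonal at matching
        angular position, mimicking distinct wall layers.
    """

    def __init__(self, spec: ShellSpec, style: str = "circumferential",
                 helix_angle: float = 0.0):
        if style not in ("circumferential", "helical", "two-layer"):
            raise ValueError(f"unknown fiber style {style!r}")
        self.spec = spec
        self.style = style
        self.helix_angle = float(helix_angle)

    def __call__(self, points: np.ndarray, with_flags: bool = False):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        n = _ellipsoid_normal(self.spec, p)
        zxn = np.cross([0.0, 0.0, 1.0], n)
        nrm = np.linalg.norm(zxn, axis=1)
        degenerate = nrm < 1e-8
        # limit rule at the poles: project x-axis onto the tangent plane
        if degenerate.any():
            fallback = np.array([1.0, 0.0, 0.0]) - n[degenerate] * n[degenerate, 0:1]
            zxn[degenerate] = fallback
        e_circ = normalize_rows(zxn)
        if self.style == "circumferential":
            f = e_circ
        else:
            e_merid = normalize_rows(np.cross(n, e_circ))
            if self.style == "helical":
                beta = np.full(len(p), self.helix_angle)
            else:  # two-layer
                u = normalize_rows(p - self.spec.center)
                r_endo = self.spec.endo_radius(u)
                d = np.linalg.norm(p - self.spec.center, axis=1) - r_endo
                s = np.clip(d / self.spec.thickness, 0.0, 1.0)
                beta = s * (np.pi / 2)
            f = np.cos(beta)[:, None] * e_circ + np.sin(beta)[:, None] * e_merid
        f = normalize_rows(f)
        if with_flags:
            return f, degenerate
        return f


def analytic_fibers(mesh: TetMesh, style: str, spec: ShellSpec,
                    helix_angle: float = 0.0) -> tuple[FiberField, np.ndarray]:
    """Evaluate an analytic fiber style at every mesh node.

    Returns the fiber field and a boolean flag array marking nodes where
    the direction was assigned by the pole limit rule.
    """
    if "endo" not in mesh.surface_tags or "epi" not in mesh.surface_tags:
        raise ContentError("mesh must carry endo/epi surface tags")
    fld = AnalyticFiberField(spec, style, helix_angle)
    vecs, flags = fld(mesh.nodes, with_flags=True)
    return FiberField(vecs), flags


def shell_landmarks(spec: ShellSpec, count: int = 13, prefix: str = "lm") -> LandmarkSet:
    """Landmarks at fixed directions on the epicardial surface.

    The directions (poles plus a golden-spiral spread) are the same for
    every spec, so landmark sets from two different shells correspond by
    position — the synthetic stand-in for anatomically matched points.
    """
    ks = np.arange(count - 2)
    z = 1 - 2 * (ks + 0.5) / (count - 2)
    phi = np.pi * (1 + np.sqrt(5.0)) * ks
    ring = np.stack([np.sqrt(1 - z**2) * np.cos(phi), np.sqrt(1 - z**2) * np.sin(phi), z], axis=1)
    dirs = np.vstack([[0, 0, 1.0], [0, 0, -1.0], ring])[:count]
    pts = spec.center + dirs * (spec.endo_radius(dirs) + spec.thickness)[:, None]
    return LandmarkSet([f"{prefix}{i:02d}" for i in range(count)], pts)


# ----------------------------------------------------------------------
# ground-truth warps
# ----------------------------------------------------------------------

@dataclass
class SyntheticWarp:
    """Smooth closed-form displacement: sinusoid modes plus an affine part.

    u(x) = sum_m a_m sin(k_m . x + phi_m) + B x + b, with the analytic
    Jacobian du/dx = sum_m a_m k_m^T cos(k_m . x + phi_m) + B.
    """

    amplitudes: np.ndarray  # (M, 3) mm
    wavevectors: np.ndarray  # (M, 3) rad/mm
    phases: np.ndarray  # (M,)
    B: np.ndarray = dc_field(default_factory=lambda: np.zeros((3, 3)))
    b: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, float))
        self.wavevectors = np.atleast_2d(np.asarray(self.wavevectors, float))
        self.phases = np.atleast_1d(np.asarray(self.phases, float))
        self.B = np.asarray(self.B, float).reshape(3, 3)
        self.b = np.asarray(self.b, float).reshape(3)

    @classmethod
    def smooth(cls, amplitude: float, wavelength: float = 60.0, seed: int = 0,
               n_modes: int = 3) -> "SyntheticWarp":
        """Random low-frequency warp with peak displacement ~ ``amplitude`` mm.

        Mode gains are rescaled so that sum |a||k| <= 0.5, which guarantees
        a positive Jacobian determinant (diffeomorphic at this amplitude).
        """
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n_modes, 3))
        a *= amplitude / np.sum(np.linalg.norm(a, axis=1))
        k = normalize_rows(rng.normal(size=(n_modes, 3))) * (2 * np.pi / wavelength)
        lip = np.sum(np.linalg.norm(a, axis=1) * np.linalg.norm(k, axis=1))
        if lip > 0.5:
            a *= 0.5 / lip
        return cls(a, k, rng.uniform(0, 2 * np.pi, size=n_modes))

    @classmethod
    def smooth_nonaffine(cls, amplitude: float, wavelength: float = 60.0,
                         seed: int = 0, n_modes: int = 3,
                         center=(0.0, 0.0, 0.0), half_extent: float = 20.0,
                         ) -> "SyntheticWarp":
        """Random smooth warp with the affine part removed at ``center``.

        The constant and linear terms of the mode sum are cancelled by the
        affine slot (u(center) = 0, du/dx(center) = 0), leaving the
        genuinely non-affine residual that an elastic registration is
        meant to recover after global alignment; the result is rescaled so
        the peak displacement over the box center +- half_extent equals
        ``amplitude`` mm, backing off (halving) if that would fold the map.
        """
        base = cls.smooth(amplitude, wavelength, seed, n_modes)
        c = np.asarray(center, dtype=float)
        B = -base.jacobian(c)
        b = -(base(c) + B @ c)
        w = cls(base.amplitudes, base.wavevectors, base.phases, B=B, b=b)
        ax = np.linspace(-half_extent, half_extent, 17)
        pts = c + np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
        peak = np.linalg.norm(w(pts), axis=1).max()
        if peak < 1e-12:
            return w
        for scale in (amplitude / peak) * 0.5 ** np.arange(6):
            cand = cls(w.amplitudes * scale, w.wavevectors, w.phases,
                       B=w.B * scale, b=w.b * scale)
            if verify_diffeomorphic(cand, c - half_extent, c + half_extent):
                return cand
        raise ContentError("could not build a diffeomorphic non-affine warp")

    @classmethod
    def translation(cls, t) -> "SyntheticWarp":
        return cls(np.zeros((1, 3)), np.zeros((1, 3)), np.zeros(1), b=np.asarray(t, float))

    @classmethod
    def affine(cls, B, b=(0, 0, 0)) -> "SyntheticWarp":
        """Affine displacement u(x) = B x + b (phi(x) = (I+B) x + b)."""
        return cls(np.zeros((1, 3)), np.zeros((1, 3)), np.zeros(1), B=B, b=np.asarray(b, float))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        flat = np.atleast_2d(x.reshape(-1, 3))
        ph = flat @ self.wavevectors.T + self.phases  # (N, M)
        u = np.sin(ph) @ self.amplitudes + flat @ self.B.T + self.b
        return u.reshape(x.shape)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic du/dx, shape (..., 3, 3)."""
        x = np.asarray(x, dtype=float)
        flat = np.atleast_2d(x.reshape(-1, 3))
        ph = np.cos(flat @ self.wavevectors.T + self.phases)  # (N, M)
        J = np.einsum("nm,mi,mj->nij", ph, self.amplitudes, self.wavevectors) + self.B
        return J.reshape(x.shape[:-1] + (3, 3)) if x.ndim > 1 else J[0]

    def invert(self, y: np.ndarray, tol: float = 1e-3, max_iter: int = 100) -> np.ndarray:
        """phi^{-1}(y) by fixed-point iteration x <- y - u(x)."""
        y = np.asarray(y, dtype=float)
        x = y.copy()
        for _ in range(max_iter):
            x_new = y - self(x)
            if np.max(np.abs(x_new - x)) < tol:
                return x_new
            x = x_new
        return x


def true_deformation_gradient(warp: SyntheticWarp, x: np.ndarray) -> np.ndarray:
    """Analytic F = I + du/dx of phi(x) = x + u(x)."""
    return np.eye(3) + warp.jacobian(x)


def verify_diffeomorphic(warp: SyntheticWarp, lo, hi, n: int = 32) -> bool:
    """Sample det F on an n^3 grid over the box [lo, hi]."""
    axes = [np.linspace(lo[d], hi[d], n) for d in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    det = np.linalg.det(true_deformation_gradient(warp, pts))
    return bool(np.all(det > 0))


def warp_mesh(mesh: TetMesh, warp: SyntheticWarp) -> TetMesh:
    """Move every node to x + u(x); fails if the warp folds any tet."""
    det = np.linalg.det(true_deformation_gradient(warp, mesh.nodes))
    if np.any(det <= 0):
        raise ContentError("warp amplitude too large: non-positive Jacobian at nodes")
    out = TetMesh(mesh.nodes + warp(mesh.nodes), mesh.tets.copy(),
                  dict(mesh.surface_tags), mesh.cell_tags)
    if np.any(out.tet_volumes(signed=True) <= 0):
        raise ContentError("warp folds a tetrahedron")
    return out


def warp_image(image: BinaryImage3D, warp: SyntheticWarp, tol: float = 1e-3) -> BinaryImage3D:
    """Push an image through the warp: J(y) = I(phi^{-1}(y)).

    The inverse map is found per voxel center by fixed-point iteration to
    ``tol`` mm; the image is then resampled trilinearly (0 outside).
    """
    centers = image.voxel_centers().reshape(-1, 3)
    pre = warp.invert(centers, tol=tol)
    vals = sample_trilinear(image.values, image.origin, image.spacing, pre)
    return BinaryImage3D(image.origin.copy(), image.spacing.copy(),
                         np.clip(vals.reshape(image.dims), 0.0, 1.0))
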