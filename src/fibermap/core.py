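"""Core containers for meshes, images, landmarks, transforms and fiber fields.

Conventions used throughout the package:

* all world coordinates are in millimetres;
* images use a voxel-center convention with 0-based indices, i.e. the world
  coordinate of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``;
* fiber vectors are sign-agnostic unit directions (``f`` and ``-f`` denote
  the same fiber).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TetMesh",
    "LandmarkSet",
    "BinaryImage3D",
    "FiberField",
    "RegionFiberSpec",
    "AffineTransform",
    "DisplacementField",
    "ContentError",
    "FormatError",
]


class ContentError(ValueError):
    """Input parses but violates a domain invariant."""


class FormatError(ValueError):
    """Input cannot be parsed in the named format."""


def _as_float(a, shape=None, name="array"):
    a = np.asarray(a, dtype=float)
    if shape is not None and a.shape[1:] != shape[1:]:
        raise ContentError(f"{name}: expected trailing shape {shape[1:]}, got {a.shape}")
    return a


@dataclass
class TetMesh:
    """Tetrahedral volume mesh with tagged surface node sets.

    Parameters
    ----------
    nodes : (N, 3) float array, mm
    tets : (M, 4) int array of node indices
    surface_tags : dict mapping a tag name (``"endo"``, ``"epi"``,
        ``"rim:<name>"``) to a 1-D array of node indices.
    cell_tags : optional per-tet integer labels.
    """

    nodes: np.ndarray
    tets: np.ndarray
    surface_tags: dict = field(default_factory=dict)
    cell_tags: np.ndarray | None = None

    def __post_init__(self):
        self.nodes = _as_float(self.nodes, (0, 3), "nodes")
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ContentError("tets must be (M, 4)")
        self.surface_tags = {
            k: np.asarray(v, dtype=np.int64).ravel() for k, v in self.surface_tags.items()
        }

    # -- invariants ------------------------------------------------------
    def validate(self, check_duplicates: bool = False) -> "TetMesh":
        n = len(self.nodes)
        if len(self.tets) == 0:
            raise ContentError("mesh contains no tetrahedra")
        if self.tets.min() < 0 or self.tets.max() >= n:
            raise ContentError("tet indices out of range")
        for tag, idx in self.surface_tags.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ContentError(f"surface tag {tag!r} references unknown nodes")
        if check_duplicates and n > 1:
            key = np.round(self.nodes / 1e-9).astype(np.int64)
            if len(np.unique(key, axis=0)) != n:
                raise ContentError("duplicate nodes within 1e-9 mm")
        return self

    def oriented(self) -> "TetMesh":
        """Return a copy with all tets reordered to positive signed volume."""
        vol = self.tet_volumes(signed=True)
        tets = self.tets.copy()
        neg = vol < 0
        tets[neg, 2], tets[neg, 3] = self.tets[neg, 3], self.tets[neg, 2]
        return TetMesh(self.nodes.copy(), tets, dict(self.surface_tags), self.cell_tags)

    def tet_volumes(self, signed: bool = False) -> np.ndarray:
        x = self.nodes[self.tets]
        v = np.einsum(
            "ij,ij->i",
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
            x[:, 3] - x[:, 0],
        ) / 6.0
        return v if signed else np.abs(v)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.nodes.min(axis=0), self.nodes.max(axis=0)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2) with i < j."""
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        e = np.vstack([self.tets[:, p] for p in pairs])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces that belong to exactly one tet."""
        local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
        faces = np.vstack([self.tets[:, f] for f in local])
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]


@dataclass
class LandmarkSet:
    """Ordered, named landmark points; correspondence is by position."""

    names: list
    points: np.ndarray

    def __post_init__(self):
        self.points = _as_float(self.points, (0, 3), "points")
        self.names = list(self.names)
        if len(self.names) != len(self.points):
            raise ContentError("names and points length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ContentError("landmark names must be unique")
        if len(self.points) < 3:
            raise ContentError("need at least 3 landmarks")

    def __len__(self):
        return len(self.points)


@dataclass
class BinaryImage3D:
    """Axis-aligned occupancy image; values in [0, 1] (binary before smoothing)."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ContentError("values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ContentError("spacing must be positive")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ContentError("values must lie in [0, 1]")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape dims + (3,)."""
        axes = [self.origin[d] + self.spacing[d] * np.arange(self.dims[d]) for d in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def same_grid(self, other: "BinaryImage3D", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class FiberField:
    """Per-node unit fiber directions with a validity mask.

    ``vectors[i]`` is meaningful only where ``defined_mask[i]`` is True.
    Fibers are directions, not orientations: consumers must treat ``f`` and
    ``-f`` as equal.
    """

    vectors: np.ndarray
    defined_mask: np.ndarray | None = None

    def __post_init__(self):
        self.vectors = _as_float(self.vectors, (0, 3), "vectors")
        if self.defined_mask is None:
            self.defined_mask = np.ones(len(self.vectors), dtype=bool)
        else:
            self.defined_mask = np.asarray(self.defined_mask, dtype=bool).ravel()
        if len(self.defined_mask) != len(self.vectors):
            raise ContentError("mask length mismatch")
        norms = np.linalg.norm(self.vectors[self.defined_mask], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ContentError("fiber vectors must be unit length on defined nodes")

    def __len__(self):
        return len(self.vectors)


@dataclass
class RegionFiberSpec:
    """Constant fiber direction per region label, plus per-node labels."""

    directions: dict
    node_labels: np.ndarray

    def __post_init__(self):
        self.node_labels = np.asarray(self.node_labels)
        dirs = {}
        for k, v in self.directions.items():
            v = np.asarray(v, dtype=float).reshape(3)
            n = np.linalg.norm(v)
            if abs(n - 1.0) > 1e-9:
                raise ContentError(f"region {k!r}: direction must be unit length")
            dirs[k] = v
        self.directions = dirs


@dataclass
class AffineTransform:
    """x -> A @ x + t with invertible A; ``rigid`` subtype has orthonormal A."""

    A: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if abs(np.linalg.det(self.A)) < 1e-12:
            raise ContentError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x @ self.A.T + self.t

    def compose(self, inner: "AffineTransform") -> "AffineTransform":
        """self ∘ inner, i.e. apply ``inner`` first."""
        return AffineTransform(self.A @ inner.A, self.A @ inner.t + self.t)

    def inverse(self) -> "AffineTransform":
        Ai = np.linalg.inv(self.A)
        return AffineTransform(Ai, -Ai @ self.t)

    @property
    def is_rigid(self) -> bool:
        return bool(
            np.allclose(self.A.T @ self.A, np.eye(3), atol=1e-9)
            and np.linalg.det(self.A) > 0
        )

    def as_flat(self) -> list:
        """Row-major 12-number serialization [A row0, t0, A row1, t1, ...]."""
        M = np.hstack([self.A, self.t[:, None]])
        return [float(v) for v in M.ravel()]

    @classmethod
    def from_flat(cls, flat) -> "AffineTransform":
        M = np.asarray(flat, dtype=float).reshape(3, 4)
        return cls(M[:, :3], M[:, 3])


@dataclass
class DisplacementField:
    """Per-voxel displacement u(x) in mm on the same grid as an image.

    The induced transformation is phi(x) = x + u(x).
    """

    origin: np.ndarray
    spacing: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[3] != 3:
            raise ContentError("u must have shape (nx, ny, nz, 3)")
        if np.any(self.spacing <= 0):
            raise ContentError("spacing must be positive")
        if not np.all(np.isfinite(self.u)):
            raise ContentError("displacement must be finite")

    @property
    def dims(self) -> tuple:
        return self.u.shape[:3]

    @classmethod
    def zeros_like(cls, image: BinaryImage3D) -> "DisplacementField":
        return cls(image.origin.copy(), image.spacing.copy(), np.zeros(image.dims + (3,)))

    def matches_grid(self, image: BinaryImage3D, tol: float = 1e-9) -> bool:
        return (
            self.dims == image.dims
            and np.allclose(self.origin, image.origin, atol=tol)
            and np.allclose(self.spacing, image.spacing, atol=tol)
        )


def normalize_rows(v: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Row-wise normalization; rows with norm <= eps are returned as zeros."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    out = np.zeros_like(v)
    ok = (n > max(eps, 1e-300)).ravel()
    out[ok] = v[ok] / n[ok]
    return out
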