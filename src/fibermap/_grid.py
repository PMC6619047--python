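"""Low-level trilinear sampling and finite differences on voxel grids."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["sample_trilinear", "sample_vector", "grid_gradient"]


def sample_trilinear(values, origin, spacing, points, outside=0.0, mode="constant"):
    """Trilinearly sample a scalar voxel array at world-coordinate points.

    Points outside the grid get ``outside`` (``mode='constant'``) or the
    clamped edge value (``mode='nearest'``).
    """
    points = np.asarray(points, dtype=float)
    idx = (points.reshape(-1, 3) - origin) / spacing
    out = map_coordinates(values, idx.T, order=1, mode=mode, cval=outside)
    return out.reshape(points.shape[:-1])


def sample_vector(vec_values, origin, spacing, points, outside=0.0, mode="constant"):
    """Componentwise trilinear sampling of an (nx,ny,nz,3) field."""
    points = np.asarray(points, dtype=float)
    flat = points.reshape(-1, 3)
    out = np.empty_like(flat)
    for c in range(3):
        out[:, c] = sample_trilinear(
            vec_values[..., c], origin, spacing, flat, outside=outside, mode=mode
        )
    return out.reshape(points.shape)


def grid_gradient(values, spacing):
    """Central-difference gradient (second-order one-sided at boundaries).

    Returns a list of three arrays, d/dx, d/dy, d/dz in physical units.
    """
    return list(np.gradient(values, *spacing, edge_order=2 if min(values.shape) > 2 else 1))
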