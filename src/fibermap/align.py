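"""Global atlas-to-patient alignment: landmark rigid fit, then affine ICP.

The rigid step is the classical Kabsch/Umeyama least-squares fit (no
scaling) on corresponding landmark pairs via SVD, with the reflection
excluded by sign-correcting the smallest singular direction.  The affine
step is iterative closest point on the full node clouds: nearest-neighbor
correspondences (KD-tree, ties broken towards the lowest index) alternate
with a closed-form least-squares affine fit until the mean closest-point
distance stops improving.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core import AffineTransform, ContentError, LandmarkSet

__all__ = ["rigid_from_landmarks", "icp_affine"]


def rigid_from_landmarks(src: LandmarkSet, dst: LandmarkSet) -> AffineTransform:
    """Least-squares rigid transform mapping src landmarks onto dst.

    Correspondence is by ordinal position; at least three non-collinear
    pairs are required.
    """
    if len(src) != len(dst):
        raise ContentError("landmark sets must have equal counts")
    P = np.asarray(src.points, dtype=float)
    Q = np.asarray(dst.points, dtype=float)
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, s, Vt = np.linalg.svd(H)
    # collinear configurations leave the rotation about the line free
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ContentError("landmarks are (nearly) collinear; rigid fit is degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return AffineTransform(R, t)


def icp_affine(src_points: np.ndarray, dst_points: np.ndarray,
               init: AffineTransform | None = None, max_iter: int = 100,
               tol: float = 1e-4, return_history: bool = False):
    """Affine ICP from the src point cloud onto the dst cloud.

    Correspondences are one-directional (every src point to its nearest
    dst point); each iteration refits the affine by normal equations on
    the current correspondences.  Stops when the mean correspondence
    distance improves by less than ``tol`` mm or after ``max_iter``
    iterations.  The mean closest-point distance is non-increasing across
    accepted iterations.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if len(src) == 0 or len(dst) == 0:
        raise ContentError("point clouds must be non-empty")
    tf = init if init is not None else AffineTransform.identity()
    tree = cKDTree(dst)
    X = np.hstack([src, np.ones((len(src), 1))])  # homogeneous src
    history = []
    prev = np.inf
    for _ in range(max_iter):
        cur = tf.apply(src)
        d, j = tree.query(cur, k=1)
        mean_d = float(d.mean())
        history.append(mean_d)
        if prev - mean_d < tol:
            break
        prev = mean_d
        Y = dst[j]
        M, *_ = np.linalg.lstsq(X, Y, rcond=None)
        A, t = M[:3].T, M[3]
        if abs(np.linalg.det(A)) < 1e-8:
            raise ContentError("ICP affine fit collapsed (|det A| < 1e-8)")
        tf = AffineTransform(A, t)
    if return_history:
        return tf, history
    return tf
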