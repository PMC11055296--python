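"""Small shared geometric primitives (ray casting, plane type helpers)."""

from __future__ import annotations

import numpy as np

from .errors import GeometryError


def line_mesh_intersections(
    vertices: np.ndarray,
    faces: np.ndarray,
    origin: np.ndarray,
    direction: np.ndarray,
    both_directions: bool = True,
) -> np.ndarray:
    """All intersection points of a line (or ray) with a triangle mesh.

    Vectorized Moller-Trumbore over every triangle. Returns an (k, 3) array
    of hit points sorted by the signed parameter along ``direction``; when
    ``both_directions`` is False only hits with parameter > 1e-9 are kept.
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    d = np.asarray(direction, dtype=float).reshape(3)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise GeometryError("ray direction must be non-zero")
    d = d / norm
    tri = vertices[faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    tvec = origin - tri[:, 0]
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = qvec @ d * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    eps = 1e-12
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
    if not both_directions:
        hit &= t > 1e-9
    t = t[hit]
    order = np.argsort(t)
    return origin + t[order, None] * d
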