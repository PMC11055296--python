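"""Mesh-plane section curves, station planes, top points and arc midpoints.

Sections drive every regional measurement: six coronal station planes locate
the crest top points, four nearly sagittal planes through pairs of tops cut
the crest profiles, and the midsagittal section provides the central pair of
radii. All operations assume the mesh is already standardized (+Z superior,
+Y anterior, +X lateral, medial crest at X < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from trimesh.intersections import mesh_plane

from ._geom import line_mesh_intersections
from .errors import GeometryError
from .frame import Plane
from .mesh_io import LandmarkSet, SurfaceMesh

__all__ = [
    "SectionCurve",
    "StationTops",
    "mesh_plane_intersection",
    "station_planes",
    "top_point",
    "region_section_plane",
    "arc_midpoint",
    "midsagittal_extremes",
    "clip_curve_y",
    "STATION_NAMES",
]

#: Station names in (medial triple, lateral triple) order.
STATION_NAMES = ("am", "mid_medial", "pm", "al", "mid_lateral", "pl")

#: Endpoint-matching tolerance when chaining segments into polylines (mm).
CHAIN_TOLERANCE = 1e-9

#: Maximum allowed point-to-plane residual of a section curve (mm).
PLANE_RESIDUAL = 1e-6


@dataclass
class SectionCurve:
    """An ordered polyline produced by cutting the mesh with a plane.

    ``arclength`` is the cumulative chord length; for a closed curve the
    first point is repeated at the end, so the final entry is the perimeter.
    """

    plane: Plane
    points: np.ndarray
    arclength: np.ndarray
    closed: bool = False

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def __len__(self) -> int:
        return len(self.points)

    def validate(self) -> "SectionCurve":
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise GeometryError("section curve has coincident consecutive points")
        if np.any(np.diff(self.arclength) <= 0):
            raise GeometryError("section curve arc length is not strictly increasing")
        resid = np.max(np.abs(self.plane.signed_distance(self.points)))
        if resid > PLANE_RESIDUAL:
            raise GeometryError(
                f"section curve off its plane by {resid:.2e} mm (> {PLANE_RESIDUAL})"
            )
        return self


@dataclass
class StationTops:
    """The six crest top points found on the coronal station sections."""

    am_top: np.ndarray
    mid_medial_top: np.ndarray
    pm_top: np.ndarray
    al_top: np.ndarray
    mid_lateral_top: np.ndarray
    pl_top: np.ndarray

    def validate(self) -> "StationTops":
        for name in ("am_top", "mid_medial_top", "pm_top"):
            if getattr(self, name)[0] >= 0:
                raise GeometryError(f"medial top {name} does not lie at X < 0")
        for name in ("al_top", "mid_lateral_top", "pl_top"):
            if getattr(self, name)[0] <= 0:
                raise GeometryError(f"lateral top {name} does not lie at X > 0")
        return self


def _chain_segments(segments: np.ndarray) -> list[np.ndarray]:
    """Chain (n, 2, 3) segments into maximal polylines by shared endpoints.

    Endpoints closer than :data:`CHAIN_TOLERANCE` are identified via a
    KD-tree + union-find, which avoids quantization-boundary artifacts.
    """
    n = len(segments)
    ends = segments.reshape(-1, 3)
    parent = np.arange(len(ends))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in cKDTree(ends).query_pairs(CHAIN_TOLERANCE):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    node_of = np.array([find(i) for i in range(len(ends))])

    adj: dict[int, list[tuple[int, int]]] = {}
    for s in range(n):
        a, b = node_of[2 * s], node_of[2 * s + 1]
        if a == b:
            continue  # degenerate segment collapsed by merging
        adj.setdefault(a, []).append((s, b))
        adj.setdefault(b, []).append((s, a))

    used = np.zeros(n, dtype=bool)

    def walk(start_node):
        """Extend a path from start_node until no unused segment continues it."""
        path_nodes = [start_node]
        node = start_node
        while True:
            nxt = next(((s, o) for s, o in adj.get(node, []) if not used[s]), None)
            if nxt is None:
                break
            used[nxt[0]] = True
            node = nxt[1]
            path_nodes.append(node)
        return path_nodes

    polylines = []
    degree = {k: len(v) for k, v in adj.items()}
    # open chains first (start at odd-degree nodes), then leftover cycles
    for start in [k for k, d in degree.items() if d % 2 == 1]:
        if any(not used[s] for s, _ in adj[start]):
            polylines.append(walk(start))
    for start in list(adj):
        if any(not used[s] for s, _ in adj[start]):
            polylines.append(walk(start))

    return [ends[nodes] for nodes in polylines if len(nodes) >= 2]


def mesh_plane_intersection(mesh: SurfaceMesh, plane: Plane) -> list[SectionCurve]:
    """Section curves of the mesh cut by a plane, longest first.

    Every triangle crossing the plane contributes one segment; segments are
    chained into maximal polylines. A plane missing the mesh yields an empty
    list (not an error).
    """
    segments = mesh_plane(
        mesh.to_trimesh(),
        plane_normal=plane.normal,
        plane_origin=plane.point_on_plane(),
    )
    if len(segments) == 0:
        return []
    lengths = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
    segments = segments[lengths > CHAIN_TOLERANCE]
    if len(segments) == 0:
        return []
    curves = []
    for pts in _chain_segments(segments):
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > CHAIN_TOLERANCE
        pts = pts[keep]
        if len(pts) < 2:
            continue
        closed = np.linalg.norm(pts[0] - pts[-1]) <= CHAIN_TOLERANCE
        if closed:
            pts = np.vstack([pts[:-1], pts[:1]])
        arclength = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        curves.append(SectionCurve(plane, pts, arclength, closed).validate())
    curves.sort(key=lambda c: c.length, reverse=True)
    return curves


def station_planes(landmarks: LandmarkSet) -> dict[str, Plane]:
    """The six coronal station planes (normal = +Y) from standardized landmarks.

    Medial stations pass through the anteroposterior positions of am_edge,
    midpoint(am, pm) and pm_edge; lateral stations likewise for al/pl. The
    duplicate-position check is applied within each side's triple: a
    symmetric trochlea legitimately places the medial and lateral stations at
    equal Y.
    """
    y = {
        "am": landmarks.am_edge[1],
        "pm": landmarks.pm_edge[1],
        "al": landmarks.al_edge[1],
        "pl": landmarks.pl_edge[1],
    }
    y["mid_medial"] = 0.5 * (y["am"] + y["pm"])
    y["mid_lateral"] = 0.5 * (y["al"] + y["pl"])
    for a, b in [("am", "pm"), ("al", "pl")]:
        if abs(y[a] - y[b]) < 1e-6:
            raise GeometryError(
                f"{a}/{b} edges share the same anteroposterior position; "
                "station planes are degenerate"
            )
    normal = np.array([0.0, 1.0, 0.0])
    return {name: Plane(normal, float(y[name])) for name in STATION_NAMES}


def top_point(curve: SectionCurve, half: str) -> np.ndarray:
    """The maximal-Z polyline point within the requested half (X < 0 medial,
    X > 0 lateral); ties within 1e-9 mm broken toward smaller |X| (the groove).
    """
    if half not in ("medial", "lateral"):
        raise GeometryError(f"half must be 'medial' or 'lateral', got {half!r}")
    mask = curve.points[:, 0] < 0 if half == "medial" else curve.points[:, 0] > 0
    if not np.any(mask):
        raise GeometryError(f"section curve has no points in the {half} half")
    pts = curve.points[mask]
    zmax = pts[:, 2].max()
    candidates = pts[pts[:, 2] >= zmax - 1e-9]
    return candidates[np.argmin(np.abs(candidates[:, 0]))].copy()


def region_section_plane(topA, topB, mesh: SurfaceMesh) -> Plane:
    """The nearly sagittal section plane through two crest tops.

    The third defining point is the superior (+Z) surface projection of the
    chord midpoint. If the three points are collinear (e.g. the tops of a
    perfect cylinder at equal anteroposterior positions) the plane falls back
    to the vertical plane through the chord.
    """
    topA = np.asarray(topA, dtype=float).reshape(3)
    topB = np.asarray(topB, dtype=float).reshape(3)
    chord = topB - topA
    if np.linalg.norm(chord) < 1e-9:
        raise GeometryError("section tops coincide")
    mid = 0.5 * (topA + topB)
    hits = line_mesh_intersections(mesh.vertices, mesh.faces, mid, [0.0, 0.0, 1.0])
    if len(hits) == 0:
        raise GeometryError("chord-midpoint projection misses the mesh")
    point3 = hits[np.argmax(hits[:, 2])]
    area = 0.5 * np.linalg.norm(np.cross(chord, point3 - topA))
    if area > 1e-9:
        n = np.cross(chord, point3 - topA)
        n /= np.linalg.norm(n)
        return Plane(n, float(n @ (topA + topB + point3) / 3.0))
    # degenerate: vertical plane containing the chord
    n = np.cross(chord, [0.0, 0.0, 1.0])
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("chord is vertical; section plane undefined")
    n /= norm
    return Plane(n, float(n @ mid))


def _snap_to_curve(curve: SectionCurve, point, tolerance: float) -> float:
    """Arc-length position of the closest polyline point to ``point``.

    The point is projected onto every polyline segment (nearest point on the
    polyline, interpolated within its segment).
    """
    p = np.asarray(point, dtype=float).reshape(3)
    a = curve.points[:-1]
    b = curve.points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    foot = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", foot - p, foot - p)
    i = int(np.argmin(d2))
    dist = float(np.sqrt(d2[i]))
    if dist > tolerance:
        raise GeometryError(
            f"point {p} lies {dist:.3f} mm from the section curve "
            f"(snap tolerance {tolerance} mm)"
        )
    return float(curve.arclength[i] + t[i] * (curve.arclength[i + 1] - curve.arclength[i]))


def _point_at_arclength(curve: SectionCurve, s: float) -> np.ndarray:
    s = float(np.clip(s, 0.0, curve.length))
    i = int(np.searchsorted(curve.arclength, s, side="right") - 1)
    i = min(max(i, 0), len(curve.points) - 2)
    seg = curve.arclength[i + 1] - curve.arclength[i]
    t = 0.0 if seg <= 0 else (s - curve.arclength[i]) / seg
    return curve.points[i] + t * (curve.points[i + 1] - curve.points[i])


def arc_midpoint(curve: SectionCurve, a, b, snap_tolerance: float = 0.5) -> np.ndarray:
    """The point halfway (by cumulative arc length) between ``a`` and ``b``.

    ``a`` and ``b`` are snapped onto the polyline (they must lie within
    ``snap_tolerance`` of it). On a closed curve the shorter of the two arcs
    is used.
    """
    sa = _snap_to_curve(curve, a, snap_tolerance)
    sb = _snap_to_curve(curve, b, snap_tolerance)
    if abs(sa - sb) < 1e-9 or (
        curve.closed and abs(curve.length - abs(sa - sb)) < 1e-9
    ):
        raise GeometryError("arc endpoints snap to the same curve position")
    lo, hi = sorted((sa, sb))
    if curve.closed and (hi - lo) > curve.length - (hi - lo):
        # wrap around the seam: midpoint of the complementary (shorter) arc
        s_mid = (hi + (curve.length - (hi - lo)) / 2.0) % curve.length
    else:
        s_mid = 0.5 * (lo + hi)
    return _point_at_arclength(curve, s_mid)


def midsagittal_extremes(curve: SectionCurve):
    """(anterior, superior, posterior) extreme points of a midsagittal profile:
    maximal-Y, maximal-Z and minimal-Y points respectively."""
    if len(curve) < 3:
        raise GeometryError("midsagittal profile has fewer than 3 points")
    pts = curve.points
    anterior = pts[np.argmax(pts[:, 1])].copy()
    posterior = pts[np.argmin(pts[:, 1])].copy()
    superior = pts[np.argmax(pts[:, 2])].copy()
    return anterior, superior, posterior


def clip_curve_y(curve: SectionCurve, y_min: float, y_max: float) -> SectionCurve:
    """Restrict a section curve to the contiguous run of points with
    y_min <= Y <= y_max that contains the curve's highest point.

    Used to confine the midsagittal profile to the trochlear patch before
    extracting its extreme points.
    """
    mask = (curve.points[:, 1] >= y_min) & (curve.points[:, 1] <= y_max)
    if not np.any(mask):
        raise GeometryError("no section points inside the requested Y range")
    idx = np.flatnonzero(mask)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    in_range_z = np.where(mask, curve.points[:, 2], -np.inf)
    peak = int(np.argmax(in_range_z))
    run = next(r for r in runs if r[0] <= peak <= r[-1])
    pts = curve.points[run]
    if len(pts) < 2:
        raise GeometryError("clipped section curve degenerates to a point")
    arclength = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    return SectionCurve(curve.plane, pts, arclength, closed=False).validate()
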