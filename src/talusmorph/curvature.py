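"""Regional radii of curvature and least-squares cylinder fitting.

Each regional radius is the radius of the circle through three points of a
section curve: the two bounding crest tops and the point halfway between
them by arc length. The global fit is a right circular cylinder, axis
roughly mediolateral, least-squares fitted to the separated trochlear patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.optimize import least_squares
from shapely.geometry import Polygon

from .errors import ConvergenceError, GeometryError, ValidationError
from .frame import Plane, plane_from_points
from .mesh_io import LandmarkSet, SurfaceMesh
from .sectioning import (
    SectionCurve,
    _point_at_arclength,
    _snap_to_curve,
    arc_midpoint,
    clip_curve_y,
    mesh_plane_intersection,
    midsagittal_extremes,
)

__all__ = [
    "CircleFit3",
    "CylinderFit",
    "RegionRadiusSet",
    "circumcircle",
    "region_radius",
    "midsagittal_radii",
    "extract_trochlear_patch",
    "fit_cylinder",
]


@dataclass(frozen=True)
class CircleFit3:
    """Exact circumcircle of three points in 3D."""

    center: np.ndarray
    radius: float
    plane: Plane


@dataclass
class CylinderFit:
    """Least-squares cylinder: axis line, radius and residual diagnostics."""

    axis_point: np.ndarray
    direction: np.ndarray
    radius: float
    rms: float
    iterations: int
    converged: bool = True

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValidationError("cylinder axis direction must be a unit vector")
        if not self.radius > 0 or self.rms < 0:
            raise ValidationError("cylinder radius must be > 0 and rms >= 0")


@dataclass
class RegionRadiusSet:
    """The six regional radii plus the cylinder fit for one specimen (mm)."""

    r_am: float
    r_al: float
    r_pm: float
    r_pl: float
    r_ma: float
    r_mp: float
    r_cyl: float
    cyl_rms: float

    def validate(self) -> "RegionRadiusSet":
        radii = [self.r_am, self.r_al, self.r_pm, self.r_pl, self.r_ma, self.r_mp, self.r_cyl]
        if not all(np.isfinite(radii)) or any(r <= 0 for r in radii):
            raise ValidationError(f"all radii must be positive and finite, got {radii}")
        if not np.isfinite(self.cyl_rms) or self.cyl_rms < 0:
            raise ValidationError("cyl_rms must be finite and >= 0")
        return self

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in (
            "r_am", "r_al", "r_pm", "r_pl", "r_ma", "r_mp", "r_cyl", "cyl_rms")}


def circumcircle(p1, p2, p3) -> CircleFit3:
    """The circle through three non-collinear points.

    The radius satisfies r = abc / (4 * area); the returned center is
    equidistant from all three points to 1e-9 relative.
    """
    A, B, C = (np.asarray(p, dtype=float).reshape(3) for p in (p1, p2, p3))
    u = B - A
    v = C - A
    w = np.cross(u, v)
    area = 0.5 * np.linalg.norm(w)
    if area <= 1e-9:
        raise GeometryError("circumcircle of collinear points is undefined")
    center = A + np.cross((u @ u) * v - (v @ v) * u, w) / (2.0 * (w @ w))
    radius = float(np.linalg.norm(center - A))
    d = np.array([np.linalg.norm(center - P) for P in (A, B, C)])
    if np.max(np.abs(d - radius)) > 1e-9 * max(radius, 1.0):
        raise GeometryError("circumcenter is not equidistant from the points")
    return CircleFit3(center=center, radius=radius, plane=plane_from_points(A, B, C))


def _select_curve(curves, endA, endB, snap_tolerance):
    """The section curve that carries both endpoints (smallest worst snap)."""
    best, best_d = None, np.inf
    for curve in curves:
        try:
            da = _snap_distance(curve, endA)
            db = _snap_distance(curve, endB)
        except GeometryError:
            continue
        worst = max(da, db)
        if worst < best_d:
            best, best_d = curve, worst
    if best is None or best_d > snap_tolerance:
        raise GeometryError(
            f"no section curve carries both endpoints within {snap_tolerance} mm"
        )
    return best


def _snap_distance(curve: SectionCurve, point) -> float:
    p = np.asarray(point, dtype=float).reshape(3)
    a, b = curve.points[:-1], curve.points[1:]
    ab = b - a
    t = np.clip(
        np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab), 0.0, 1.0
    )
    foot = a + t[:, None] * ab
    return float(np.sqrt(np.min(np.einsum("ij,ij->i", foot - p, foot - p))))


def region_radius(
    mesh: SurfaceMesh,
    plane: Plane,
    endA,
    endB,
    snap_tolerance: float = 0.5,
) -> float:
    """Radius of one crest region: cut the mesh with the region section plane
    and take the circumcircle through the two (snapped) tops and their
    arc-length midpoint."""
    curves = mesh_plane_intersection(mesh, plane)
    if not curves:
        raise GeometryError("region section plane does not intersect the mesh")
    curve = _select_curve(curves, endA, endB, snap_tolerance)
    sa = _snap_to_curve(curve, endA, snap_tolerance)
    sb = _snap_to_curve(curve, endB, snap_tolerance)
    pa = _point_at_arclength(curve, sa)
    pb = _point_at_arclength(curve, sb)
    mid = arc_midpoint(curve, pa, pb, snap_tolerance)
    return circumcircle(pa, mid, pb).radius


def midsagittal_radii(
    mesh: SurfaceMesh,
    landmarks: LandmarkSet | None = None,
    plane: Plane | None = None,
    snap_tolerance: float = 0.5,
) -> tuple[float, float]:
    """The mid-anterior and mid-posterior radii from the midsagittal profile.

    The mesh must be standardized; the profile is the X = 0 section restricted
    (when landmarks are given) to the anteroposterior span of the corner
    edges. r_ma uses (anterior, arc midpoint, superior); r_mp uses
    (superior, arc midpoint, posterior).
    """
    if plane is None:
        plane = Plane(np.array([1.0, 0.0, 0.0]), 0.0)
    curves = mesh_plane_intersection(mesh, plane)
    if not curves:
        raise GeometryError("midsagittal plane does not intersect the mesh")
    # the trochlear profile is the curve carrying the globally highest point
    curve = max(curves, key=lambda c: c.points[:, 2].max())
    if landmarks is not None:
        ys = landmarks.corner_quad()[:, 1]
        curve = clip_curve_y(curve, float(ys.min()), float(ys.max()))
    anterior, superior, posterior = midsagittal_extremes(curve)
    mid_a = arc_midpoint(curve, anterior, superior, snap_tolerance)
    mid_p = arc_midpoint(curve, superior, posterior, snap_tolerance)
    r_ma = circumcircle(anterior, mid_a, superior).radius
    r_mp = circumcircle(superior, mid_p, posterior).radius
    return r_ma, r_mp


def extract_trochlear_patch(
    mesh: SurfaceMesh, landmarks: LandmarkSet, margin: float = 0.0
) -> np.ndarray:
    """Vertex indices of the separated trochlear patch (standardized mesh).

    A vertex belongs to the patch when its (X, Y) lies inside the corner-edge
    quadrilateral inflated by ``margin`` and its outward normal points
    superior (positive Z component).
    """
    quad = landmarks.corner_quad()[:, :2]
    poly = Polygon(quad)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("corner-edge quadrilateral is degenerate")
    poly = poly.buffer(margin + 1e-9)  # epsilon keeps boundary vertices inside
    inside = shapely.contains_xy(poly, mesh.vertices[:, 0], mesh.vertices[:, 1])
    normals = mesh.to_trimesh().vertex_normals
    superior = normals[:, 2] > 0
    idx = np.flatnonzero(inside & superior)
    if len(idx) == 0:
        raise GeometryError("trochlear patch is empty")
    return idx


def _orthobasis(d: np.ndarray, e2: np.ndarray, e3: np.ndarray):
    """Two unit vectors spanning the plane perpendicular to ``d``."""
    ref = e2 if abs(d @ e2) < 0.9 else e3
    f1 = np.cross(d, ref)
    f1 /= np.linalg.norm(f1)
    f2 = np.cross(d, f1)
    return f1, f2


def fit_cylinder(
    points: np.ndarray,
    init_axis=(1.0, 0.0, 0.0),
    max_iter: int = 200,
    gtol: float = 1e-10,
) -> CylinderFit:
    """Least-squares right circular cylinder through a point cloud.

    Minimizes sum((d_i - r)^2) where d_i is the distance of point i to the
    axis line, over 5 parameters: two axis-tilt components about the initial
    axis, two axis-point offsets in the plane through the centroid
    perpendicular to the axis, and the radius. The problem is internally
    centered and scaled by the mean centroid distance, making the fit exactly
    scale-equivariant.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 6:
        raise GeometryError("cylinder fit needs at least 6 three-dimensional points")
    centroid = points.mean(axis=0)
    scale = float(np.mean(np.linalg.norm(points - centroid, axis=1)))
    if scale <= 0:
        raise GeometryError("cylinder fit points are all coincident")
    X = (points - centroid) / scale

    e1 = np.asarray(init_axis, dtype=float).reshape(3)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.eye(3)[np.argmin(np.abs(e1))]
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)

    def unpack(p):
        a, b, c1, c2, r = p
        d = e1 + a * e2 + b * e3
        d = d / np.linalg.norm(d)
        f1, f2 = _orthobasis(d, e2, e3)
        q = c1 * f1 + c2 * f2
        return d, q, r

    def residuals(p):
        d, q, r = unpack(p)
        dist = np.linalg.norm(np.cross(X - q, d), axis=1)
        return dist - r

    r0 = float(np.mean(np.linalg.norm(np.cross(X, e1), axis=1)))
    x0 = np.array([0.0, 0.0, 0.0, 0.0, r0])
    result = least_squares(
        residuals,
        x0,
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=min(gtol, 1e-15),
        max_nfev=max_iter * 6,
    )

    # Gauss-Newton polish: LM's relative stopping rules leave the radius at
    # ~rms * 1e-7 reproducibility; a few explicit normal-equation steps push
    # the iterate to the actual stationary point.
    x = result.x
    nfev = int(result.nfev)
    h = 1e-7
    for _ in range(20):
        J = np.empty((len(X), 5))
        for i in range(5):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            J[:, i] = (residuals(xp) - residuals(xm)) / (2.0 * h)
        r_vec = residuals(x)
        nfev += 11
        try:
            step = np.linalg.solve(J.T @ J, J.T @ r_vec)
        except np.linalg.LinAlgError:
            break
        x = x - step
        if np.max(np.abs(step)) < 1e-13:
            break
    result.x = x
    result.fun = residuals(x)
    result.nfev = nfev
    grad_norm = float(np.linalg.norm(J.T @ result.fun))
    converged = result.status > 0 or grad_norm < gtol
    if not converged:
        raise ConvergenceError(
            f"cylinder fit did not converge in {max_iter} iterations "
            f"(gradient norm {grad_norm:.2e})",
            last_iterate=result.x,
        )
    d, q, r = unpack(result.x)
    r = abs(float(r))
    rms = float(np.sqrt(np.mean(result.fun**2))) * scale
    return CylinderFit(
        axis_point=centroid + q * scale,
        direction=d,
        radius=r * scale,
        rms=rms,
        iterations=int(result.nfev),
        converged=converged,
    )
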