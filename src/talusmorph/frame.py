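"""Anatomical coordinate-frame construction from trochlear landmarks.

The standardized world frame is anchored at the fitted talar centerpoint and
oriented by two landmark-derived datum planes:

* the transverse plane (alpha) through the three border-extreme landmarks;
* the coronal plane (beta), perpendicular to alpha, through the midpoint of
  the medial border extremes and the midpoint of (anterior lateral border
  extreme, posterolateral corner edge).

Axes: +Z superior (alpha normal), +Y anterior (beta normal), +X = Y x Z
(lateral for a right talus). Left-side specimens are mirrored about the
sagittal plane after the rigid alignment so that "medial" always lies at
X < 0; all measured radii are mirror-invariant. Axis signs are resolved from
the data (which side of alpha carries the trochlea, which side of beta the
anterior landmarks), never assumed from the input pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import line_mesh_intersections
from .errors import GeometryError
from .mesh_io import LandmarkSet, SurfaceMesh

__all__ = [
    "Plane",
    "AnatomicalFrame",
    "plane_from_points",
    "build_planes",
    "fit_centerpoint",
    "build_frame",
]

#: Axis meaning in the standardized frame.
AXIS_CONVENTION = {"+Z": "superior", "+Y": "anterior", "+X": "lateral"}


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``{p : normal . p = offset}`` with a unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise GeometryError("plane normal must be non-zero")
            object.__setattr__(self, "offset", float(self.offset) / norm)
            n = n / norm
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def point_on_plane(self) -> np.ndarray:
        return self.normal * self.offset


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points (triangle area > 1e-9 mm^2)."""
    p1, p2, p3 = (np.asarray(p, dtype=float).reshape(3) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    if 0.5 * np.linalg.norm(n) <= 1e-9:
        raise GeometryError("points are collinear; they do not define a plane")
    n = n / np.linalg.norm(n)
    offset = float(n @ (p1 + p2 + p3) / 3.0)
    return Plane(n, offset)


def build_planes(landmarks: LandmarkSet) -> tuple[Plane, Plane]:
    """The transverse (alpha) and coronal (beta) datum planes.

    beta contains midpoint1 = midpoint(ant_medial_edge, post_medial_edge) and
    midpoint2 = midpoint(ant_lateral_edge, pl_edge), and its normal is exactly
    perpendicular to alpha's.
    """
    alpha = plane_from_points(*landmarks.alpha_triplet())
    m1 = 0.5 * (landmarks.ant_medial_edge + landmarks.post_medial_edge)
    m2 = 0.5 * (landmarks.ant_lateral_edge + landmarks.pl_edge)
    chord = m2 - m1
    if np.linalg.norm(chord) < 1e-6:
        raise GeometryError("beta midpoints coincide; coronal plane is undefined")
    n_beta = np.cross(alpha.normal, chord)
    norm = np.linalg.norm(n_beta)
    if norm < 1e-12:
        raise GeometryError("beta chord is parallel to the alpha normal")
    n_beta = n_beta / norm
    beta = Plane(n_beta, float(n_beta @ (0.5 * (m1 + m2))))
    return alpha, beta


def _superior_sign(
    alpha: Plane, landmarks: LandmarkSet, mesh: SurfaceMesh | None = None
) -> float:
    """Orient the alpha normal toward the trochlear (superior) side.

    The four corner edges sit on the articular crest, superior to the border
    rim through which alpha passes, so their mean signed offset fixes the
    sign. When the corners themselves lie on alpha (a degenerate patch such
    as a pure cylinder), the mean vertex side of the surface decides instead.
    """
    mean_off = float(np.mean(alpha.signed_distance(landmarks.corner_quad())))
    if abs(mean_off) < 1e-6 and mesh is not None:
        mean_off = float(np.mean(alpha.signed_distance(mesh.vertices)))
    if abs(mean_off) < 1e-9:
        raise GeometryError(
            "corner landmarks lie on the transverse plane; superior side ambiguous"
        )
    return 1.0 if mean_off > 0 else -1.0


def fit_centerpoint(
    mesh: SurfaceMesh, landmarks: LandmarkSet, alpha: Plane | None = None
) -> np.ndarray:
    """The talar centerpoint: circumcenter of the two corner-chord midpoints
    and the superior surface projection of their own midpoint.

    point1 = midpoint(am, al), point2 = midpoint(pm, pl); their midpoint is
    projected along the superior alpha normal onto the trochlear surface
    (point3); the centerpoint is the circumcenter of (point1, point2, point3).
    """
    from .curvature import circumcircle  # local import; curvature does not import frame

    if alpha is None:
        alpha, _ = build_planes(landmarks)
    up = alpha.normal * _superior_sign(alpha, landmarks, mesh)
    point1 = 0.5 * (landmarks.am_edge + landmarks.al_edge)
    point2 = 0.5 * (landmarks.pm_edge + landmarks.pl_edge)
    mid = 0.5 * (point1 + point2)
    hits = line_mesh_intersections(mesh.vertices, mesh.faces, mid, up)
    if len(hits) == 0:
        raise GeometryError("projection ray from the chord midpoint misses the mesh")
    # most superior intersection = the trochlear surface (not the talar body)
    point3 = hits[np.argmax(hits @ up)]
    fit = circumcircle(point1, point2, point3)
    return fit.center


@dataclass
class AnatomicalFrame:
    """Rigid (plus optional mirror) map from object to world coordinates.

    ``apply`` computes ``R (p - centerpoint)`` and, for left-side specimens,
    then flips X so the medial crest always lies at X < 0. The rotation is
    proper orthonormal; the mirror is carried separately.
    """

    rotation: np.ndarray
    centerpoint: np.ndarray
    side: str = "right"
    axis_convention: dict = field(default_factory=lambda: dict(AXIS_CONVENTION))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-9:
            raise GeometryError("frame rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise GeometryError("frame rotation must be proper (det = +1)")
        self.rotation = R
        self.centerpoint = np.asarray(self.centerpoint, dtype=float).reshape(3)

    @property
    def translation(self) -> np.ndarray:
        return -self.rotation @ self.centerpoint

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        out = (pts - self.centerpoint) @ self.rotation.T
        if self.side == "left":
            out = out.copy()
            out[..., 0] *= -1.0
        return out

    def apply_mesh(self, mesh: SurfaceMesh) -> SurfaceMesh:
        verts = self.apply(mesh.vertices)
        faces = mesh.faces[:, ::-1].copy() if self.side == "left" else mesh.faces.copy()
        return SurfaceMesh(verts, faces, mesh.specimen_id)

    def apply_landmarks(self, landmarks: LandmarkSet) -> LandmarkSet:
        return landmarks.transformed(self.apply)


def build_frame(
    mesh: SurfaceMesh, landmarks: LandmarkSet, side: str = "right"
) -> AnatomicalFrame:
    """Construct the standardized frame for one specimen.

    Z is the alpha normal oriented superior, Y the beta normal oriented toward
    the anterior landmarks, X = Y x Z (right-handed). The world origin is the
    fitted centerpoint. For ``side="left"`` the resulting map additionally
    mirrors X (applied by :class:`AnatomicalFrame`), so measured radii are
    directly comparable across sides.
    """
    if side not in ("left", "right"):
        raise GeometryError(f"side must be 'left' or 'right', got {side!r}")
    alpha, beta = build_planes(landmarks)
    origin = fit_centerpoint(mesh, landmarks, alpha)
    quad = landmarks.corner_quad()
    quad_size = float(np.linalg.norm(quad.max(axis=0) - quad.min(axis=0)))
    if np.linalg.norm(origin - quad.mean(axis=0)) > 50.0 * quad_size:
        raise GeometryError(
            "fitted centerpoint lies implausibly far from the trochlea: the "
            "three-point centerpoint circle is nearly collinear (flat dome)"
        )
    z_dir = alpha.normal * _superior_sign(alpha, landmarks, mesh)
    anterior_ref = 0.5 * (landmarks.ant_medial_edge + landmarks.ant_lateral_edge)
    posterior_ref = 0.5 * (landmarks.post_medial_edge + landmarks.pl_edge)
    y_sign = float(beta.normal @ (anterior_ref - posterior_ref))
    if abs(y_sign) < 1e-9:
        raise GeometryError("anterior direction ambiguous for the beta normal")
    y_dir = beta.normal * (1.0 if y_sign > 0 else -1.0)
    x_dir = np.cross(y_dir, z_dir)
    rotation = np.stack([x_dir, y_dir, z_dir])
    return AnatomicalFrame(rotation=rotation, centerpoint=origin, side=side)
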