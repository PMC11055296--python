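"""Synthetic trochlea-like surfaces with analytically known regional radii.

The generator emulates the superior articular surface of the talus: two
anteroposteriorly running crests (medial and lateral) whose sagittal profiles
are a pair of circular arcs tangent at the apex, with independent anterior
and posterior radii per crest; a shallow central groove between the crests;
and a short shoulder ramp on each side descending to a flat rim (the "thin
skirt"), which widens anteriorly the way a real trochlea does.

Because each sagittal profile is exactly two tangent arcs whose radii vary
only mediolaterally, the radii measured by the full pipeline (coronal-station
top points, nearly sagittal sections, three-point circumcircles) have exact
closed-form ground truth: the crest radii themselves for the four corner
regions, and the mid-station (x = 0) radii for the midsagittal pair.

Geometry conventions (generator frame, right-side specimen):
+X lateral, +Y anterior, +Z superior; the medial crest runs along x = -x_c,
the lateral along x = +x_c; each profile's apex sits at y = 0, the midpoint
of the articular anteroposterior extent, so arc-length midpoints sampled by
the measurement stay on a single arc.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, ValidationError
from .mesh_io import LandmarkSet, SurfaceMesh

__all__ = [
    "TrochleaSpec",
    "GroundTruth",
    "generate_trochlea",
    "generate_cylinder_patch",
    "PRESETS",
    "preset_spec",
]


@dataclass(frozen=True)
class TrochleaSpec:
    """Parameters of a synthetic trochlea (all lengths mm).

    The four crest radii default to the regional means reported for adult
    tali (anteromedial smallest, posteromedial largest). ``r_mid_ant`` and
    ``r_mid_post`` optionally pin the arc radii of the midsagittal (x = 0)
    profile; when ``None`` the radius field is linear between the crests and
    the mid radii are the crest means.
    """

    r_med_ant: float = 15.97
    r_med_post: float = 34.17
    r_lat_ant: float = 22.06
    r_lat_post: float = 27.95
    r_mid_ant: float | None = None
    r_mid_post: float | None = None
    crest_halfwidth: float = 13.0   # x_c: crest lines at x = +/- x_c
    groove_depth: float = 2.5       # apex dip at x = 0
    anterior_halfwidth_extra: float = 2.0  # extra shoulder width at the anterior end
    ap_extent: float = 24.0         # articular anteroposterior length (corners at +/- L/2)
    ap_margin: float = 1.0          # mesh continues this far beyond the corners
    rim_drop: float = 2.0           # rim level below the lowest crest corner
    shoulder_slope: float = 1.5     # nominal descent rate of the shoulder ramp
    base_height: float = 30.0       # z of the crest apex in the generator frame
    grid_nx: int = 200
    grid_ny: int = 200
    noise_sd: float = 0.0           # Gaussian vertex noise along z
    seed: int = 0
    side: str = "right"             # "left" mirrors the specimen about x = 0

    def validate(self) -> "TrochleaSpec":
        radii = [self.r_med_ant, self.r_med_post, self.r_lat_ant, self.r_lat_post]
        radii += [r for r in (self.r_mid_ant, self.r_mid_post) if r is not None]
        if any(r <= 0 for r in radii):
            raise ValidationError("all arc radii must be positive")
        if self.groove_depth < 0:
            raise ValidationError("groove_depth must be >= 0")
        if self.grid_nx < 16 or self.grid_ny < 16:
            raise ValidationError("grid counts must be >= 16")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.crest_halfwidth <= 0 or self.ap_extent <= 0:
            raise ValidationError("crest_halfwidth and ap_extent must be positive")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        # Each arc must span from its apex to the mesh edge: an arc of radius r
        # only reaches y = r, so the two arcs cannot meet tangentially at the
        # apex and still cover the requested extent when r is too small.
        reach = self.ap_extent / 2.0 + self.ap_margin
        if min(radii) <= reach:
            raise GeometryError(
                f"arc radius {min(radii):.2f} mm cannot span half-extent + margin "
                f"{reach:.2f} mm; arcs cannot meet tangentially for these extents"
            )
        return self

    @property
    def mid_ant(self) -> float:
        return (
            self.r_mid_ant
            if self.r_mid_ant is not None
            else 0.5 * (self.r_med_ant + self.r_lat_ant)
        )

    @property
    def mid_post(self) -> float:
        return (
            self.r_mid_post
            if self.r_mid_post is not None
            else 0.5 * (self.r_med_post + self.r_lat_post)
        )


@dataclass
class GroundTruth:
    """Analytic truth for one generated specimen."""

    r_am: float
    r_al: float
    r_pm: float
    r_pl: float
    r_ma: float
    r_mp: float
    landmarks: LandmarkSet
    cylinder_equivalent_radius: float | None = None

    def radii(self) -> dict:
        return {
            "r_am": self.r_am,
            "r_al": self.r_al,
            "r_pm": self.r_pm,
            "r_pl": self.r_pl,
            "r_ma": self.r_ma,
            "r_mp": self.r_mp,
        }

    def as_dict(self) -> dict:
        doc = {k: float(v) for k, v in self.radii().items()}
        doc["cylinder_equivalent_radius"] = (
            None
            if self.cylinder_equivalent_radius is None
            else float(self.cylinder_equivalent_radius)
        )
        doc["landmarks"] = self.landmarks.as_dict()
        return doc


def arc_drop(r: float, y: float) -> float:
    """Height drop of an apex-tangent arc of radius r at offset y from the apex."""
    return float(r - np.sqrt(r * r - y * y))


def _check_feasibility(spec: TrochleaSpec) -> None:
    """Reject parameter combinations that break the trochlear geometry.

    Two conditions, both evaluated at the articular corners (|y| = L/2):

    * crest dominance — the groove center must stay below each crest, i.e.
      the groove depth must exceed the arc-drop difference when a mid radius
      is larger than its crest radius; otherwise the crest top points (maxima
      of the coronal sections) would migrate into the groove;
    * dome sagitta — the apex must rise above the corner-chord plane by a
      safe margin, or the three-point centerpoint circle becomes nearly
      collinear and the fitted talar center meaningless.
    """
    half = spec.ap_extent / 2.0
    drops = {
        "am": arc_drop(spec.r_med_ant, half),
        "al": arc_drop(spec.r_lat_ant, half),
        "pm": arc_drop(spec.r_med_post, half),
        "pl": arc_drop(spec.r_lat_post, half),
    }
    mids = {"ant": arc_drop(spec.mid_ant, half), "post": arc_drop(spec.mid_post, half)}
    worst = max(
        drops["am"] - mids["ant"],
        drops["al"] - mids["ant"],
        drops["pm"] - mids["post"],
        drops["pl"] - mids["post"],
    )
    if worst > spec.groove_depth - CREST_MARGIN:
        raise GeometryError(
            f"groove depth {spec.groove_depth:.2f} mm too shallow for the radius "
            f"field (crest-to-mid arc-drop difference {worst:.2f} mm): the groove "
            "center would rise above a crest"
        )
    sagitta = np.mean(list(drops.values())) - spec.groove_depth
    if sagitta < SAGITTA_MARGIN:
        raise GeometryError(
            f"dome sagitta {sagitta:.2f} mm below the safe minimum "
            f"{SAGITTA_MARGIN} mm: the centerpoint circle would be nearly "
            "collinear (flat dome)"
        )


#: Safety margins (mm) for the generator feasibility checks.
CREST_MARGIN = 0.25
SAGITTA_MARGIN = 0.5


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _interp_radius(x, x_c, r_med, r_mid, r_lat):
    """Radius field over knots (-x_c, 0, +x_c): smoothstep per half, clamped
    at the crests.

    The zero derivative at every knot keeps the crest lines and the
    midsagittal profile stationary in x, so the top points and section planes
    recovered from a discretized mesh carry only second-order error.
    """
    x = np.clip(np.asarray(x, dtype=float), -x_c, x_c)
    medial = r_med + (r_mid - r_med) * _smoothstep((x + x_c) / x_c)
    lateral = r_mid + (r_lat - r_mid) * _smoothstep(x / x_c)
    return np.where(x < 0, medial, lateral)


def _arc_z(apex_z, r, y):
    """Height of a circular arc of radius ``r`` with apex (tangent point) at y=0."""
    return apex_z - r + np.sqrt(r * r - y * y)


def _surface_height(spec: TrochleaSpec, x, y):
    """Vectorized z(x, y) of the noise-free surface (generator frame)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_c = spec.crest_halfwidth
    H0 = spec.base_height
    ant = y >= 0
    ra = _interp_radius(x, x_c, spec.r_med_ant, spec.mid_ant, spec.r_lat_ant)
    rp = _interp_radius(x, x_c, spec.r_med_post, spec.mid_post, spec.r_lat_post)
    r = np.where(ant, ra, rp)
    inside = np.abs(x) <= x_c
    # squared profile: the dip's x-derivative vanishes at the crests, keeping
    # the surface smooth across the crest lines
    dip = spec.groove_depth * np.clip(1.0 - (x / x_c) ** 2, 0.0, None) ** 2
    z_inside = _arc_z(H0 - dip, r, y)
    # shoulder: quadratic ramp from the crest profile down to the flat rim
    # (zero slope at the crest, steepest at the rim edge)
    z_crest = _arc_z(H0, r, y)  # radii are clamped at the crest for |x| > x_c
    z_rim = _rim_level(spec)
    halfw = _border_halfwidth(spec, y, np.sign(x))
    frac = np.clip((np.abs(x) - x_c) / np.maximum(halfw - x_c, 1e-12), 0.0, 1.0)
    z_outside = z_crest - (z_crest - z_rim) * frac**2
    return np.where(inside, z_inside, z_outside)


def _rim_level(spec: TrochleaSpec) -> float:
    reach = spec.ap_extent / 2.0 + spec.ap_margin
    H0 = spec.base_height
    corner_z = [
        _arc_z(H0, r, reach)
        for r in (spec.r_med_ant, spec.r_med_post, spec.r_lat_ant, spec.r_lat_post)
    ]
    return float(min(corner_z) - spec.rim_drop)


def _border_halfwidth(spec: TrochleaSpec, y, sign):
    """|x| of the rim border at anteroposterior position y, per side (sign of x).

    Width = crest halfwidth + ramp width needed for the quadratic shoulder to
    descend from the crest profile to the rim (reaching ``shoulder_slope`` at
    the rim edge), plus a linear anterior widening.
    """
    y = np.asarray(y, dtype=float)
    ant = y >= 0
    r_med = np.where(ant, spec.r_med_ant, spec.r_med_post)
    r_lat = np.where(ant, spec.r_lat_ant, spec.r_lat_post)
    r = np.where(np.asarray(sign) < 0, r_med, r_lat)
    z_crest = _arc_z(spec.base_height, r, y)
    z_rim = _rim_level(spec)
    total = spec.ap_extent + 2.0 * spec.ap_margin
    t = (y + total / 2.0) / total  # 0 at the posterior mesh edge, 1 anterior
    return (
        spec.crest_halfwidth
        + 2.0 * (z_crest - z_rim) / spec.shoulder_slope
        + spec.anterior_halfwidth_extra * t
    )


def _grid_mesh(spec: TrochleaSpec) -> SurfaceMesh:
    ny, nx = spec.grid_ny, spec.grid_nx
    reach = spec.ap_extent / 2.0 + spec.ap_margin
    y = np.linspace(-reach, reach, ny)
    b_med = _border_halfwidth(spec, y, -1.0)
    b_lat = _border_halfwidth(spec, y, +1.0)
    u = np.linspace(0.0, 1.0, nx)
    X = -b_med[:, None] + u[None, :] * (b_med + b_lat)[:, None]
    Y = np.broadcast_to(y[:, None], X.shape)
    Z = _surface_height(spec, X, Y)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(ny * nx).reshape(ny, nx)
    q00 = idx[:-1, :-1].ravel()
    q10 = idx[:-1, 1:].ravel()
    q01 = idx[1:, :-1].ravel()
    q11 = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([q00, q10, q11]), np.column_stack([q00, q11, q01])]
    )
    return SurfaceMesh(vertices, faces)


def _landmarks(spec: TrochleaSpec) -> LandmarkSet:
    x_c = spec.crest_halfwidth
    H0 = spec.base_height
    L2 = spec.ap_extent / 2.0
    reach = L2 + spec.ap_margin
    z_rim = _rim_level(spec)
    return LandmarkSet(
        am_edge=[-x_c, L2, _arc_z(H0, spec.r_med_ant, L2)],
        pm_edge=[-x_c, -L2, _arc_z(H0, spec.r_med_post, L2)],
        al_edge=[x_c, L2, _arc_z(H0, spec.r_lat_ant, L2)],
        pl_edge=[x_c, -L2, _arc_z(H0, spec.r_lat_post, L2)],
        ant_medial_edge=[-float(_border_halfwidth(spec, reach, -1.0)), reach, z_rim],
        post_medial_edge=[-float(_border_halfwidth(spec, -reach, -1.0)), -reach, z_rim],
        ant_lateral_edge=[float(_border_halfwidth(spec, reach, +1.0)), reach, z_rim],
    )


def _mirror_x(mesh: SurfaceMesh, landmarks: LandmarkSet):
    verts = mesh.vertices.copy()
    verts[:, 0] *= -1.0
    faces = mesh.faces[:, ::-1].copy()  # restore outward orientation
    mirrored = SurfaceMesh(verts, faces, mesh.specimen_id)

    def flip(pts):
        pts = np.array(pts, dtype=float)
        pts[..., 0] *= -1.0
        return pts

    return mirrored, landmarks.transformed(flip)


def generate_trochlea(spec: TrochleaSpec) -> tuple[SurfaceMesh, GroundTruth]:
    """Generate one trochlea mesh with exact landmarks and ground-truth radii.

    Deterministic: the same spec (including seed) yields a bit-identical mesh.
    Gaussian vertex noise, when requested, is applied along z only so the
    parametric grid stays single-valued in (x, y).
    """
    spec.validate()
    _check_feasibility(spec)
    mesh = _grid_mesh(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mesh.vertices[:, 2] += rng.normal(0.0, spec.noise_sd, mesh.n_vertices)
    landmarks = _landmarks(spec)
    if spec.side == "left":
        mesh, landmarks = _mirror_x(mesh, landmarks)
    gt = GroundTruth(
        r_am=spec.r_med_ant,
        r_al=spec.r_lat_ant,
        r_pm=spec.r_med_post,
        r_pl=spec.r_lat_post,
        r_ma=spec.mid_ant,
        r_mp=spec.mid_post,
        landmarks=landmarks,
        cylinder_equivalent_radius=None,
    )
    return mesh.validate(), gt


def generate_cylinder_patch(
    radius: float,
    axis_extent: float = 30.0,
    arc_span: float = 120.0,
    grid: int | tuple[int, int] = 257,
    corner_inset: float = 0.92,
) -> tuple[SurfaceMesh, GroundTruth]:
    """Patch of a right circular cylinder with its axis along x (mediolateral).

    All six ground-truth radii equal ``radius``; this is the exact oracle for
    the cylinder fit and for every section-based measurement. The four corner
    landmarks sit at ``corner_inset`` of the angular half-span so that the
    coronal station planes cut the interior of the patch, not its boundary.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    if not (30.0 <= arc_span <= 180.0):
        raise GeometryError(f"arc_span must be in [30, 180] degrees, got {arc_span}")
    if axis_extent <= 0:
        raise ValidationError("axis_extent must be positive")
    nx, ny = (grid, grid) if isinstance(grid, int) else grid
    if nx < 16 or ny < 16:
        raise ValidationError("grid counts must be >= 16")
    half = np.deg2rad(arc_span) / 2.0
    W = axis_extent / 2.0
    zc = 0.0
    t = np.linspace(-half, half, ny)  # angle from the apex, positive anterior
    x = np.linspace(-W, W, nx)
    X, T = np.meshgrid(x, t)
    Y = radius * np.sin(T)
    Z = zc + radius * np.cos(T)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(ny * nx).reshape(ny, nx)
    faces = np.concatenate(
        [
            np.column_stack([idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel(), idx[1:, 1:].ravel()]),
            np.column_stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), idx[1:, :-1].ravel()]),
        ]
    )
    mesh = SurfaceMesh(vertices, faces).validate()

    # Corner and border landmarks share the inset angle: a cylinder patch has
    # sagittal-parallel borders, so "most anterior border point" is ours to
    # place, and the symmetric choice keeps the datum planes exactly axial.
    t_lm = corner_inset * half
    y_lm, z_lm = radius * np.sin(t_lm), zc + radius * np.cos(t_lm)
    landmarks = LandmarkSet(
        am_edge=[-W, y_lm, z_lm],
        pm_edge=[-W, -y_lm, z_lm],
        al_edge=[W, y_lm, z_lm],
        pl_edge=[W, -y_lm, z_lm],
        ant_medial_edge=[-W, y_lm, z_lm],
        post_medial_edge=[-W, -y_lm, z_lm],
        ant_lateral_edge=[W, y_lm, z_lm],
    )
    gt = GroundTruth(
        r_am=radius,
        r_al=radius,
        r_pm=radius,
        r_pl=radius,
        r_ma=radius,
        r_mp=radius,
        landmarks=landmarks,
        cylinder_equivalent_radius=radius,
    )
    return mesh, gt


#: Named generator presets. "reference" pins all six regional radii to the
#: cohort means of the published reference summaries; "ordered" uses strictly
#: separated radii in the anatomical ordering PM > PL > MP > AL > MA > AM.
PRESETS: dict[str, dict] = {
    "asymmetric": dict(
        r_med_ant=16.0, r_med_post=34.0, r_lat_ant=22.0, r_lat_post=28.0
    ),
    "reference": dict(
        r_med_ant=15.97,
        r_med_post=34.17,
        r_lat_ant=22.06,
        r_lat_post=27.95,
        r_mid_ant=16.97,
        r_mid_post=22.44,
    ),
    "ordered": dict(
        r_med_ant=16.0,
        r_mid_ant=20.0,
        r_lat_ant=24.0,
        r_mid_post=28.0,
        r_lat_post=32.0,
        r_med_post=36.0,
    ),
}


def preset_spec(name: str, **overrides) -> TrochleaSpec:
    """A :class:`TrochleaSpec` for a named preset, with keyword overrides."""
    if name == "cylinder":
        raise ValueError("use generate_cylinder_patch for the cylinder preset")
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return TrochleaSpec(**params)
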