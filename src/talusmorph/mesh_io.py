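"""Reading, writing and validation of meshes, landmarks, manifests and records.

All lengths are millimetres end-to-end. Meshes are triangulated surfaces in
STL (ASCII or binary); landmarks are a JSON document with seven fixed keys;
cohort manifests and per-specimen measurement records are UTF-8 CSV.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .errors import FormatError, GeometryError, SchemaError, ValidationError

#: The seven anatomical landmark names. The four corner edges bound the
#: trochlear articular surface; the three border extremes define the
#: transverse datum plane.
LANDMARK_NAMES = (
    "am_edge",
    "pm_edge",
    "al_edge",
    "pl_edge",
    "ant_medial_edge",
    "post_medial_edge",
    "ant_lateral_edge",
)

#: Columns of a per-specimen measurement record.
RECORD_COLUMNS = (
    "specimen_id",
    "sex",
    "age",
    "side",
    "r_am",
    "r_al",
    "r_pm",
    "r_pl",
    "r_ma",
    "r_mp",
    "r_cyl",
    "cyl_rms",
)

_RADIUS_COLUMNS = ("r_am", "r_al", "r_pm", "r_pl", "r_ma", "r_mp", "r_cyl", "cyl_rms")

#: Vertices closer than this are merged on read so faces share indices (mm).
MERGE_TOLERANCE = 1e-6


@dataclass
class SurfaceMesh:
    """A triangulated surface in mm.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    specimen_id : identifier carried through the pipeline
    """

    vertices: np.ndarray
    faces: np.ndarray
    specimen_id: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def transformed(self, apply) -> "SurfaceMesh":
        """Return a copy with ``apply`` (an (n,3)->(n,3) map) applied to vertices."""
        return SurfaceMesh(apply(self.vertices), self.faces.copy(), self.specimen_id)

    def validate(self) -> "SurfaceMesh":
        """Check the domain invariants; raise :class:`ValidationError` on failure."""
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("mesh contains non-finite vertex coordinates")
        if self.n_vertices < 4 or self.n_faces < 4:
            raise ValidationError(
                f"mesh too small: {self.n_vertices} vertices, {self.n_faces} faces "
                "(need at least 4 of each)"
            )
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise ValidationError("face references an out-of-range vertex index")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if np.any(areas <= 0.0):
            raise ValidationError(f"{int(np.sum(areas <= 0))} zero-area faces present")
        return self


@dataclass
class LandmarkSet:
    """The seven named anatomical points (mm) digitized on the trochlea."""

    am_edge: np.ndarray
    pm_edge: np.ndarray
    al_edge: np.ndarray
    pl_edge: np.ndarray
    ant_medial_edge: np.ndarray
    post_medial_edge: np.ndarray
    ant_lateral_edge: np.ndarray

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in LANDMARK_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {name: getattr(self, name).tolist() for name in LANDMARK_NAMES}

    def as_array(self) -> np.ndarray:
        """(7, 3) array in :data:`LANDMARK_NAMES` order."""
        return np.stack([getattr(self, name) for name in LANDMARK_NAMES])

    def transformed(self, apply) -> "LandmarkSet":
        pts = apply(self.as_array())
        return LandmarkSet(*pts)

    def corner_quad(self) -> np.ndarray:
        """The four trochlear corner edges in cyclic order (am, al, pl, pm)."""
        return np.stack([self.am_edge, self.al_edge, self.pl_edge, self.pm_edge])

    def alpha_triplet(self) -> np.ndarray:
        """The three border-extreme points defining the transverse datum plane."""
        return np.stack(
            [self.ant_medial_edge, self.post_medial_edge, self.ant_lateral_edge]
        )

    def validate(
        self,
        mesh: SurfaceMesh | None = None,
        surface_tolerance: float = 2.0,
    ) -> "LandmarkSet":
        """Check finiteness, non-collinearity of the datum triplet and, when a
        mesh is supplied, proximity of every landmark to the surface.

        Surface proximity is assessed as nearest-vertex distance, so the
        tolerance should comfortably exceed the mesh edge length; its purpose
        is catching gross mislabels, not sub-millimetre digitization error.
        """
        pts = self.as_array()
        if not np.all(np.isfinite(pts)):
            raise ValidationError("landmark coordinates must be finite")
        a, b, c = self.alpha_triplet()
        area2 = np.linalg.norm(np.cross(b - a, c - a))
        if area2 <= 2e-9:  # triangle area > 1e-9 mm^2
            raise GeometryError(
                "datum triplet (ant_medial_edge, post_medial_edge, ant_lateral_edge) "
                "is collinear; it cannot define the transverse plane"
            )
        if mesh is not None:
            from scipy.spatial import cKDTree

            dist, _ = cKDTree(mesh.vertices).query(pts)
            worst = dist.max()
            if worst > surface_tolerance:
                name = LANDMARK_NAMES[int(np.argmax(dist))]
                raise ValidationError(
                    f"landmark '{name}' lies {worst:.2f} mm from the mesh surface "
                    f"(tolerance {surface_tolerance} mm)"
                )
        return self


@dataclass
class ManifestRow:
    specimen_id: str
    sex: str
    age: float
    side: str
    mesh_path: str
    landmark_path: str


def read_mesh(path: str | os.PathLike, specimen_id: str | None = None) -> SurfaceMesh:
    """Read an ASCII or binary STL file into a validated :class:`SurfaceMesh`.

    Duplicate vertices within :data:`MERGE_TOLERANCE` are merged so that
    faces share indices (STL stores three loose vertices per facet).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"mesh file not found: {path}")
    if os.path.getsize(path) == 0:
        raise FormatError(f"mesh file is empty: {path}")
    try:
        tm = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:
        raise FormatError(f"could not parse STL file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"STL file {path} contains no triangles")
    tm.merge_vertices(digits_vertex=int(round(-math.log10(MERGE_TOLERANCE))))
    tm.update_faces(tm.nondegenerate_faces())
    sid = specimen_id or os.path.splitext(os.path.basename(path))[0]
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), sid)
    try:
        return mesh.validate()
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_mesh(mesh: SurfaceMesh, path: str | os.PathLike, ascii: bool = False) -> None:
    """Write a mesh to STL (binary by default; ASCII loses precision)."""
    tm = mesh.to_trimesh()
    file_type = "stl_ascii" if ascii else "stl"
    tm.export(os.fspath(path), file_type=file_type)


def read_landmarks(
    path: str | os.PathLike,
    mesh: SurfaceMesh | None = None,
    surface_tolerance: float = 2.0,
) -> LandmarkSet:
    """Read a landmark JSON file (seven fixed keys, each a 3-number array, mm)."""
    path = os.fspath(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except FileNotFoundError:
        raise FormatError(f"landmark file not found: {path}")
    except json.JSONDecodeError as exc:
        raise FormatError(f"landmark file {path} is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"landmark file {path} must contain a JSON object")
    missing = [n for n in LANDMARK_NAMES if n not in doc]
    if missing:
        raise SchemaError(
            f"landmark file {path} is missing required key(s): {', '.join(missing)}"
        )
    pts = {}
    for name in LANDMARK_NAMES:
        value = doc[name]
        arr = np.asarray(value, dtype=float)
        if arr.shape != (3,):
            raise SchemaError(
                f"landmark '{name}' in {path} must be a 3-number array, got {value!r}"
            )
        pts[name] = arr
    lms = LandmarkSet(**pts)
    return lms.validate(mesh=mesh, surface_tolerance=surface_tolerance)


def write_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        json.dump(landmarks.as_dict(), fh, indent=2)
        fh.write("\n")


def read_manifest(path: str | os.PathLike, check_files: bool = True) -> list[ManifestRow]:
    """Read a cohort manifest CSV and check its invariants."""
    path = os.fspath(path)
    try:
        df = pd.read_csv(path, dtype={"specimen_id": str})
    except FileNotFoundError:
        raise FormatError(f"manifest not found: {path}")
    except Exception as exc:
        raise FormatError(f"could not parse manifest {path}: {exc}") from exc
    required = {"specimen_id", "sex", "age", "side", "mesh_path", "landmark_path"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"manifest {path} missing column(s): {sorted(missing)}")
    rows: list[ManifestRow] = []
    seen: set[tuple[str, str]] = set()
    base = os.path.dirname(os.path.abspath(path))
    for _, rec in df.iterrows():
        sex = str(rec["sex"]).strip().lower()
        side = str(rec["side"]).strip().lower()
        if sex not in ("male", "female"):
            raise SchemaError(f"manifest sex must be male/female, got {rec['sex']!r}")
        if side not in ("left", "right"):
            raise SchemaError(f"manifest side must be left/right, got {rec['side']!r}")
        age = float(rec["age"])
        if not age > 0:
            raise SchemaError(f"manifest age must be positive, got {age}")
        key = (str(rec["specimen_id"]), side)
        if key in seen:
            raise SchemaError(f"duplicate (specimen_id, side) in manifest: {key}")
        seen.add(key)
        mesh_path = str(rec["mesh_path"])
        lm_path = str(rec["landmark_path"])
        if not os.path.isabs(mesh_path):
            mesh_path = os.path.join(base, mesh_path)
        if not os.path.isabs(lm_path):
            lm_path = os.path.join(base, lm_path)
        if check_files:
            for p in (mesh_path, lm_path):
                if not os.path.exists(p):
                    raise ValidationError(f"manifest references missing file: {p}")
        rows.append(ManifestRow(str(rec["specimen_id"]), sex, age, side, mesh_path, lm_path))
    return rows


def record_row(
    specimen_id: str,
    sex: str,
    age: float,
    side: str,
    radii,  # RegionRadiusSet (duck-typed to avoid a circular import)
) -> dict:
    """Assemble one record dict from metadata plus a measured radius set."""
    row = {"specimen_id": specimen_id, "sex": sex, "age": age, "side": side}
    for col in _RADIUS_COLUMNS:
        row[col] = float(getattr(radii, col))
    return row


def write_records(records: list[dict], path: str | os.PathLike) -> None:
    """Write measurement records to CSV with radii formatted to 4 decimals."""
    df = pd.DataFrame(records, columns=list(RECORD_COLUMNS))
    for col in _RADIUS_COLUMNS:
        df[col] = df[col].map(lambda v: f"{float(v):.4f}")
    try:
        df.to_csv(os.fspath(path), index=False)
    except OSError as exc:
        raise FormatError(f"cannot write records to {path}: {exc}") from exc


def read_records(path: str | os.PathLike) -> pd.DataFrame:
    """Read a records CSV back into a typed DataFrame."""
    try:
        df = pd.read_csv(os.fspath(path), dtype={"specimen_id": str})
    except FileNotFoundError:
        raise FormatError(f"records file not found: {path}")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"records file {path} missing column(s): {sorted(missing)}")
    for col in _RADIUS_COLUMNS:
        df[col] = df[col].astype(float)
    df["age"] = df["age"].astype(float)
    return df
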