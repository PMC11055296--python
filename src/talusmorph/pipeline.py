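"""End-to-end measurement orchestration.

``measure_specimen`` runs the full chain for one talus: standardize into the
anatomical frame, place the six coronal stations, find the crest tops, cut
the four nearly sagittal crest sections and the midsagittal section, measure
the six regional radii, separate the trochlear patch and fit the cylinder.
``run_batch`` applies it across a cohort manifest with per-specimen failure
isolation, and ``make_synthetic_cohort`` writes a fully synthetic cohort
(meshes, landmarks, ground truth, manifest) for validation studies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mesh_io
from .curvature import (
    RegionRadiusSet,
    extract_trochlear_patch,
    fit_cylinder,
    midsagittal_radii,
    region_radius,
)
from .errors import TalusMorphError, ValidationError
from .frame import build_frame
from .mesh_io import LandmarkSet, SurfaceMesh
from .sectioning import (
    mesh_plane_intersection,
    region_section_plane,
    station_planes,
    top_point,
    StationTops,
)
from .synthetic import TrochleaSpec, generate_trochlea, preset_spec
from .errors import GeometryError

__all__ = [
    "PipelineConfig",
    "RunLog",
    "measure_specimen",
    "run_batch",
    "make_synthetic_cohort",
    "COHORT_PROFILES",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable tolerances and controls of the measurement chain."""

    landmark_surface_tol: float = 2.0  # mm, gross-mislabel check
    snap_tol: float = 0.5              # mm, endpoint snapping onto section curves
    patch_margin: float = 0.0          # mm, inflation of the corner quadrilateral
    cyl_max_iter: int = 200
    cyl_gtol: float = 1e-10
    age_cut: float | str = "median"
    precision: int = 4                 # decimals in written records
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.landmark_surface_tol <= 0 or self.snap_tol <= 0:
            raise ValidationError("tolerances must be positive")
        if self.cyl_max_iter < 1 or self.cyl_gtol <= 0:
            raise ValidationError("cylinder-fit controls must be positive")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        return self

    def hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Load overrides from a simple ``key = value`` text file."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        overrides: dict = {}
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
                if key == "age_cut" and value != "median":
                    overrides[key] = float(value)
                elif key in ("cyl_max_iter", "precision", "seed"):
                    overrides[key] = int(value)
                elif key == "age_cut":
                    overrides[key] = value
                else:
                    overrides[key] = float(value)
        return cls(**overrides).validate()


@dataclass
class RunLog:
    """Per-specimen status and warnings for a pipeline run."""

    config_hash: str = ""
    entries: list = field(default_factory=list)

    def add(self, specimen_id: str, status: str, detail: str = "", warnings=()):
        if any(e["specimen_id"] == specimen_id for e in self.entries):
            raise ValidationError(f"specimen {specimen_id!r} already logged")
        self.entries.append(
            {
                "specimen_id": specimen_id,
                "status": status,
                "detail": detail,
                "warnings": list(warnings),
            }
        )

    @property
    def n_succeeded(self) -> int:
        return sum(e["status"] == "ok" for e in self.entries)

    @property
    def n_failed(self) -> int:
        return sum(e["status"] == "failed" for e in self.entries)

    def summary(self) -> str:
        return f"{self.n_succeeded} succeeded / {self.n_failed} failed"


def _find_tops(mesh: SurfaceMesh, planes: dict) -> StationTops:
    """Top points of the six coronal stations.

    For each station the top is searched across every section curve of that
    plane and taken from the curve carrying the highest point in the
    station's half.
    """
    tops = {}
    for name, half in (
        ("am", "medial"), ("mid_medial", "medial"), ("pm", "medial"),
        ("al", "lateral"), ("mid_lateral", "lateral"), ("pl", "lateral"),
    ):
        curves = mesh_plane_intersection(mesh, planes[name])
        best = None
        for curve in curves:
            try:
                candidate = top_point(curve, half)
            except GeometryError:
                continue
            if best is None or candidate[2] > best[2]:
                best = candidate
        if best is None:
            raise GeometryError(f"station '{name}' produced no {half} section points")
        tops[f"{name}_top"] = best
    return StationTops(**tops).validate()


def measure_specimen(
    mesh: SurfaceMesh | str | os.PathLike,
    landmarks: LandmarkSet | str | os.PathLike,
    side: str = "right",
    config: PipelineConfig | None = None,
) -> tuple[RegionRadiusSet, dict]:
    """Measure the six regional radii and the cylinder-fit radius of one talus.

    Accepts in-memory objects or file paths. Returns the radius set and a
    log-entry dict (warnings include cylinder-fit iteration counts and any
    degenerate fallbacks). Deterministic given inputs and config.
    """
    cfg = (config or PipelineConfig()).validate()
    if not isinstance(mesh, SurfaceMesh):
        mesh = mesh_io.read_mesh(mesh)
    mesh.validate()
    if not isinstance(landmarks, LandmarkSet):
        landmarks = mesh_io.read_landmarks(
            landmarks, mesh=mesh, surface_tolerance=cfg.landmark_surface_tol
        )
    else:
        landmarks.validate(mesh=mesh, surface_tolerance=cfg.landmark_surface_tol)

    warnings: list[str] = []
    frame = build_frame(mesh, landmarks, side=side)
    std_mesh = frame.apply_mesh(mesh)
    std_lms = frame.apply_landmarks(landmarks)

    planes = station_planes(std_lms)
    tops = _find_tops(std_mesh, planes)

    sections = {
        "am": (tops.am_top, tops.mid_medial_top),
        "pm": (tops.pm_top, tops.mid_medial_top),
        "al": (tops.al_top, tops.mid_lateral_top),
        "pl": (tops.pl_top, tops.mid_lateral_top),
    }
    radii: dict[str, float] = {}
    for name, (end_a, end_b) in sections.items():
        plane = region_section_plane(end_a, end_b, std_mesh)
        radii[f"r_{name}"] = region_radius(
            std_mesh, plane, end_a, end_b, snap_tolerance=cfg.snap_tol
        )

    r_ma, r_mp = midsagittal_radii(std_mesh, landmarks=std_lms, snap_tolerance=cfg.snap_tol)

    patch_idx = extract_trochlear_patch(std_mesh, std_lms, margin=cfg.patch_margin)
    fit = fit_cylinder(
        std_mesh.vertices[patch_idx],
        init_axis=(1.0, 0.0, 0.0),
        max_iter=cfg.cyl_max_iter,
        gtol=cfg.cyl_gtol,
    )
    warnings.append(f"cylinder fit: {fit.iterations} evaluations, rms {fit.rms:.4f} mm")

    result = RegionRadiusSet(
        **radii, r_ma=r_ma, r_mp=r_mp, r_cyl=fit.radius, cyl_rms=fit.rms
    ).validate()
    entry = {
        "specimen_id": mesh.specimen_id,
        "status": "ok",
        "detail": "",
        "warnings": warnings,
    }
    return result, entry


def run_batch(
    manifest: list[mesh_io.ManifestRow] | str | os.PathLike,
    config: PipelineConfig | None = None,
    out_csv: str | os.PathLike | None = None,
) -> tuple[list[dict], RunLog]:
    """Measure every specimen in a manifest; one failure never stops the batch."""
    cfg = (config or PipelineConfig()).validate()
    if not isinstance(manifest, list):
        manifest = mesh_io.read_manifest(manifest)
    if len(manifest) == 0:
        raise ValidationError("manifest contains no specimens")
    log = RunLog(config_hash=cfg.hash())
    records: list[dict] = []
    for row in manifest:
        uid = f"{row.specimen_id}_{row.side}"
        try:
            mesh = mesh_io.read_mesh(row.mesh_path, specimen_id=uid)
            lms = mesh_io.read_landmarks(
                row.landmark_path, mesh=mesh, surface_tolerance=cfg.landmark_surface_tol
            )
            radii, entry = measure_specimen(mesh, lms, side=row.side, config=cfg)
        except TalusMorphError as exc:
            log.add(uid, "failed", detail=str(exc))
            continue
        records.append(
            mesh_io.record_row(row.specimen_id, row.sex, row.age, row.side, radii)
        )
        log.add(uid, "ok", warnings=entry["warnings"])
    if out_csv is not None and records:
        mesh_io.write_records(records, out_csv)
    return records, log


#: Cohort effect profiles: per-region population means (mm), per-region
#: between-specimen SDs (mm), and a multiplicative male effect.
COHORT_PROFILES: dict[str, dict] = {
    # separated means in the anatomical ordering PM > PL > MP > AL > MA > AM
    "ordered": {
        "means": {"am": 16.0, "ma": 20.0, "al": 24.0, "mp": 28.0, "pl": 32.0, "pm": 36.0},
        "sds": {"am": 3.1, "ma": 3.1, "al": 3.9, "mp": 5.0, "pl": 4.0, "pm": 5.0},
        "male_scale": 1.0,
    },
    # reference-cohort regional means with moderate spreads, no sex effect
    "null": {
        "means": {"am": 15.97, "ma": 16.97, "al": 22.06, "mp": 22.44, "pl": 27.95, "pm": 34.17},
        "sds": {"am": 3.1, "ma": 3.1, "al": 3.9, "mp": 5.0, "pl": 4.0, "pm": 5.0},
        "male_scale": 1.0,
    },
    # same means with male radii scaled up, as in the reference sex contrast
    "sexdiff": {
        "means": {"am": 15.97, "ma": 16.97, "al": 22.06, "mp": 22.44, "pl": 27.95, "pm": 34.17},
        "sds": {"am": 3.1, "ma": 3.1, "al": 3.9, "mp": 5.0, "pl": 4.0, "pm": 3.1},
        "male_scale": 1.12,
    },
}

#: Shorter articular extent for cohort specimens so small-radius draws stay
#: constructible (an arc of radius r only spans y in [-r, r]).
_COHORT_AP_EXTENT = 20.0
_COHORT_AP_MARGIN = 1.0
_MIN_RADIUS = _COHORT_AP_EXTENT / 2.0 + _COHORT_AP_MARGIN + 0.1


def _groove_depth_for(radii: dict) -> float | None:
    """A feasible groove depth for one specimen's six radii, or None.

    The groove must be deep enough that neither mid radius lifts the groove
    center above a crest, yet shallow enough that the dome keeps a positive
    sagitta over the corner-chord plane (see the generator feasibility
    checks). Returns the smallest comfortable depth within that window.
    """
    from .synthetic import CREST_MARGIN, SAGITTA_MARGIN, arc_drop

    half = _COHORT_AP_EXTENT / 2.0
    drops = {k: arc_drop(radii[k], half) for k in ("am", "al", "pm", "pl")}
    worst = max(
        drops["am"] - arc_drop(radii["ma"], half),
        drops["al"] - arc_drop(radii["ma"], half),
        drops["pm"] - arc_drop(radii["mp"], half),
        drops["pl"] - arc_drop(radii["mp"], half),
    )
    lo = max(1.0, worst + CREST_MARGIN + 0.05)
    hi = float(np.mean(list(drops.values()))) - SAGITTA_MARGIN - 0.05
    return lo if lo <= hi else None


def _draw_radii(rng, means, sds, scale, max_attempts: int = 500):
    """One specimen's six true radii plus its groove depth.

    Radii are drawn independently per region and the six-tuple is redrawn
    until it admits a feasible groove depth; this truncates the joint tails
    (a mid radius far above its crests, or a dome too flat to center) while
    leaving the per-region means close to their targets.
    """
    for _ in range(max_attempts):
        out = {}
        for key in ("am", "ma", "al", "mp", "pl", "pm"):
            value = rng.normal(means[key] * scale, sds[key])
            while value <= _MIN_RADIUS:
                value = rng.normal(means[key] * scale, sds[key])
            out[key] = float(value)
        groove = _groove_depth_for(out)
        if groove is not None:
            return out, groove
    raise ValidationError(
        "could not draw a geometrically feasible radius set; the effect "
        "profile's means/SDs are incompatible with the trochlea geometry"
    )


def make_synthetic_cohort(
    out_dir: str | os.PathLike,
    n_male: int = 28,
    n_female: int = 33,
    bilateral_fraction: float = 30 / 61,
    effect_profile: str = "null",
    seed: int = 0,
    grid: int = 96,
    side_jitter_sd: float = 0.3,
    noise_sd: float = 0.0,
) -> tuple[str, list[dict]]:
    """Write a synthetic cohort (STL + landmark JSON + ground truth + manifest).

    Subjects are assigned an age uniform on [14, 69]; a ``bilateral_fraction``
    of them contribute both sides, the rest one side, with sides balanced the
    way a clinical CT archive tends to be. Bilateral subjects share their
    subject-level radii; each talus adds independent per-side jitter. Returns
    the manifest path and the per-talus ground-truth records.
    """
    if effect_profile not in COHORT_PROFILES:
        raise ValidationError(
            f"unknown effect profile {effect_profile!r}; choose from {sorted(COHORT_PROFILES)}"
        )
    profile = COHORT_PROFILES[effect_profile]
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)

    manifest_rows = []
    truth_records = []
    subjects = [("male", i) for i in range(n_male)] + [("female", i) for i in range(n_female)]
    # deterministic bilateral count: the default demographics give exactly
    # 61 subjects -> 30 bilateral -> 91 tali
    n_bilateral = int(round(bilateral_fraction * len(subjects)))
    bilateral_idx = set(rng.permutation(len(subjects))[:n_bilateral].tolist())
    for subject_no, (sex, i) in enumerate(subjects):
        subject_id = f"{sex[0]}{i:03d}"
        age = float(rng.uniform(14.0, 69.0))
        scale = profile["male_scale"] if sex == "male" else 1.0
        base, _ = _draw_radii(rng, profile["means"], profile["sds"], scale)
        bilateral = subject_no in bilateral_idx
        sides = ["left", "right"] if bilateral else [rng.choice(["left", "right"])]
        for side in sides:
            groove = None
            while groove is None:  # re-jitter until the talus stays feasible
                radii = {
                    k: max(_MIN_RADIUS, v + rng.normal(0.0, side_jitter_sd))
                    for k, v in base.items()
                }
                groove = _groove_depth_for(radii)
            spec = TrochleaSpec(
                groove_depth=groove,
                r_med_ant=radii["am"],
                r_lat_ant=radii["al"],
                r_med_post=radii["pm"],
                r_lat_post=radii["pl"],
                r_mid_ant=radii["ma"],
                r_mid_post=radii["mp"],
                ap_extent=_COHORT_AP_EXTENT,
                ap_margin=_COHORT_AP_MARGIN,
                grid_nx=grid,
                grid_ny=grid,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                side=side,
            )
            mesh, gt = generate_trochlea(spec)
            stem = f"{subject_id}_{side}"
            mesh_path = os.path.join(out_dir, f"{stem}.stl")
            lm_path = os.path.join(out_dir, f"{stem}_landmarks.json")
            gt_path = os.path.join(out_dir, f"{stem}_truth.json")
            mesh_io.write_mesh(mesh, mesh_path)
            mesh_io.write_landmarks(gt.landmarks, lm_path)
            with open(gt_path, "w", encoding="utf-8") as fh:
                json.dump(gt.as_dict() | {"age": age, "sex": sex}, fh, indent=2)
            manifest_rows.append(
                {
                    "specimen_id": subject_id,
                    "sex": sex,
                    "age": round(age, 1),
                    "side": side,
                    "mesh_path": f"{stem}.stl",
                    "landmark_path": f"{stem}_landmarks.json",
                }
            )
            truth_records.append(
                {"specimen_id": subject_id, "sex": sex, "age": age, "side": side}
                | {f"r_{k}": v for k, v in radii.items()}
            )
    manifest_path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    return manifest_path, truth_records
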