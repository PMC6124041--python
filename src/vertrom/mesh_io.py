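"""Reading and writing vertebra meshes, column manifests and result tables.

A vertebral column is delivered as one triangle-mesh file per anatomical part
(Wavefront OBJ required; PLY and STL accepted) plus a JSON manifest listing
the vertebrae in anterior-to-posterior order.  Part names come from a
controlled vocabulary; coordinates are millimetres after loading (the manifest
declares its units and the loader rescales).

Angle tables are CSV with the stable header ``joint,profile,trial,angle_deg``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import (
    LandmarkError,
    LoadError,
    MeshValidationError,
    VocabularyError,
)

#: Controlled vocabulary of anatomical parts.
PART_NAMES = frozenset(
    {
        "centrum",
        "neural_spine",
        "prezygapophysis_L",
        "prezygapophysis_R",
        "postzygapophysis_L",
        "postzygapophysis_R",
        "cervical_rib_L",
        "cervical_rib_R",
    }
)

#: Pairs of left/right part names, for mirror operations.
MIRROR_PAIRS = {
    "prezygapophysis_L": "prezygapophysis_R",
    "prezygapophysis_R": "prezygapophysis_L",
    "postzygapophysis_L": "postzygapophysis_R",
    "postzygapophysis_R": "postzygapophysis_L",
    "cervical_rib_L": "cervical_rib_R",
    "cervical_rib_R": "cervical_rib_L",
}

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}

#: Local anatomical frame rows: anterior, left-lateral, dorsal.
DEFAULT_FRAME = np.eye(3)


@dataclass
class LabeledVertebraMesh:
    """One vertebra: per-part triangle surfaces plus anatomical landmarks.

    Coordinates are millimetres in the vertebra's local frame, whose rows are
    the anterior (+x), left-lateral (+y) and dorsal (+z) directions.
    """

    id: str
    parts: dict[str, trimesh.Trimesh]
    landmarks: dict[str, np.ndarray]
    frame: np.ndarray = field(default_factory=lambda: DEFAULT_FRAME.copy())

    def validate(self) -> None:
        if "centrum" not in self.parts:
            raise MeshValidationError(f"{self.id}: 'centrum' part is required")
        for name, mesh in self.parts.items():
            if name not in PART_NAMES:
                raise VocabularyError(f"{self.id}: unknown part name {name!r}")
            if len(mesh.faces) < 1:
                raise MeshValidationError(f"{self.id}/{name}: mesh has no triangles")
            if not np.isfinite(mesh.vertices).all():
                raise MeshValidationError(f"{self.id}/{name}: non-finite vertex coordinates")
        if not np.allclose(self.frame @ self.frame.T, np.eye(3), atol=1e-9):
            raise MeshValidationError(f"{self.id}: frame axes not orthonormal")
        for key in ("anterior", "posterior"):
            if key not in self.landmarks:
                raise LandmarkError(f"{self.id}: missing {key} landmark")
        if np.allclose(self.landmarks["anterior"], self.landmarks["posterior"]):
            raise LandmarkError(f"{self.id}: anterior and posterior landmarks coincide")

    @property
    def part_names(self) -> set[str]:
        return set(self.parts)


@dataclass
class ColumnManifest:
    """Ordered description of a column: per-vertebra part files and metadata.

    ``entries`` maps, in anterior-to-posterior order, each vertebra id to its
    ``{part_name: file path}`` dict.  ``landmarks`` optionally overrides the
    estimated anterior/posterior/dorsal landmarks (mm, local frame).  ``gaps``
    optionally records the preserved intervertebral spacing (mm, one value per
    joint); ``damage`` lists vertebra ids with missing parts.
    """

    entries: list[tuple[str, dict[str, str]]]
    units: str = "mm"
    landmarks: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    gaps: list[float] | None = None
    damage: list[str] = field(default_factory=list)

    def validate(self) -> None:
        ids = [vid for vid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise MeshValidationError("duplicate vertebra ids in manifest")
        if self.units not in _UNIT_TO_MM:
            raise LoadError(f"unknown units {self.units!r} (use mm/cm/m)")
        unknown = set(self.damage) - set(ids)
        if unknown:
            raise MeshValidationError(f"damage mask names unknown vertebrae: {sorted(unknown)}")
        if self.gaps is not None and len(self.gaps) != len(self.entries) - 1:
            raise MeshValidationError("gaps list must have n_vertebrae - 1 entries")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "units": self.units,
            "vertebrae": [{"id": vid, "parts": parts} for vid, parts in self.entries],
            "landmarks": self.landmarks,
            "gaps": self.gaps,
            "damage": self.damage,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ColumnManifest":
        try:
            payload = json.loads(Path(path).read_text())
        except FileNotFoundError as exc:
            raise LoadError(f"manifest not found: {path}") from exc
        except json.JSONDecodeError as exc:
            raise LoadError(f"manifest is not valid JSON: {path}") from exc
        entries = [(v["id"], dict(v["parts"])) for v in payload["vertebrae"]]
        return cls(
            entries=entries,
            units=payload.get("units", "mm"),
            landmarks=payload.get("landmarks", {}),
            gaps=payload.get("gaps"),
            damage=payload.get("damage", []),
        )


def _load_part(path: Path) -> trimesh.Trimesh:
    if not path.exists():
        raise LoadError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise LoadError(f"cannot parse mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshValidationError(f"empty or non-triangular mesh: {path}")
    return mesh


def estimate_landmarks(
    centrum: trimesh.Trimesh, frame: np.ndarray = DEFAULT_FRAME
) -> dict[str, np.ndarray]:
    """Estimate anatomical landmarks from the centrum surface.

    Anterior/posterior face centroids are area-weighted centroids of the
    centrum triangles whose outward normals lie within 45 degrees of the
    -/+ anterior axis respectively (the faces that look forward/backward);
    the dorsal reference is the highest centrum vertex along the dorsal axis.
    """
    anterior, _, dorsal = frame
    normals = centrum.face_normals
    areas = centrum.area_faces
    centers = centrum.triangles_center
    cos45 = np.cos(np.deg2rad(45.0))
    out = {}
    for key, axis in (("anterior", anterior), ("posterior", -anterior)):
        sel = normals @ axis >= cos45
        if not sel.any():
            raise LandmarkError(f"no centrum faces oriented toward the {key} axis")
        w = areas[sel]
        out[key] = (centers[sel] * w[:, None]).sum(axis=0) / w.sum()
    out["dorsal"] = centrum.vertices[np.argmax(centrum.vertices @ dorsal)].astype(float)
    return out


def load_column(
    manifest: ColumnManifest, base_dir: str | Path | None = None
) -> list[LabeledVertebraMesh]:
    """Load every vertebra referenced by a manifest, in manifest order.

    Coordinates are rescaled to millimetres.  Landmarks come from the
    manifest's override table when present and are otherwise estimated from
    the centrum surface (:func:`estimate_landmarks`).
    """
    manifest.validate()
    base = Path(base_dir) if base_dir is not None else Path(".")
    scale = _UNIT_TO_MM[manifest.units]
    column = []
    for vid, part_paths in manifest.entries:
        parts = {}
        for name, rel in part_paths.items():
            if name not in PART_NAMES:
                raise VocabularyError(f"{vid}: unknown part name {name!r}")
            mesh = _load_part(base / rel)
            if scale != 1.0:
                mesh = mesh.copy()
                mesh.vertices = mesh.vertices * scale
            parts[name] = mesh
        if vid in manifest.landmarks:
            lm = {
                k: np.asarray(v, dtype=float) * scale
                for k, v in manifest.landmarks[vid].items()
            }
        else:
            if "centrum" not in parts:
                raise MeshValidationError(f"{vid}: 'centrum' part is required")
            lm = estimate_landmarks(parts["centrum"])
        vert = LabeledVertebraMesh(id=vid, parts=parts, landmarks=lm)
        vert.validate()
        column.append(vert)
    return column


def save_column(
    column: list[LabeledVertebraMesh],
    out_dir: str | Path,
    gaps: list[float] | None = None,
    damage: list[str] | None = None,
) -> Path:
    """Write one OBJ per part plus a manifest JSON; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    landmarks = {}
    for vert in column:
        paths = {}
        for name, mesh in vert.parts.items():
            rel = f"{vert.id}_{name}.obj"
            mesh.export(str(out / rel))
            paths[name] = rel
        entries.append((vert.id, paths))
        landmarks[vert.id] = {k: np.asarray(v).tolist() for k, v in vert.landmarks.items()}
    manifest = ColumnManifest(
        entries=entries,
        units="mm",
        landmarks=landmarks,
        gaps=None if gaps is None else [float(g) for g in gaps],
        damage=list(damage or []),
    )
    path = out / "manifest.json"
    manifest.to_json(path)
    return path


ANGLE_TABLE_COLUMNS = ["joint", "profile", "trial", "angle_deg"]


def read_angle_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV angle table with the ``joint,profile,trial,angle_deg`` schema."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise LoadError(f"angle table not found: {path}") from exc
    missing = [c for c in ANGLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"angle table {path} lacks columns {missing}")
    df["angle_deg"] = df["angle_deg"].astype(float)
    return df[ANGLE_TABLE_COLUMNS + [c for c in df.columns if c not in ANGLE_TABLE_COLUMNS]]


def write_results(obj, path: str | Path, provenance: dict | None = None) -> Path:
    """Persist a result object.

    DataFrames (ROM/angle/summary/test tables) go to CSV; dicts go to JSON.
    ``provenance`` (tolerances, contact rule, seed, ...) is embedded in JSON
    output and written alongside CSVs as ``<name>.provenance.json``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(obj, "to_dataframe"):
        obj = obj.to_dataframe()
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
        if provenance is not None:
            side = path.with_suffix(path.suffix + ".provenance.json")
            side.write_text(json.dumps(provenance, indent=2, default=str))
    else:
        payload = {"results": obj}
        if provenance is not None:
            payload["provenance"] = provenance
        path.write_text(json.dumps(payload, indent=2, default=str))
    return path
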