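"""Reading and writing meshes, landmarks and cohort tables.

Meshes travel as PLY (preferred, binary little-endian) or legacy ASCII VTK
polydata, in both cases with an integer per-vertex attribute named
``region`` holding the anatomical label codes documented in
:mod:`bivatlas.mesh_core`.  Landmarks are a flat JSON object of
``name -> [x, y, z]`` in mm.  The cohort table is a CSV with the exact
header ``subject_id,bsa,qrs_ms,sbp_mmHg,dbp_mmHg,adverse_outcome,prvi``;
empty cells are missing values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import trimesh

from .mesh_core import (
    LANDMARK_NAMES,
    BiventricularModel,
    LandmarkSet,
    MeshValidationError,
    SubjectRecord,
    SurfaceMesh,
)

COHORT_COLUMNS = [
    "subject_id",
    "bsa",
    "qrs_ms",
    "sbp_mmHg",
    "dbp_mmHg",
    "adverse_outcome",
    "prvi",
]


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

def write_mesh(path: str | Path, mesh: SurfaceMesh) -> None:
    """Write a labelled surface as PLY (.ply) or legacy ASCII VTK (.vtk)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_ply_double(path, mesh)
    elif path.suffix.lower() == ".vtk":
        _write_vtk_polydata(path, mesh)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix!r} (use .ply or .vtk)")


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read a labelled surface written by :func:`write_mesh`."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        tm = trimesh.load(path, file_type="ply", process=False)
        labels = _ply_region_labels(tm)
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), labels)
    if path.suffix.lower() == ".vtk":
        return _read_vtk_polydata(path)
    raise ValueError(f"unsupported mesh format: {path.suffix!r} (use .ply or .vtk)")


def _write_ply_double(path: Path, mesh: SurfaceMesh) -> None:
    """Binary little-endian PLY with double-precision vertices.

    Written directly because general-purpose exporters downcast coordinates
    to float32, which loses the sub-micrometre round-trip fidelity the
    correspondence pipeline relies on.  Readable by any PLY reader.
    """
    V, F = len(mesh.vertices), len(mesh.faces)
    header = "\n".join(
        [
            "ply",
            "format binary_little_endian 1.0",
            "comment bivatlas labelled surface (units mm)",
            f"element vertex {V}",
            "property double x",
            "property double y",
            "property double z",
            "property int region",
            f"element face {F}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
    )
    vert = np.empty(
        V, dtype=[("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("region", "<i4")]
    )
    vert["x"], vert["y"], vert["z"] = mesh.vertices.T
    vert["region"] = mesh.vertex_labels
    face = np.empty(F, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
    face["n"] = 3
    face["idx"] = mesh.faces
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii") + b"\n")
        fh.write(vert.tobytes())
        fh.write(face.tobytes())


def _ply_region_labels(tm: "trimesh.Trimesh") -> np.ndarray:
    labels = tm.vertex_attributes.get("region")
    if labels is None:
        raw = tm.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
        if raw is not None and "region" in getattr(raw, "dtype", np.dtype([])).names:
            labels = raw["region"]
    if labels is None:
        raise MeshValidationError("PLY file lacks the per-vertex 'region' label channel")
    return np.asarray(labels, dtype=np.int64).ravel()


def _write_vtk_polydata(path: Path, mesh: SurfaceMesh) -> None:
    V, F = len(mesh.vertices), len(mesh.faces)
    lines = [
        "# vtk DataFile Version 3.0",
        "bivatlas surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {V} double",
    ]
    lines += [" ".join(f"{c:.9g}" for c in v) for v in mesh.vertices]
    lines.append(f"POLYGONS {F} {4 * F}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in mesh.faces]
    lines += [
        f"POINT_DATA {V}",
        "SCALARS region int 1",
        "LOOKUP_TABLE default",
    ]
    lines += [str(int(l)) for l in mesh.vertex_labels]
    path.write_text("\n".join(lines) + "\n")


def _read_vtk_polydata(path: Path) -> SurfaceMesh:
    tokens = path.read_text().split("\n")
    it = iter(tokens)
    vertices = faces = labels = None
    for line in it:
        parts = line.split()
        if not parts:
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            flat: list[float] = []
            while len(flat) < 3 * n:
                flat += [float(x) for x in next(it).split()]
            vertices = np.asarray(flat, dtype=np.float64).reshape(n, 3)
        elif key == "POLYGONS":
            n = int(parts[1])
            rows = []
            for _ in range(n):
                vals = [int(x) for x in next(it).split()]
                if vals[0] != 3:
                    raise MeshValidationError("VTK polydata contains non-triangle polygons")
                rows.append(vals[1:])
            faces = np.asarray(rows, dtype=np.int64)
        elif key == "SCALARS" and parts[1] == "region":
            next(it)  # LOOKUP_TABLE line
            vals: list[int] = []
            while vertices is not None and len(vals) < len(vertices):
                vals += [int(x) for x in next(it).split()]
            labels = np.asarray(vals, dtype=np.int64)
    if vertices is None or faces is None:
        raise MeshValidationError(f"{path}: not a triangulated VTK polydata file")
    if labels is None:
        raise MeshValidationError(f"{path}: missing 'region' label channel")
    return SurfaceMesh(vertices, faces, labels)


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

def write_landmarks(path: str | Path, ed: LandmarkSet, es: LandmarkSet) -> None:
    """Write ED and ES landmark sets to one JSON file."""
    payload = {"ed": ed.as_dict(), "es": es.as_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks(path: str | Path) -> tuple[LandmarkSet, LandmarkSet]:
    payload = json.loads(Path(path).read_text())
    out = []
    for phase in ("ed", "es"):
        entry = payload.get(phase, payload if phase == "ed" else None)
        if entry is None:
            raise ValueError(f"{path}: missing landmark block for phase {phase!r}")
        missing = [n for n in LANDMARK_NAMES if n not in entry]
        if missing:
            raise ValueError(f"{path}: landmark file lacks {missing}")
        out.append(LandmarkSet(**{n: np.asarray(entry[n], dtype=float) for n in LANDMARK_NAMES}))
    return out[0], out[1]


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------

def write_model(directory: str | Path, model: BiventricularModel, fmt: str = "ply") -> None:
    """Write one subject's ED/ES meshes and landmarks into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mesh(directory / f"{model.subject_id}_ed.{fmt}", model.ed)
    write_mesh(directory / f"{model.subject_id}_es.{fmt}", model.es)
    write_landmarks(
        directory / f"{model.subject_id}_landmarks.json",
        model.landmarks_ed,
        model.landmarks_es,
    )


def read_model(
    ed_path: str | Path,
    es_path: str | Path,
    landmark_path: str | Path,
    subject_id: str | None = None,
    validate: bool = True,
) -> BiventricularModel:
    """Read and validate one subject's biventricular model."""
    ed = read_mesh(ed_path)
    es = read_mesh(es_path)
    lm_ed, lm_es = read_landmarks(landmark_path)
    sid = subject_id or Path(ed_path).stem.removesuffix("_ed")
    model = BiventricularModel(sid, ed, es, lm_ed, lm_es)
    if validate:
        model.validate()
    return model


def read_cohort_models(directory: str | Path, fmt: str = "ply") -> list[BiventricularModel]:
    directory = Path(directory)
    models = []
    for ed_path in sorted(directory.glob(f"*_ed.{fmt}")):
        sid = ed_path.stem.removesuffix("_ed")
        models.append(
            read_model(
                ed_path,
                directory / f"{sid}_es.{fmt}",
                directory / f"{sid}_landmarks.json",
                subject_id=sid,
            )
        )
    return models


# --------------------------------------------------------------------------
# cohort table
# --------------------------------------------------------------------------

def write_cohort_csv(path: str | Path, records: Iterable[SubjectRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "bsa": r.bsa,
                "qrs_ms": r.qrs_ms,
                "sbp_mmHg": r.sbp_mmHg,
                "dbp_mmHg": r.dbp_mmHg,
                "adverse_outcome": r.adverse_outcome,
                "prvi": r.prvi,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    if list(df.columns) != COHORT_COLUMNS:
        raise ValueError(
            f"{path}: cohort CSV header must be exactly {','.join(COHORT_COLUMNS)}"
        )
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                bsa=float(row["bsa"]),
                qrs_ms=None if pd.isna(row["qrs_ms"]) else float(row["qrs_ms"]),
                sbp_mmHg=None if pd.isna(row["sbp_mmHg"]) else float(row["sbp_mmHg"]),
                dbp_mmHg=None if pd.isna(row["dbp_mmHg"]) else float(row["dbp_mmHg"]),
                adverse_outcome=int(row["adverse_outcome"]),
                prvi=None if pd.isna(row["prvi"]) else float(row["prvi"]),
            )
        )
    return records
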