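"""Mesh and landmark data model plus chamber volumetrics.

Units are fixed throughout the package: vertex coordinates in mm, volumes in
ml (1 ml = 1000 mm^3), mass in g, body surface area in m^2.  All unit
conversions live here.

A biventricular model carries three closed surfaces in one mesh, told apart
by integer per-vertex region labels: LV endocardium, LV epicardium and the
RV endocardium (the latter split into free wall and septum so the septal
plane can be recovered for the anatomical frame).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

MM3_PER_ML = 1000.0
#: conventional CMR myocardial density, g/ml
MYOCARDIAL_DENSITY_G_PER_ML = 1.05

# per-vertex anatomical labels
LV_ENDO, LV_EPI, RV_FREE_WALL, RV_SEPTUM = 0, 1, 2, 3

LABEL_NAMES: dict[int, str] = {
    LV_ENDO: "lv_endo",
    LV_EPI: "lv_epi",
    RV_FREE_WALL: "rv_free_wall",
    RV_SEPTUM: "rv_septum",
}
LABEL_CODES: dict[str, int] = {v: k for k, v in LABEL_NAMES.items()}

#: closed chamber components as label subsets
CHAMBERS: dict[str, tuple[int, ...]] = {
    "lv_endo": (LV_ENDO,),
    "lv_epi": (LV_EPI,),
    "rv": (RV_FREE_WALL, RV_SEPTUM),
}

LANDMARK_NAMES = ("mv_centroid", "tv_centroid", "pv_centroid", "rv_apex", "lv_apex")


class MeshValidationError(ValueError):
    """A surface mesh violates a structural invariant."""


@dataclass
class SurfaceMesh:
    """Triangulated labelled surface.

    vertices : (V, 3) float array, mm
    faces : (F, 3) int array, outward-oriented triangles
    vertex_labels : (V,) int array with codes from :data:`LABEL_NAMES`
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be (F, 3)")
        if self.vertex_labels.shape != (len(self.vertices),):
            raise MeshValidationError("vertex_labels must be (V,)")

    # -- chamber helpers -------------------------------------------------
    def chamber_face_mask(self, labels: Iterable[int]) -> np.ndarray:
        """Faces whose three vertices all carry one of ``labels``."""
        sel = np.isin(self.vertex_labels, np.asarray(tuple(labels)))
        return sel[self.faces].all(axis=1)

    def chamber_faces(self, labels: Iterable[int]) -> np.ndarray:
        return self.faces[self.chamber_face_mask(labels)]

    def vertex_mask(self, labels: Iterable[int]) -> np.ndarray:
        return np.isin(self.vertex_labels, np.asarray(tuple(labels)))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Rigidly transformed copy (labels and topology shared)."""
        return SurfaceMesh(
            self.vertices @ np.asarray(rotation).T + np.asarray(translation),
            self.faces,
            self.vertex_labels,
        )

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.vertex_labels.copy())

    def validate(self, min_area: float = 1e-9) -> None:
        """Check watertightness, orientation and non-degeneracy per chamber."""
        present = set(np.unique(self.vertex_labels).tolist())
        unknown = present - set(LABEL_NAMES)
        if unknown:
            raise MeshValidationError(f"unknown vertex labels: {sorted(unknown)}")
        v0, v1, v2 = (self.vertices[self.faces[:, i]] for i in range(3))
        areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
        if (areas < min_area).any():
            bad = int((areas < min_area).sum())
            raise MeshValidationError(f"{bad} degenerate (zero-area) triangles")
        for name, labels in CHAMBERS.items():
            if not any(l in present for l in labels):
                continue
            faces = self.chamber_faces(labels)
            if len(faces) == 0:
                raise MeshValidationError(f"chamber {name!r} has labelled vertices but no faces")
            _check_watertight(faces, name)
            if _signed_volume_mm3(self.vertices, faces) <= 0:
                raise MeshValidationError(f"chamber {name!r} has inward orientation")


def _edge_counts(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    return np.unique(edges, axis=0, return_counts=True)


def _check_watertight(faces: np.ndarray, name: str) -> None:
    uniq, counts = _edge_counts(faces)
    bad = uniq[counts != 2]
    if len(bad):
        raise MeshValidationError(
            f"chamber {name!r} not watertight: {len(bad)} edges not shared by exactly "
            f"2 faces (first offenders: {bad[:5].tolist()})"
        )


def _signed_volume_mm3(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Divergence-theorem signed volume: sum of tetrahedra about the origin."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)


def chamber_volume(mesh: SurfaceMesh, labels: Iterable[int] | str) -> float:
    """Volume (ml) enclosed by the closed chamber component selected by labels.

    ``labels`` may be a chamber name from :data:`CHAMBERS` or an iterable of
    label codes.  Raises :class:`MeshValidationError` if the selected face set
    is not watertight.
    """
    if isinstance(labels, str):
        labels = CHAMBERS[labels]
    faces = mesh.chamber_faces(labels)
    if len(faces) == 0:
        raise MeshValidationError("no faces for requested chamber labels")
    _check_watertight(faces, str(tuple(labels)))
    vol = _signed_volume_mm3(mesh.vertices, faces) / MM3_PER_ML
    if vol <= 0:
        raise MeshValidationError("chamber volume non-positive; check face orientation")
    return vol


@dataclass
class LandmarkSet:
    """Anatomical key points (mm): valve centroids and the two apices."""

    mv_centroid: np.ndarray
    tv_centroid: np.ndarray
    pv_centroid: np.ndarray
    rv_apex: np.ndarray
    lv_apex: np.ndarray

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=np.float64)
            if p.shape != (3,) or not np.isfinite(p).all():
                raise ValueError(f"landmark {name!r} must be a finite 3-vector")
            setattr(self, name, p)
        if np.allclose(self.rv_apex, self.tv_centroid) or np.allclose(
            self.rv_apex, self.pv_centroid
        ):
            raise ValueError("rv_apex coincides with a valve centroid (zero height)")

    def as_dict(self) -> dict[str, list[float]]:
        return {name: getattr(self, name).tolist() for name in LANDMARK_NAMES}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        R = np.asarray(rotation)
        t = np.asarray(translation)
        return LandmarkSet(**{n: getattr(self, n) @ R.T + t for n in LANDMARK_NAMES})


@dataclass
class BiventricularModel:
    """One subject's corresponded ED and ES surfaces plus landmarks.

    ED and ES share topology (identical faces, labels and vertex count), which
    is what makes cross-phase and cross-subject point correspondence valid.
    ``landmark_indices`` optionally records which template vertices the
    landmarks were taken from, so synthesized shapes can re-derive them.
    """

    subject_id: str
    ed: SurfaceMesh
    es: SurfaceMesh
    landmarks_ed: LandmarkSet
    landmarks_es: LandmarkSet
    landmark_indices: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.ed.vertices.shape != self.es.vertices.shape:
            raise MeshValidationError(
                f"{self.subject_id}: ED/ES vertex count mismatch "
                f"({len(self.ed.vertices)} vs {len(self.es.vertices)})"
            )
        if not np.array_equal(self.ed.faces, self.es.faces):
            raise MeshValidationError(f"{self.subject_id}: ED/ES face lists differ")
        if not np.array_equal(self.ed.vertex_labels, self.es.vertex_labels):
            raise MeshValidationError(f"{self.subject_id}: ED/ES vertex labels differ")

    def validate(self) -> None:
        self.ed.validate()
        self.es.validate()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BiventricularModel":
        return BiventricularModel(
            self.subject_id,
            self.ed.transformed(rotation, translation),
            self.es.transformed(rotation, translation),
            self.landmarks_ed.transformed(rotation, translation),
            self.landmarks_es.transformed(rotation, translation),
            self.landmark_indices,
        )

    def mesh(self, phase: str) -> SurfaceMesh:
        if phase not in ("ed", "es"):
            raise ValueError("phase must be 'ed' or 'es'")
        return self.ed if phase == "ed" else self.es

    def landmarks(self, phase: str) -> LandmarkSet:
        if phase not in ("ed", "es"):
            raise ValueError("phase must be 'ed' or 'es'")
        return self.landmarks_ed if phase == "ed" else self.landmarks_es


@dataclass
class SubjectRecord:
    """Clinical covariates for one subject."""

    subject_id: str
    bsa: float
    qrs_ms: float | None = None
    sbp_mmHg: float | None = None
    dbp_mmHg: float | None = None
    adverse_outcome: int = 0
    prvi: float | None = None

    def __post_init__(self) -> None:
        if not (self.bsa is not None and np.isfinite(self.bsa) and self.bsa > 0):
            raise ValueError(f"{self.subject_id}: bsa must be positive")
        if self.adverse_outcome not in (0, 1):
            raise ValueError(f"{self.subject_id}: adverse_outcome must be 0 or 1")


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Mosteller body surface area (m^2) fallback when BSA is not tabulated."""
    return math.sqrt(height_cm * weight_kg / 3600.0)


@dataclass
class Volumetrics:
    """Global chamber volumes, function and mass for one subject.

    Volumes ml, mass g; ``*_i`` fields are BSA-indexed (per m^2); EFs are
    fractions; mass-to-volume ratios g/ml.
    """

    subject_id: str
    lvedv: float
    lvesv: float
    rvedv: float
    rvesv: float
    lvm: float
    bsa: float

    lv_sv: float = field(init=False)
    rv_sv: float = field(init=False)
    lvef: float = field(init=False)
    rvef: float = field(init=False)
    lv_ed_mvr: float = field(init=False)
    lv_es_mvr: float = field(init=False)

    def __post_init__(self) -> None:
        self.lv_sv = self.lvedv - self.lvesv
        self.rv_sv = self.rvedv - self.rvesv
        self.lvef = self.lv_sv / self.lvedv
        self.rvef = self.rv_sv / self.rvedv
        self.lv_ed_mvr = self.lvm / self.lvedv
        self.lv_es_mvr = self.lvm / self.lvesv

    def __getattr__(self, name: str):
        # BSA-indexed variants: lvedv_i, rv_sv_i, lvm_i, ...
        if name.endswith("_i"):
            return getattr(self, name[:-2]) / self.bsa
        raise AttributeError(name)

    def to_dict(self) -> dict[str, float]:
        base = {
            k: v for k, v in dataclasses.asdict(self).items() if k != "subject_id"
        }
        out: dict[str, float] = {"subject_id": self.subject_id}
        out.update(base)
        for key in ("lvedv", "lvesv", "rvedv", "rvesv", "lv_sv", "rv_sv", "lvm"):
            out[key + "_i"] = getattr(self, key + "_i")
        return out


def compute_volumetrics(
    model: BiventricularModel,
    record: SubjectRecord,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> Volumetrics:
    """Chamber volumes, EF and LV mass from the closed model surfaces.

    The LV cavity is the volume enclosed by the endocardial surface, the RV
    cavity that enclosed by free wall + septum, and LV mass is the epi-endo
    shell volume at ED times the myocardial density.
    """
    lvedv = chamber_volume(model.ed, "lv_endo")
    lvesv = chamber_volume(model.es, "lv_endo")
    rvedv = chamber_volume(model.ed, "rv")
    rvesv = chamber_volume(model.es, "rv")
    epi_ed = chamber_volume(model.ed, "lv_epi")
    if epi_ed <= lvedv:
        raise MeshValidationError(
            f"{model.subject_id}: epicardial volume <= endocardial volume (inverted surfaces)"
        )
    lvm = (epi_ed - lvedv) * density_g_per_ml
    return Volumetrics(
        subject_id=model.subject_id,
        lvedv=lvedv,
        lvesv=lvesv,
        rvedv=rvedv,
        rvesv=rvesv,
        lvm=lvm,
        bsa=record.bsa,
    )


def volumetrics_table(rows: Iterable[Volumetrics]):
    """Stack Volumetrics into a pandas DataFrame indexed by subject_id."""
    import pandas as pd

    df = pd.DataFrame([r.to_dict() for r in rows]).set_index("subject_id")
    return df
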