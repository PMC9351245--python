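"""Calliper-based morphometry of the two ventricles.

Heights, level-wise widths, sphericity and eccentricity are measured in an
anatomical frame derived from the landmarks and the septal surface:

* LV long axis: mitral valve centroid -> LV apex;
* RV long axis: tricuspid valve centroid -> RV apex;
* septal normal: normal of the least-squares plane through the septal
  vertices, oriented LV -> RV;
* anterior-posterior (AP) axis: orthogonal to both the septal normal and
  the LV long axis.

Widths at a fraction r of the ventricle height (measured from the apex, so
r = 1/4 is apical and r = 3/4 basal) are the extent of the plane-mesh
intersection projected on the stated axis.  Sphericity is septal-lateral
width over height; eccentricity is AP width over septal-lateral width.
Displacements are ED -> ES motions of the apex and valve centroids and are
meaningful in a common (atlas) frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .mesh_core import (
    LV_ENDO,
    RV_FREE_WALL,
    RV_SEPTUM,
    BiventricularModel,
    SurfaceMesh,
)

LEVELS = {"apical": 0.25, "mid": 0.5, "basal": 0.75}
PHASES = ("ed", "es")
VENTRICLES = ("lv", "rv")


class CaliperError(ValueError):
    """A calliper measure cannot be computed on this mesh."""


@dataclass
class AnatomicalFrame:
    long_axis_lv: np.ndarray
    long_axis_rv: np.ndarray
    septal_normal: np.ndarray
    ap_axis: np.ndarray


def anatomical_frame(model: BiventricularModel, phase: str) -> AnatomicalFrame:
    """Landmark- and septum-derived axes for one phase."""
    mesh = model.mesh(phase)
    lm = model.landmarks(phase)

    def unit(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise CaliperError("degenerate axis (coincident landmarks)")
        return v / n

    long_lv = unit(lm.lv_apex - lm.mv_centroid)
    long_rv = unit(lm.rv_apex - lm.tv_centroid)

    septum = mesh.vertices[mesh.vertex_labels == RV_SEPTUM]
    if len(septum) < 3:
        raise CaliperError("no septal vertices labelled")
    centred = septum - septum.mean(axis=0)
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-6 * svals[0]:
        raise CaliperError("septal vertices are collinear; plane undefined")
    normal = vt[2]
    # orient LV -> RV
    lv_c = mesh.vertices[mesh.vertex_labels == LV_ENDO].mean(axis=0)
    rv_c = mesh.vertices[mesh.vertex_labels == RV_FREE_WALL].mean(axis=0)
    if normal @ (rv_c - lv_c) < 0:
        normal = -normal
    ap = unit(np.cross(normal, long_lv))
    return AnatomicalFrame(long_lv, long_rv, normal, ap)


def _section_points(
    vertices: np.ndarray, faces: np.ndarray, origin: np.ndarray, normal: np.ndarray
) -> np.ndarray:
    """Points of the plane-mesh intersection (segment endpoints)."""
    tm = trimesh.Trimesh(vertices, faces, process=False)
    segments = trimesh.intersections.mesh_plane(tm, normal, origin)
    if len(segments) == 0:
        raise CaliperError("empty slice: plane does not intersect the chamber")
    return np.asarray(segments).reshape(-1, 3)


def _extent(points: np.ndarray, axis: np.ndarray) -> float:
    proj = points @ axis
    return float(proj.max() - proj.min())


@dataclass
class CaliperSet:
    """Flat dictionary of calliper measures for one subject.

    Keys follow ``{ventricle}_{measure}_{level}_{phase}``, e.g.
    ``lv_sphericity_mid_ed``; heights are ``{ventricle}_height_{phase}``;
    displacement/shortening keys name the structure directly.
    """

    subject_id: str
    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def sphericity(self, ventricle: str, level: str, phase: str) -> float:
        return self.values[f"{ventricle}_sphericity_{level}_{phase}"]

    def eccentricity(self, ventricle: str, level: str, phase: str) -> float:
        return self.values[f"{ventricle}_eccentricity_{level}_{phase}"]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id)


def compute_calipers(
    model: BiventricularModel, ventricles: tuple[str, ...] = VENTRICLES
) -> CaliperSet:
    """All calliper measures for one (atlas-frame) model.

    Heights and widths in mm; sphericity, eccentricity and longitudinal
    shortening dimensionless; displacements in mm (ED -> ES, so they are
    only comparable across subjects after alignment to a common frame).
    """
    out: dict[str, float] = {}
    for phase in PHASES:
        frame = anatomical_frame(model, phase)
        mesh = model.mesh(phase)
        lm = model.landmarks(phase)
        for vent in ventricles:
            if vent == "lv":
                apex, valve = lm.lv_apex, lm.mv_centroid
                axis = -frame.long_axis_lv  # apex -> base
                faces = mesh.chamber_faces((LV_ENDO,))
                fw_faces = faces
            else:
                apex, valve = lm.rv_apex, lm.tv_centroid
                axis = -frame.long_axis_rv
                faces = mesh.chamber_faces((RV_FREE_WALL, RV_SEPTUM))
                fw_faces = mesh.chamber_faces((RV_FREE_WALL,))
            h = float(np.linalg.norm(valve - apex))
            out[f"{vent}_height_{phase}"] = h
            for level, r in LEVELS.items():
                origin = apex + r * h * axis
                pts = _section_points(mesh.vertices, faces, origin, axis)
                w_sl = _extent(pts, frame.septal_normal)
                w_ap = _extent(pts, frame.ap_axis)
                out[f"{vent}_width_sl_{level}_{phase}"] = w_sl
                out[f"{vent}_width_ap_{level}_{phase}"] = w_ap
                out[f"{vent}_sphericity_{level}_{phase}"] = w_sl / h
                out[f"{vent}_eccentricity_{level}_{phase}"] = w_ap / w_sl
                if vent == "rv" and level == "mid":
                    # free-wall extent parallel to the septum
                    fw_pts = _section_points(mesh.vertices, fw_faces, origin, axis)
                    out[f"rv_l_mid_{phase}"] = _extent(fw_pts, frame.ap_axis)

    lm_ed, lm_es = model.landmarks_ed, model.landmarks_es
    if "lv" in ventricles:
        out["lv_apex_displacement"] = float(np.linalg.norm(lm_es.lv_apex - lm_ed.lv_apex))
        out["mv_displacement"] = float(np.linalg.norm(lm_es.mv_centroid - lm_ed.mv_centroid))
        out["lv_longitudinal_shortening"] = (
            out["lv_height_ed"] - out["lv_height_es"]
        ) / out["lv_height_ed"]
    if "rv" in ventricles:
        out["rv_apex_displacement"] = float(np.linalg.norm(lm_es.rv_apex - lm_ed.rv_apex))
        out["tv_displacement"] = float(np.linalg.norm(lm_es.tv_centroid - lm_ed.tv_centroid))
        out["rv_longitudinal_shortening"] = (
            out["rv_height_ed"] - out["rv_height_es"]
        ) / out["rv_height_ed"]
    return CaliperSet(model.subject_id, out)


def caliper_table(models: list[BiventricularModel]) -> pd.DataFrame:
    """Calliper measures for a cohort, one row per subject."""
    return pd.DataFrame([compute_calipers(m).to_series() for m in models])


def regress_calipers_on_modes(
    calipers: pd.DataFrame, scores: np.ndarray
) -> pd.DataFrame:
    """OLS of each standardized calliper measure on the retained z-scores.

    Returns the coefficient matrix (measures x modes).  With standardized
    responses and (near-)orthonormal scores, coefficients are comparable
    across measures and modes; the largest |coefficient| per mode names the
    callipers that mode drives.
    """
    Z = np.asarray(scores, dtype=float)
    n, k = Z.shape
    if n < k + 2:
        raise ValueError("need at least n_retained + 2 subjects for the regression")
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear scores)")
    sd = calipers.std(ddof=1)
    if (sd == 0).any():
        sd = sd.replace(0, 1.0)
    Y = (calipers - calipers.mean()) / sd
    beta, *_ = np.linalg.lstsq(X, Y.values, rcond=None)
    return pd.DataFrame(
        beta[1:].T,
        index=calipers.columns,
        columns=[f"mode_{j + 1}" for j in range(k)],
    )


def top_associations(coef: pd.DataFrame, n_top: int = 5) -> dict[str, list[str]]:
    """Per mode, the calliper measures with the largest |coefficient|."""
    return {
        mode: coef[mode].abs().sort_values(ascending=False).head(n_top).index.tolist()
        for mode in coef.columns
    }
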