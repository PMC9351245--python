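"""Statistical shape atlas: Procrustes alignment, PCA modes, z-scores.

The atlas is built in two steps.  First, every subject's ED surface is
rigidly aligned (rotation + translation, no scaling — size is part of the
biology and must stay in the modes) to an evolving population mean by
generalized Procrustes analysis; each subject's ED transform is applied
unchanged to its ES surface, preserving the ED->ES deformation.  Second,
principal component analysis is run on the concatenated ED+ES coordinate
vectors, so each mode encodes geometry and motion jointly.  A subject's
z-score on mode k is its centred projection divided by the mode's standard
deviation, giving dimensionless scores with mean 0 / sd 1 over the training
cohort.  Modes explaining more than a retention threshold (default 1 %) of
total variance are kept for downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .mesh_core import BiventricularModel, SurfaceMesh


# --------------------------------------------------------------------------
# rigid alignment
# --------------------------------------------------------------------------

def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping source onto target.

    Proper rotation (det +1) is enforced via the SVD sign correction.
    """
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - R @ sc
    return R, t


def generalized_procrustes(
    models: list[BiventricularModel],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[list[BiventricularModel], list[tuple[np.ndarray, np.ndarray]], list[float]]:
    """Iterative rigid GPA of the ED surfaces; transforms propagate to ES.

    Returns (aligned models, per-subject (R, t), objective history).  The
    objective is the mean squared vertex distance to the current mean shape;
    it is non-increasing across iterations.  Convergence is declared when
    the mean shape moves less than ``tol`` mm RMS.
    """
    if len(models) < 2:
        raise ValueError("GPA needs at least 2 models")
    eds = [m.ed.vertices for m in models]
    n = len(eds)
    transforms = [(np.eye(3), np.zeros(3)) for _ in range(n)]
    aligned = [e.copy() for e in eds]
    reference = aligned[0].copy()
    history: list[float] = []
    for _ in range(max_iter):
        for i in range(n):
            R, t = kabsch(eds[i], reference)
            transforms[i] = (R, t)
            aligned[i] = eds[i] @ R.T + t
        mean = np.mean(aligned, axis=0)
        history.append(float(np.mean([(a - mean) ** 2 for a in aligned])))
        shift = float(np.sqrt(np.mean((mean - reference) ** 2)))
        reference = mean
        if shift < tol:
            break
    aligned_models = [m.transformed(R, t) for m, (R, t) in zip(models, transforms)]
    return aligned_models, transforms, history


# --------------------------------------------------------------------------
# shape vectors
# --------------------------------------------------------------------------

def shape_vector(model: BiventricularModel) -> np.ndarray:
    """Concatenated ED+ES coordinates, length 6V (mm)."""
    return np.concatenate([model.ed.vertices.ravel(), model.es.vertices.ravel()])


def split_shape_vector(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    half = len(vec) // 2
    return vec[:half].reshape(-1, 3), vec[half:].reshape(-1, 3)


# --------------------------------------------------------------------------
# atlas estimator
# --------------------------------------------------------------------------

class ShapeAtlas(BaseEstimator, TransformerMixin):
    """PCA shape atlas over GPA-aligned concatenated ED+ES shapes.

    Parameters
    ----------
    retention_threshold : float
        Keep modes whose explained-variance fraction exceeds this (default
        0.01, i.e. modes explaining more than 1 % of total variation).
    gpa_tol, gpa_max_iter : GPA convergence controls (mm RMS / iterations).

    Fitted attributes
    -----------------
    mean_shape_ : (6V,) mean shape vector in the atlas frame
    modes_ : (n_modes, 6V) orthonormal shape modes, sign-fixed
    eigenvalues_ : per-mode variance (mm^2), non-increasing
    explained_fraction_ : per-mode fraction of total variance
    n_retained_ : number of modes above the retention threshold
    training_scores_ : (n, n_retained) z-scores of the training cohort
    aligned_models_ : the GPA-aligned training models
    """

    def __init__(
        self,
        retention_threshold: float = 0.01,
        gpa_tol: float = 1e-6,
        gpa_max_iter: int = 100,
    ):
        self.retention_threshold = retention_threshold
        self.gpa_tol = gpa_tol
        self.gpa_max_iter = gpa_max_iter

    # -- fitting ---------------------------------------------------------
    def fit(self, models: list[BiventricularModel], y=None) -> "ShapeAtlas":
        if len(models) < 2:
            raise ValueError("atlas needs at least 2 subjects")
        aligned, transforms, history = generalized_procrustes(
            models, tol=self.gpa_tol, max_iter=self.gpa_max_iter
        )
        X = np.stack([shape_vector(m) for m in aligned])
        pca = PCA(svd_solver="full")
        proj = pca.fit_transform(X)

        # fix the arbitrary PCA sign: largest-|coordinate| positive
        comps = pca.components_
        flip = np.sign(comps[np.arange(len(comps)), np.abs(comps).argmax(axis=1)])
        comps = comps * flip[:, None]
        proj = proj * flip[None, :]

        self.gpa_transforms_ = transforms
        self.gpa_history_ = history
        self.aligned_models_ = aligned
        self.template_model_ = aligned[0]
        self.mean_shape_ = pca.mean_
        self.modes_ = comps
        self.eigenvalues_ = pca.explained_variance_
        self.explained_fraction_ = pca.explained_variance_ratio_
        self.n_retained_ = int((self.explained_fraction_ > self.retention_threshold).sum())
        nonzero = self.eigenvalues_ > 1e-12
        sd = np.sqrt(np.where(nonzero, self.eigenvalues_, 1.0))
        scores = proj / sd
        self.training_scores_ = scores[:, : self.n_retained_]
        self._score_sd_ = sd
        return self

    # -- projection ------------------------------------------------------
    def _align_to_atlas(self, model: BiventricularModel) -> BiventricularModel:
        mean_ed, _ = split_shape_vector(self.mean_shape_)
        R, t = kabsch(model.ed.vertices, mean_ed)
        return model.transformed(R, t)

    def transform(self, models: list[BiventricularModel]) -> np.ndarray:
        """Project models into z-scores (n, n_retained).

        Each model's ED surface is first rigidly aligned to the atlas mean
        ED shape; zero-variance modes are excluded by construction.
        """
        rows = []
        for m in models:
            aligned = self._align_to_atlas(m)
            x = shape_vector(aligned) - self.mean_shape_
            z = (self.modes_ @ x) / self._score_sd_
            rows.append(z[: self.n_retained_])
        return np.stack(rows)

    def project(self, model: BiventricularModel) -> np.ndarray:
        """z-scores of a single model."""
        return self.transform([model])[0]

    # -- synthesis -------------------------------------------------------
    def synthesize(
        self, direction: int | np.ndarray, magnitude_sd: float
    ) -> BiventricularModel:
        """Shape at ``magnitude_sd`` standard deviations along a direction.

        ``direction`` is a retained-mode index (0-based) or a vector in
        z-space over the retained modes (normalized internally).  The
        returned model reuses the template topology; landmarks are taken
        from the template's landmark vertices.
        """
        k = self.n_retained_
        if np.isscalar(direction):
            d = np.zeros(k)
            d[int(direction)] = 1.0
        else:
            d = np.asarray(direction, dtype=float)
            if d.shape != (k,) or not np.isfinite(d).all():
                raise ValueError(f"direction must be a finite vector of length {k}")
            norm = np.linalg.norm(d)
            if norm == 0:
                raise ValueError("direction must be nonzero")
            d = d / norm
        coeffs = magnitude_sd * d * self._score_sd_[:k]
        vec = self.mean_shape_ + coeffs @ self.modes_[:k]
        ed_v, es_v = split_shape_vector(vec)
        tm = self.template_model_
        ed = SurfaceMesh(ed_v, tm.ed.faces, tm.ed.vertex_labels)
        es = SurfaceMesh(es_v, tm.es.faces, tm.es.vertex_labels)
        idx = tm.landmark_indices or self._nearest_landmark_indices()
        lm_ed = {k_: ed_v[i] for k_, i in idx.items()}
        lm_es = {k_: es_v[i] for k_, i in idx.items()}
        from .mesh_core import LandmarkSet

        return BiventricularModel(
            subject_id=f"synth_{magnitude_sd:+g}sd",
            ed=ed,
            es=es,
            landmarks_ed=LandmarkSet(**lm_ed),
            landmarks_es=LandmarkSet(**lm_es),
            landmark_indices=idx,
        )

    # -- serialization ---------------------------------------------------
    def save(self, directory) -> None:
        """Serialize to a directory of .npy arrays plus a JSON sidecar."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "mean_shape.npy", self.mean_shape_)
        np.save(d / "modes.npy", self.modes_)
        np.save(d / "eigenvalues.npy", self.eigenvalues_)
        tm = self.template_model_
        np.save(d / "template_faces.npy", tm.ed.faces)
        np.save(d / "template_labels.npy", tm.ed.vertex_labels)
        np.save(d / "training_scores.npy", self.training_scores_)
        idx = tm.landmark_indices or self._nearest_landmark_indices()
        meta = {
            "n_subjects": len(self.aligned_models_),
            "n_retained": self.n_retained_,
            "retention_threshold": self.retention_threshold,
            "explained_fraction": self.explained_fraction_.tolist(),
            "landmark_indices": idx,
        }
        (d / "atlas.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "ShapeAtlas":
        import json
        from pathlib import Path

        from .mesh_core import LandmarkSet

        d = Path(directory)
        meta = json.loads((d / "atlas.json").read_text())
        self = cls(retention_threshold=meta["retention_threshold"])
        self.mean_shape_ = np.load(d / "mean_shape.npy")
        self.modes_ = np.load(d / "modes.npy")
        self.eigenvalues_ = np.load(d / "eigenvalues.npy")
        self.training_scores_ = np.load(d / "training_scores.npy")
        self.explained_fraction_ = np.asarray(meta["explained_fraction"])
        self.n_retained_ = meta["n_retained"]
        nonzero = self.eigenvalues_ > 1e-12
        self._score_sd_ = np.sqrt(np.where(nonzero, self.eigenvalues_, 1.0))
        faces = np.load(d / "template_faces.npy")
        labels = np.load(d / "template_labels.npy")
        idx = {k: int(v) for k, v in meta["landmark_indices"].items()}
        ed_v, es_v = split_shape_vector(self.mean_shape_)
        ed = SurfaceMesh(ed_v, faces, labels)
        es = SurfaceMesh(es_v, faces, labels)
        self.template_model_ = BiventricularModel(
            "atlas_mean",
            ed,
            es,
            LandmarkSet(**{k: ed_v[i] for k, i in idx.items()}),
            LandmarkSet(**{k: es_v[i] for k, i in idx.items()}),
            landmark_indices=idx,
        )
        self.aligned_models_ = [self.template_model_] * meta["n_subjects"]
        return self

    def _nearest_landmark_indices(self) -> dict[str, int]:
        """Map landmarks to nearest template ED vertices (fallback)."""
        tm = self.template_model_
        out = {}
        for name in ("mv_centroid", "tv_centroid", "pv_centroid", "rv_apex", "lv_apex"):
            p = getattr(tm.landmarks_ed, name)
            out[name] = int(np.linalg.norm(tm.ed.vertices - p, axis=1).argmin())
        return out


# --------------------------------------------------------------------------
# functional wrappers (spec-style operation names)
# --------------------------------------------------------------------------

def fit_pca(models: list[BiventricularModel], retention_threshold: float = 0.01) -> ShapeAtlas:
    """Build a ShapeAtlas (GPA + PCA) from corresponded models."""
    return ShapeAtlas(retention_threshold=retention_threshold).fit(models)


def project(atlas: ShapeAtlas, model: BiventricularModel) -> np.ndarray:
    return atlas.project(model)


def synthesize_shape(
    atlas: ShapeAtlas, direction: int | np.ndarray, magnitude_sd: float
) -> BiventricularModel:
    return atlas.synthesize(direction, magnitude_sd)


@dataclass
class AtlasSummary:
    n_subjects: int
    n_retained: int
    explained_by_retained: float
    eigenvalues: np.ndarray

    @classmethod
    def from_atlas(cls, atlas: ShapeAtlas) -> "AtlasSummary":
        return cls(
            n_subjects=len(atlas.aligned_models_),
            n_retained=atlas.n_retained_,
            explained_by_retained=float(
                atlas.explained_fraction_[: atlas.n_retained_].sum()
            ),
            eigenvalues=atlas.eigenvalues_,
        )
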