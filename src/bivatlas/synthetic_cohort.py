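"""Synthetic biventricular cohorts with known latent structure.

Every downstream stage of the package (volumetrics, parcellation, atlas,
calipers, risk modelling) is exercised on cohorts produced here, because the
clinical CMR-derived meshes this pipeline was designed for cannot be
redistributed.  The generator emulates their essential structure:

* a fixed-topology template of three watertight surfaces — LV endocardium
  (truncated prolate spheroid), LV epicardium (offset shell) and an RV
  built as lofted D-shaped sections with a planar septal side and a capped
  base carrying the tricuspid/pulmonary valve landmarks;
* inter-subject shape variation as a few orthonormal vertex-displacement
  fields (LV basal dilation, RV apical dilation with basal constriction,
  global size) scaled by Gaussian latent factors, plus iid vertex noise;
* an ED->ES contraction toward each chamber's long axis with a per-subject
  global ejection-fraction target and per-region RV multipliers (the LV
  epicardium contracts so that wall volume — and hence mass — is conserved);
* a random rigid pose applied identically to both phases;
* a Bernoulli adverse-outcome label driven by a logistic model on the
  latent factors and the apical contraction, and a pulmonary regurgitant
  volume index (PRVI) tied to a designated latent factor.

The per-subject random streams are spawned by counter from one seed, so a
cohort can be extended without reshuffling existing subjects, and a fixed
seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation
from scipy.special import expit, roots_hermitenorm

from .mesh_core import (
    LV_ENDO,
    LV_EPI,
    RV_FREE_WALL,
    RV_SEPTUM,
    BiventricularModel,
    LandmarkSet,
    SubjectRecord,
    SurfaceMesh,
    chamber_volume,
)
from .parcellation import APICAL, INLET, OUTLET, nearest_landmark_regions


class GenerationError(ValueError):
    """The cohort specification produces invalid geometry."""


# --------------------------------------------------------------------------
# template geometry (mm)
# --------------------------------------------------------------------------

#: LV endocardial semi-axes; gives an EDV near the study population mean
LV_ENDO_AXES = (28.0, 26.0, 48.0)
LV_EPI_AXES = (34.5, 32.5, 55.0)
#: RV half-ellipsoid: extent from the septal plane, lateral half-width, length
RV_AXES = (40.0, 54.0, 52.0)
SEPTAL_PLANE_X = 36.0
RV_CENTER_Z = 2.0
#: basal truncation as a fraction of the long semi-axis
TRUNCATION = 0.55


@dataclass
class Template:
    """Fixed-topology reference shape all subjects share."""

    mesh: SurfaceMesh
    landmark_indices: dict[str, int]

    @property
    def n_vertices(self) -> int:
        return len(self.mesh.vertices)

    def landmarks_from(self, vertices: np.ndarray) -> LandmarkSet:
        return LandmarkSet(**{k: vertices[i] for k, i in self.landmark_indices.items()})


def _orient_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip winding if the closed surface's signed volume is negative."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    if np.einsum("ij,ij->", v0, np.cross(v1, v2)) < 0:
        faces = faces[:, [0, 2, 1]]
    return faces


def _truncated_ellipsoid(
    axes: Sequence[float],
    center: Sequence[float],
    n_theta: int,
    n_rings: int,
    trunc: float = TRUNCATION,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Closed truncated ellipsoid: apex pole, rings, flat basal cap.

    Returns (vertices, faces, apex_index, base_center_index).
    """
    a, b, c = axes
    cx, cy, cz = center
    phi_base = np.arccos(trunc)
    phis = np.pi - (np.pi - phi_base) * np.arange(1, n_rings + 1) / n_rings
    thetas = 2 * np.pi * np.arange(n_theta) / n_theta

    verts = [np.array([cx, cy, cz - c])]  # apex pole
    for phi in phis:
        ring = np.stack(
            [
                cx + a * np.cos(thetas) * np.sin(phi),
                cy + b * np.sin(thetas) * np.sin(phi),
                np.full(n_theta, cz + c * np.cos(phi)),
            ],
            axis=1,
        )
        verts.append(ring)
    base_center = np.array([cx, cy, cz + c * trunc])
    vertices = np.concatenate([verts[0][None], *verts[1:], base_center[None]])
    apex_idx = 0
    base_idx = len(vertices) - 1

    def ring_idx(j: int, i: int) -> int:  # j: 0-based ring, i: segment
        return 1 + j * n_theta + i % n_theta

    faces = []
    for i in range(n_theta):  # apex fan
        faces.append([apex_idx, ring_idx(0, i), ring_idx(0, i + 1)])
    for j in range(n_rings - 1):  # strips
        for i in range(n_theta):
            q = (ring_idx(j, i), ring_idx(j, i + 1), ring_idx(j + 1, i + 1), ring_idx(j + 1, i))
            faces.append([q[0], q[2], q[1]])
            faces.append([q[0], q[3], q[2]])
    for i in range(n_theta):  # basal cap fan
        faces.append([base_idx, ring_idx(n_rings - 1, i + 1), ring_idx(n_rings - 1, i)])
    faces = _orient_outward(vertices, np.asarray(faces, dtype=np.int64))
    return vertices, faces, apex_idx, base_idx


def _rv_section_curve(n_theta: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed unit D-shaped section; returns (points (n,2), septal mask).

    Free wall = half ellipse on x >= 0, septum = flat chord on x = 0.
    """
    n_flat = max(n_theta // 3, 2)
    n_arc = n_theta - n_flat
    u = -np.pi / 2 + np.pi * np.arange(n_arc + 1) / n_arc
    arc = np.stack([np.cos(u), np.sin(u)], axis=1)
    arc[0] = (0.0, -1.0)
    arc[-1] = (0.0, 1.0)
    m = np.arange(1, n_flat)
    flat = np.stack([np.zeros(n_flat - 1), 1.0 - 2.0 * m / n_flat], axis=1)
    pts = np.concatenate([arc, flat])
    septal = np.abs(pts[:, 0]) < 1e-12
    return pts, septal


def _rv_mesh(n_theta: int, n_rings: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Lofted watertight RV with planar septum and a two-ring basal cap.

    Returns (vertices, faces, septal vertex mask, info dict).
    """
    rx, ry, c = RV_AXES
    section, septal2d = _rv_section_curve(n_theta)
    n_sec = len(section)
    phi_base = np.arccos(TRUNCATION)
    phis = np.pi - (np.pi - phi_base) * np.arange(1, n_rings + 1) / n_rings
    z_base = RV_CENTER_Z + c * TRUNCATION

    verts = [np.array([SEPTAL_PLANE_X, 0.0, RV_CENTER_Z - c])]  # apex pole
    septal_mask = [False]
    for phi in phis:
        s = np.sin(phi)
        ring = np.stack(
            [
                SEPTAL_PLANE_X + rx * s * section[:, 0],
                ry * s * section[:, 1],
                np.full(n_sec, RV_CENTER_Z + c * np.cos(phi)),
            ],
            axis=1,
        )
        verts.append(ring)
        septal_mask.extend(septal2d.tolist())

    # basal cap: rim (= last ring) -> mid ring -> centroid fan
    s_b = np.sin(phi_base)
    centroid = np.array([SEPTAL_PLANE_X + 4 * rx * s_b / (3 * np.pi), 0.0, z_base])
    rim = verts[-1]
    mid = centroid + 0.5 * (rim - centroid)
    verts.append(mid)
    septal_mask.extend([False] * n_sec)
    verts.append(centroid[None])
    septal_mask.append(False)

    vertices = np.concatenate([verts[0][None], *verts[1:-1], verts[-1]])
    apex_idx = 0
    mid0 = 1 + n_rings * n_sec
    center_idx = len(vertices) - 1

    def ring_idx(j: int, i: int) -> int:
        return 1 + j * n_sec + i % n_sec

    def mid_idx(i: int) -> int:
        return mid0 + i % n_sec

    faces = []
    for i in range(n_sec):
        faces.append([apex_idx, ring_idx(0, i), ring_idx(0, i + 1)])
    for j in range(n_rings - 1):
        for i in range(n_sec):
            q = (ring_idx(j, i), ring_idx(j, i + 1), ring_idx(j + 1, i + 1), ring_idx(j + 1, i))
            faces.append([q[0], q[2], q[1]])
            faces.append([q[0], q[3], q[2]])
    last = n_rings - 1
    for i in range(n_sec):  # rim -> mid strip (cap plane)
        q = (ring_idx(last, i), ring_idx(last, i + 1), mid_idx(i + 1), mid_idx(i))
        faces.append([q[0], q[2], q[1]])
        faces.append([q[0], q[3], q[2]])
    for i in range(n_sec):  # mid -> centre fan
        faces.append([center_idx, mid_idx(i + 1), mid_idx(i)])

    info = {"apex": apex_idx, "mid0": mid0, "n_sec": n_sec, "z_base": z_base, "s_b": s_b}
    faces = _orient_outward(vertices, np.asarray(faces, dtype=np.int64))
    return vertices, faces, np.asarray(septal_mask), info


def build_template(n_theta: int = 24, n_rings: int = 12) -> Template:
    """Construct the biventricular template at the given angular resolution."""
    lv_v, lv_f, lv_apex, lv_base = _truncated_ellipsoid(LV_ENDO_AXES, (0, 0, 0), n_theta, n_rings)
    epi_v, epi_f, _, _ = _truncated_ellipsoid(LV_EPI_AXES, (0, 0, 0), n_theta, n_rings)
    rv_v, rv_f, rv_septal, rv_info = _rv_mesh(n_theta, n_rings)

    offs_epi = len(lv_v)
    offs_rv = offs_epi + len(epi_v)
    vertices = np.concatenate([lv_v, epi_v, rv_v])
    faces = np.concatenate([lv_f, epi_f + offs_epi, rv_f + offs_rv])
    labels = np.concatenate(
        [
            np.full(len(lv_v), LV_ENDO),
            np.full(len(epi_v), LV_EPI),
            np.where(rv_septal, RV_SEPTUM, RV_FREE_WALL),
        ]
    )
    mesh = SurfaceMesh(vertices, faces, labels)
    mesh.validate()

    # valve landmarks sit on the RV basal cap mid-ring
    rx, ry, _ = RV_AXES
    s_b, z_base = rv_info["s_b"], rv_info["z_base"]
    mid_ids = offs_rv + rv_info["mid0"] + np.arange(rv_info["n_sec"])
    tv_target = np.array([SEPTAL_PLANE_X + 0.2 * rx * s_b, -0.6 * ry * s_b, z_base])
    pv_target = np.array([SEPTAL_PLANE_X + 0.2 * rx * s_b, +0.6 * ry * s_b, z_base])
    tv_idx = int(mid_ids[np.linalg.norm(vertices[mid_ids] - tv_target, axis=1).argmin()])
    pv_idx = int(mid_ids[np.linalg.norm(vertices[mid_ids] - pv_target, axis=1).argmin()])

    landmark_indices = {
        "mv_centroid": lv_base,
        "tv_centroid": tv_idx,
        "pv_centroid": pv_idx,
        "rv_apex": offs_rv + rv_info["apex"],
        "lv_apex": lv_apex,
    }
    return Template(mesh, landmark_indices)


# --------------------------------------------------------------------------
# latent displacement fields
# --------------------------------------------------------------------------

def make_basis_fields(template: Template, n_latent: int = 3) -> np.ndarray:
    """Orthonormal vertex-displacement fields, shape (n_latent, V, 3).

    Field 1: LV basal dilation (radial, weight growing toward the base).
    Field 2: RV free-wall apical dilation with basal constriction.
    Field 3: global isotropic size.

    Each field is corrected, within its own support, to have zero net
    translation and zero net rotational moment about the centroid, so that
    latent shape variation carries no pose component and rigid alignment
    of the cohort is a fixed point of Procrustes analysis.  Fields are then
    Gram-Schmidt orthonormalized.
    """
    if not 1 <= n_latent <= 3:
        raise ValueError("n_latent must be between 1 and 3")
    mesh = template.mesh
    V = len(mesh.vertices)
    verts = mesh.vertices
    labels = mesh.vertex_labels
    fields = np.zeros((3, V, 3))

    # field 1: LV radial dilation weighted by squared normalized height
    lv = np.isin(labels, (LV_ENDO, LV_EPI))
    xy = verts[:, :2].copy()
    r = np.linalg.norm(xy, axis=1)
    radial = np.zeros((V, 3))
    ok = r > 1e-9
    radial[ok, :2] = xy[ok] / r[ok, None]
    z_lv = verts[lv, 2]
    t = (verts[:, 2] - z_lv.min()) / (z_lv.max() - z_lv.min())
    w = np.clip(t, 0.0, 1.0) ** 2
    fields[0][lv] = (w[:, None] * radial)[lv]

    # field 2: RV free-wall radial about the RV long axis, + apical / - basal
    fw = labels == RV_FREE_WALL
    apex = verts[template.landmark_indices["rv_apex"]]
    base = 0.5 * (
        verts[template.landmark_indices["tv_centroid"]]
        + verts[template.landmark_indices["pv_centroid"]]
    )
    axis = (base - apex) / np.linalg.norm(base - apex)
    d = verts - apex
    ax = d @ axis
    rad_vec = d - ax[:, None] * axis
    rn = np.linalg.norm(rad_vec, axis=1)
    rad_unit = np.zeros_like(rad_vec)
    ok = rn > 1e-9
    rad_unit[ok] = rad_vec[ok] / rn[ok, None]
    t_rv = np.clip(ax / (ax[fw].max() if fw.any() else 1.0), 0.0, 1.0)
    # taper to zero at the basal cap so the valve landmarks (and with them the
    # contraction frame) are not displaced by this field
    w_rv = np.cos(np.pi * t_rv) * np.clip((1.0 - t_rv) / 0.15, 0.0, 1.0)
    fields[1][fw] = (w_rv[:, None] * rad_unit)[fw]

    # field 3: global size
    fields[2] = verts - verts.mean(axis=0)

    # rigid-motion tangent space: translations + rotations about the centroid
    centred = verts - verts.mean(axis=0)
    rigid = np.zeros((6, V, 3))
    rigid[0, :, 0] = rigid[1, :, 1] = rigid[2, :, 2] = 1.0
    for a, e in enumerate(np.eye(3)):
        rigid[3 + a] = np.cross(np.broadcast_to(e, (V, 3)), centred)
    rigid_flat = rigid.reshape(6, -1)

    supports = [lv, fw, np.ones(V, dtype=bool)]
    flat = fields.reshape(3, -1)
    for k in range(3):
        # subtract support-restricted rigid fields so the global net
        # translation/moment vanish without spreading the field globally
        masked = rigid * supports[k][None, :, None]
        M = masked.reshape(6, -1)
        G = rigid_flat @ M.T
        c = np.linalg.solve(G, rigid_flat @ flat[k])
        flat[k] = flat[k] - c @ M
    out = []
    for k in range(n_latent):
        v = flat[k].copy()
        for u in out:
            v -= (v @ u) * u
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise GenerationError("degenerate basis field")
        out.append(v / n)
    return np.asarray(out).reshape(n_latent, V, 3)


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------

def _default_outcome_model() -> dict:
    # moderate effects (odds ratio ~e^0.9~2.5 per sd) on the LV-basal-dilation
    # latent and on reduced apical contraction; event rate matches 16/192
    return {
        "latent": (0.9, 0.0, 0.0),
        "apical": 0.9,
        "target_rate": 16.0 / 192.0,
        "intercept": None,
    }


def _default_prvi_model() -> dict:
    # PRVI tied to the RV-dilation latent; slope == noise sd gives R^2 = 0.5
    return {"mean": 25.0, "latent_index": 1, "slope": 10.0, "noise_sd": 10.0}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the target population: 192 subjects with a ~16/192
    adverse-event rate, LV EF 52 +/- 8 %, lower outlet contraction, and
    PRVI around 25 ml/m^2 explaining half its variance through RV dilation.
    """

    n_subjects: int = 192
    n_latent: int = 3
    latent_sd: tuple[float, ...] = (35.0, 25.0, 15.0)
    contraction_mean: float = 0.52
    contraction_sd: float = 0.08
    longitudinal_shortening: float = 0.15
    regional_contraction: tuple[float, float, float] = (1.14, 1.22, 1.14)
    regional_contraction_sd: tuple[float, float, float] = (0.04, 0.04, 0.08)
    outcome_model: dict = field(default_factory=_default_outcome_model)
    prvi_model: dict = field(default_factory=_default_prvi_model)
    pose_rotation_sd_deg: float = 8.0
    pose_translation_sd_mm: float = 10.0
    vertex_noise_sd: float = 0.8
    seed: int = 0
    n_theta: int = 24
    n_rings: int = 12

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise GenerationError("n_subjects must be >= 2")
        if len(self.latent_sd) != self.n_latent:
            raise GenerationError("latent_sd length must equal n_latent")
        sds = (
            *self.latent_sd,
            self.contraction_sd,
            *self.regional_contraction_sd,
            self.pose_rotation_sd_deg,
            self.pose_translation_sd_mm,
            self.vertex_noise_sd,
        )
        if any(s < 0 for s in sds):
            raise GenerationError("all standard deviations must be >= 0")
        if not 0.0 < self.contraction_mean < 1.0:
            raise GenerationError("contraction_mean (target EF) must be in (0, 1)")
        l = 1.0 - self.longitudinal_shortening
        worst = (1.0 - self.contraction_mean) * max(self.regional_contraction) ** 2
        if worst >= 1.0 or l <= 0:
            raise GenerationError("contraction would produce ESV >= EDV; rejecting spec")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Per-subject latent state; for tests and audits, never for pipeline stages."""

    table: pd.DataFrame
    basis_fields: np.ndarray
    template: Template


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _contract(
    verts: np.ndarray,
    base: np.ndarray,
    axis_unit: np.ndarray,
    radial_scale: np.ndarray | float,
    longitudinal_scale: float,
) -> np.ndarray:
    """Scale radial distance to the long axis and axial distance to the base."""
    d = verts - base
    ax = d @ axis_unit
    rad = d - ax[:, None] * axis_unit
    s = np.broadcast_to(np.atleast_1d(radial_scale), (len(verts),))
    return base + (longitudinal_scale * ax)[:, None] * axis_unit + s[:, None] * rad


def _solve_intercept(sigma: float, target_rate: float) -> float:
    """Intercept b0 with E[expit(b0 + sigma*Z)] = target_rate, Z ~ N(0,1)."""
    if sigma == 0.0:
        return float(np.log(target_rate / (1.0 - target_rate)))
    x, w = roots_hermitenorm(60)
    w = w / w.sum()

    def mean_rate(b0: float) -> float:
        return float(w @ expit(b0 + sigma * x)) - target_rate

    return float(brentq(mean_rate, -25.0, 25.0))


def _random_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    if sd_deg == 0.0:
        rng.normal(size=4)  # keep the draw count stable across specs
        return np.eye(3)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    angle = np.deg2rad(rng.normal(0.0, sd_deg))
    return Rotation.from_rotvec(angle * v).as_matrix()


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[BiventricularModel], list[SubjectRecord], GroundTruth]:
    """Generate a cohort of models + records with recorded ground truth."""
    template = build_template(spec.n_theta, spec.n_rings)
    fields = make_basis_fields(template, spec.n_latent)
    tverts = template.mesh.vertices
    faces = template.mesh.faces
    labels = template.mesh.vertex_labels
    lv_endo = labels == LV_ENDO
    lv_epi = labels == LV_EPI
    rv = np.isin(labels, (RV_FREE_WALL, RV_SEPTUM))
    # topology is fixed and validated once in build_template, so per-subject
    # volumes can use the raw signed-tetra sum without watertightness checks
    from .mesh_core import _signed_volume_mm3

    chamber_face_arrays = {
        "lv_endo": template.mesh.chamber_faces((LV_ENDO,)),
        "lv_epi": template.mesh.chamber_faces((LV_EPI,)),
        "rv": template.mesh.chamber_faces((RV_FREE_WALL, RV_SEPTUM)),
    }

    def fast_volume(verts: np.ndarray, chamber: str) -> float:
        return _signed_volume_mm3(verts, chamber_face_arrays[chamber]) / 1000.0
    l_long = 1.0 - spec.longitudinal_shortening

    # Latent factors are drawn from a dedicated cohort-level stream and
    # whitened so each cohort realizes the prescribed latent covariance
    # (zero mean, diagonal with the given sds) exactly; cohort-level shape
    # statistics (explained-variance fractions, mode-latent alignment) then
    # match the specification instead of fluctuating with the sampling noise
    # of empirical variances and cross-correlations.
    rng_lat = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2**31,)))
    L = rng_lat.normal(size=(spec.n_subjects, spec.n_latent))
    L = L - L.mean(axis=0)
    if spec.n_subjects > spec.n_latent + 1:
        cov = (L.T @ L) / (spec.n_subjects - 1)
        L = L @ np.linalg.inv(np.linalg.cholesky(cov)).T
    else:  # too few subjects to whiten; scale marginally
        sd = L.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        L = L / sd
    L = L * np.asarray(spec.latent_sd)

    om = spec.outcome_model
    lat_coef = np.asarray(om.get("latent", np.zeros(spec.n_latent)), dtype=float)
    ap_coef = float(om.get("apical", 0.0))
    sigma_eta = float(np.sqrt((lat_coef[: spec.n_latent] ** 2).sum() + ap_coef**2))
    if om.get("intercept") is None:
        b0 = _solve_intercept(sigma_eta, float(om.get("target_rate", 16.0 / 192.0)))
    else:
        b0 = float(om["intercept"])

    pm = spec.prvi_model
    models: list[BiventricularModel] = []
    records: list[SubjectRecord] = []
    truth_rows = []

    for i in range(spec.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(i,)))
        latents = L[i]
        noise = rng.normal(0.0, 1.0, size=tverts.shape) * spec.vertex_noise_sd
        ef = float(np.clip(rng.normal(spec.contraction_mean, spec.contraction_sd), 0.05, 0.85))
        mult = np.asarray(spec.regional_contraction) + rng.normal(
            0.0, 1.0, size=3
        ) * np.asarray(spec.regional_contraction_sd)
        mult = np.clip(mult, 0.4, np.sqrt(0.98 / (1.0 - ef)))
        rot = _random_rotation(rng, spec.pose_rotation_sd_deg)
        trans = rng.normal(0.0, 1.0, size=3) * spec.pose_translation_sd_mm

        ed_verts = tverts + np.tensordot(latents, fields, axes=(0, 0)) + noise
        lm_ed = template.landmarks_from(ed_verts)

        # --- contraction -> ES ------------------------------------------
        es_verts = ed_verts.copy()
        s_rad = float(np.sqrt((1.0 - ef) / l_long))

        u_lv = lm_ed.lv_apex - lm_ed.mv_centroid
        u_lv = u_lv / np.linalg.norm(u_lv)
        es_verts[lv_endo] = _contract(ed_verts[lv_endo], lm_ed.mv_centroid, u_lv, s_rad, l_long)

        ed_mesh = SurfaceMesh(ed_verts, faces, labels)
        v_endo = fast_volume(ed_verts, "lv_endo")
        v_epi = fast_volume(ed_verts, "lv_epi")
        s_epi_sq = (v_epi - v_endo * (1.0 - s_rad**2 * l_long)) / (l_long * v_epi)
        if s_epi_sq <= 0:
            raise GenerationError(f"subject {i}: epicardial contraction underflow")
        es_verts[lv_epi] = _contract(
            ed_verts[lv_epi], lm_ed.mv_centroid, u_lv, float(np.sqrt(s_epi_sq)), l_long
        )

        region = nearest_landmark_regions(
            ed_verts[rv], lm_ed.tv_centroid, lm_ed.pv_centroid, lm_ed.rv_apex
        )
        u_rv = lm_ed.rv_apex - lm_ed.tv_centroid
        u_rv = u_rv / np.linalg.norm(u_rv)
        s_region = s_rad * mult[region]
        es_verts[rv] = _contract(ed_verts[rv], lm_ed.tv_centroid, u_rv, s_region, l_long)

        es_mesh = SurfaceMesh(es_verts, faces, labels)
        for chamber in ("lv_endo", "rv"):
            if fast_volume(es_verts, chamber) >= fast_volume(ed_verts, chamber):
                raise GenerationError(f"subject {i}: ESV >= EDV in {chamber}")

        lm_es = template.landmarks_from(es_verts)

        # --- pose --------------------------------------------------------
        model = BiventricularModel(
            subject_id=f"S{i:04d}",
            ed=ed_mesh,
            es=es_mesh,
            landmarks_ed=lm_ed,
            landmarks_es=lm_es,
            landmark_indices=dict(template.landmark_indices),
        ).transformed(rot, trans)
        models.append(model)

        # --- record ------------------------------------------------------
        bsa = float(np.clip(rng.normal(1.59, 0.30), 0.9, 2.6))
        qrs = float(rng.normal(147.2, 22.8))
        sbp = float(rng.normal(118.0, 14.4))
        dbp = float(rng.normal(64.1, 10.2))

        z_lat = np.array(
            [
                latents[k] / spec.latent_sd[k] if spec.latent_sd[k] > 0 else 0.0
                for k in range(spec.n_latent)
            ]
        )
        ap_sd = spec.regional_contraction_sd[APICAL]
        z_ap = (mult[APICAL] - spec.regional_contraction[APICAL]) / ap_sd if ap_sd > 0 else 0.0
        eta = b0 + float(lat_coef[: spec.n_latent] @ z_lat) + ap_coef * z_ap
        p = float(expit(eta))
        outcome = int(rng.uniform() < p)

        idx = int(pm.get("latent_index", 1))
        z_prvi = z_lat[idx] if idx < spec.n_latent else 0.0
        prvi = float(
            max(
                0.0,
                pm.get("mean", 25.0)
                + pm.get("slope", 10.0) * z_prvi
                + rng.normal(0.0, pm.get("noise_sd", 10.0)),
            )
        )
        records.append(
            SubjectRecord(
                subject_id=model.subject_id,
                bsa=bsa,
                qrs_ms=qrs,
                sbp_mmHg=sbp,
                dbp_mmHg=dbp,
                adverse_outcome=outcome,
                prvi=prvi,
            )
        )

        row = {
            "subject_id": model.subject_id,
            "ef_target": ef,
            "p_outcome": p,
            "adverse_outcome": outcome,
            "prvi": prvi,
            "m_inlet": mult[INLET],
            "m_outlet": mult[OUTLET],
            "m_apical": mult[APICAL],
            "ef_inlet_true": 1.0 - (1.0 - ef) * mult[INLET] ** 2,
            "ef_outlet_true": 1.0 - (1.0 - ef) * mult[OUTLET] ** 2,
            "ef_apical_true": 1.0 - (1.0 - ef) * mult[APICAL] ** 2,
            "rot_x": Rotation.from_matrix(rot).as_rotvec()[0],
            "rot_y": Rotation.from_matrix(rot).as_rotvec()[1],
            "rot_z": Rotation.from_matrix(rot).as_rotvec()[2],
            "trans_x": trans[0],
            "trans_y": trans[1],
            "trans_z": trans[2],
        }
        for k in range(spec.n_latent):
            row[f"latent_{k + 1}"] = latents[k]
        truth_rows.append(row)

    truth = GroundTruth(
        table=pd.DataFrame(truth_rows).set_index("subject_id"),
        basis_fields=fields,
        template=template,
    )
    return models, records, truth
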