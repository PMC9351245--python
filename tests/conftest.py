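"""Shared fixtures: synthetic cohorts and analytic oracle meshes."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from bivatlas.mesh_core import (
    LV_ENDO,
    RV_FREE_WALL,
    RV_SEPTUM,
    BiventricularModel,
    LandmarkSet,
    SurfaceMesh,
)
from bivatlas.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale cohort: 192 subjects under the default conditions."""
    return generate_cohort(CohortSpec(n_subjects=192, seed=11))


@pytest.fixture(scope="session")
def latent_cohort():
    """Noise-free cohort driven purely by the three latent fields.

    sds (3, 2, 1) mm with uniform contraction, so the population covariance
    is exactly rank 3 with variances 9:4:1 (up to the ED->ES amplification).
    """
    spec = CohortSpec(
        n_subjects=200,
        seed=3,
        latent_sd=(3.0, 2.0, 1.0),
        vertex_noise_sd=0.0,
        contraction_sd=0.0,
        regional_contraction=(1.0, 1.0, 1.0),
        regional_contraction_sd=(0.0, 0.0, 0.0),
    )
    return generate_cohort(spec)


def ellipsoid_mesh(a: float, b: float, c: float, subdivisions: int = 4) -> trimesh.Trimesh:
    """Triangulated ellipsoid with semi-axes (a, b, c) from an icosphere."""
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    m = sphere.copy()
    m.vertices = m.vertices * np.array([a, b, c])
    return m


def ellipsoid_lv_model(a_ap: float = 20.0, b_sl: float = 15.0, c_long: float = 45.0):
    """An LV-only model for calliper oracles: full ellipsoid + flat septum.

    The long axis is z (apex at -c), the septal-lateral axis is y (a small
    planar septum patch sits at y = -4b with normal +y and a couple of RV
    free-wall marker vertices at y = +4b fix the LV->RV orientation).
    """
    ell = ellipsoid_mesh(a_ap, b_sl, c_long)
    verts = [np.asarray(ell.vertices)]
    labels = [np.full(len(ell.vertices), LV_ENDO)]
    faces = [np.asarray(ell.faces)]

    grid = np.array(
        [[x, -4.0 * b_sl, z] for z in (-10.0, 0.0, 10.0) for x in (-10.0, 0.0, 10.0)]
    )
    offs = len(verts[0])
    verts.append(grid)
    labels.append(np.full(len(grid), RV_SEPTUM))
    faces.append(np.array([[offs, offs + 1, offs + 4], [offs + 4, offs + 5, offs + 8]]))
    fw = np.array([[0.0, 4.0 * b_sl, 0.0], [5.0, 4.0 * b_sl, 0.0]])
    verts.append(fw)
    labels.append(np.full(2, RV_FREE_WALL))

    mesh = SurfaceMesh(
        np.concatenate(verts), np.concatenate(faces), np.concatenate(labels)
    )
    lm = LandmarkSet(
        mv_centroid=np.array([0.0, 0.0, c_long]),
        tv_centroid=np.array([0.0, -4.0 * b_sl, 10.0]),
        pv_centroid=np.array([10.0, -4.0 * b_sl, 10.0]),
        rv_apex=np.array([0.0, -4.0 * b_sl, -10.0]),
        lv_apex=np.array([0.0, 0.0, -c_long]),
    )
    return BiventricularModel("ellipsoid", mesh, mesh.copy(), lm, lm)


@pytest.fixture(scope="session")
def lv_ellipsoid_model():
    return ellipsoid_lv_model()


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
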