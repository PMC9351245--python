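"""Volume integration, volumetrics identities and mesh/landmark I/O."""

import numpy as np
import pytest
import trimesh

from bivatlas.io import (
    read_landmarks,
    read_mesh,
    read_model,
    write_landmarks,
    write_mesh,
    write_model,
)
from bivatlas.mesh_core import (
    LV_ENDO,
    LV_EPI,
    MeshValidationError,
    SubjectRecord,
    SurfaceMesh,
    Volumetrics,
    chamber_volume,
    compute_volumetrics,
    mosteller_bsa,
)
from bivatlas.synthetic_cohort import build_template

from conftest import ellipsoid_mesh


def as_surface(tm: trimesh.Trimesh, label: int = LV_ENDO) -> SurfaceMesh:
    return SurfaceMesh(tm.vertices, tm.faces, np.full(len(tm.vertices), label))


class TestChamberVolume:
    def test_sphere_matches_analytic_volume(self):
        r = 10.0
        tm = trimesh.creation.icosphere(subdivisions=5, radius=r)
        assert len(tm.faces) >= 20000
        vol = chamber_volume(as_surface(tm), (LV_ENDO,))
        analytic = 4.0 / 3.0 * np.pi * r**3 / 1000.0  # 4.18879 ml
        assert vol == pytest.approx(analytic, rel=5e-3)

    def test_icosahedron_closed_form(self):
        # unit circumradius icosahedron: V = (5/12)(3+sqrt5) a^3, a = 4/sqrt(10+2sqrt5)
        tm = trimesh.creation.icosahedron()
        a = 4.0 / np.sqrt(10.0 + 2.0 * np.sqrt(5.0))
        expected_mm3 = 5.0 / 12.0 * (3.0 + np.sqrt(5.0)) * a**3
        assert expected_mm3 == pytest.approx(2.53615, abs=1e-5)
        vol_ml = chamber_volume(as_surface(tm), (LV_ENDO,))
        assert vol_ml * 1000.0 == pytest.approx(expected_mm3, rel=1e-9)

    def test_refinement_reduces_error(self):
        analytic = 4.0 / 3.0 * np.pi * 20.0 * 15.0 * 45.0 / 1000.0
        errs = []
        for sub in (4, 5):
            vol = chamber_volume(as_surface(ellipsoid_mesh(20, 15, 45, sub)), (LV_ENDO,))
            errs.append(abs(vol - analytic) / analytic)
        assert errs[1] <= errs[0] / 2.0

    def test_rigid_invariance_and_cubic_scaling(self):
        from scipy.spatial.transform import Rotation

        mesh = as_surface(ellipsoid_mesh(20, 15, 45, 3))
        v0 = chamber_volume(mesh, (LV_ENDO,))
        R = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        moved = mesh.transformed(R, np.array([100.0, -50.0, 20.0]))
        assert chamber_volume(moved, (LV_ENDO,)) == pytest.approx(v0, rel=1e-9)
        for s in (0.5, 2.0):
            scaled = SurfaceMesh(mesh.vertices * s, mesh.faces, mesh.vertex_labels)
            assert chamber_volume(scaled, (LV_ENDO,)) == pytest.approx(v0 * s**3, rel=1e-9)

    def test_open_surface_rejected_with_offending_edges(self):
        tm = trimesh.creation.icosphere(subdivisions=2)
        mesh = SurfaceMesh(tm.vertices, tm.faces[:-1], np.full(len(tm.vertices), LV_ENDO))
        with pytest.raises(MeshValidationError, match="not watertight"):
            chamber_volume(mesh, (LV_ENDO,))


class TestVolumetrics:
    def test_sv_ef_and_indexing_identities(self):
        v = Volumetrics("s", lvedv=100.0, lvesv=60.0, rvedv=176.0, rvesv=100.0,
                        lvm=90.0, bsa=2.0)
        assert v.lv_sv == 40.0
        assert v.lvef == pytest.approx(0.40)
        assert v.rvedv_i == pytest.approx(88.0)
        assert v.lv_ed_mvr == pytest.approx(0.9)
        assert v.lv_es_mvr == pytest.approx(1.5)

    def test_ellipsoid_lv_mass_analytic(self):
        # endo 80 ml / epi 140 ml by construction -> LVM 63 g at 1.05 g/ml
        endo_axes = (30.0, 25.4648, 25.0)
        k = (140.0 / 80.0) ** (1.0 / 3.0)
        epi_axes = tuple(a * k for a in endo_axes)
        endo = ellipsoid_mesh(*endo_axes, 4)
        epi = ellipsoid_mesh(*epi_axes, 4)
        verts = np.concatenate([endo.vertices, epi.vertices])
        faces = np.concatenate([endo.faces, epi.faces + len(endo.vertices)])
        labels = np.concatenate(
            [np.full(len(endo.vertices), LV_ENDO), np.full(len(epi.vertices), LV_EPI)]
        )
        mesh = SurfaceMesh(verts, faces, labels)
        v_endo = chamber_volume(mesh, "lv_endo")
        v_epi = chamber_volume(mesh, "lv_epi")
        lvm = (v_epi - v_endo) * 1.05
        assert lvm == pytest.approx(63.0, rel=5e-3)
        assert lvm / v_endo == pytest.approx(0.7875, rel=1e-2)

    def test_inverted_surfaces_rejected(self, default_cohort):
        models, records, _ = default_cohort
        m = models[0]
        swapped_labels = m.ed.vertex_labels.copy()
        swapped_labels[m.ed.vertex_labels == LV_ENDO] = LV_EPI
        swapped_labels[m.ed.vertex_labels == LV_EPI] = LV_ENDO
        bad_ed = SurfaceMesh(m.ed.vertices, m.ed.faces, swapped_labels)
        bad_es = SurfaceMesh(m.es.vertices, m.es.faces, swapped_labels)
        from bivatlas.mesh_core import BiventricularModel

        bad = BiventricularModel(m.subject_id, bad_ed, bad_es, m.landmarks_ed, m.landmarks_es)
        with pytest.raises(MeshValidationError, match="epicardial"):
            compute_volumetrics(bad, records[0])

    def test_mosteller_fallback(self):
        assert mosteller_bsa(180.0, 72.0) == pytest.approx(1.897, abs=1e-3)


class TestIO:
    @pytest.mark.parametrize("fmt", ["ply", "vtk"])
    def test_writer_reader_identity(self, tmp_path, fmt):
        mesh = build_template().mesh
        path = tmp_path / f"m.{fmt}"
        write_mesh(path, mesh)
        back = read_mesh(path)
        assert np.abs(back.vertices - mesh.vertices).max() < 1e-6
        assert np.array_equal(back.faces, mesh.faces)
        assert np.array_equal(back.vertex_labels, mesh.vertex_labels)

    def test_model_round_trip_and_validation(self, tmp_path, default_cohort):
        models, _, _ = default_cohort
        write_model(tmp_path, models[0])
        sid = models[0].subject_id
        back = read_model(
            tmp_path / f"{sid}_ed.ply",
            tmp_path / f"{sid}_es.ply",
            tmp_path / f"{sid}_landmarks.json",
        )
        assert np.abs(back.ed.vertices - models[0].ed.vertices).max() < 1e-6
        assert np.allclose(back.landmarks_ed.rv_apex, models[0].landmarks_ed.rv_apex)

    def test_phase_topology_mismatch_rejected(self, tmp_path, default_cohort):
        models, _, _ = default_cohort
        m = models[0]
        write_model(tmp_path, m)
        truncated = SurfaceMesh(
            m.es.vertices[:-1], m.es.faces[: len(m.es.faces) - 6], m.es.vertex_labels[:-1]
        )
        write_mesh(tmp_path / "bad_es.ply", truncated)
        with pytest.raises(MeshValidationError, match="mismatch"):
            read_model(
                tmp_path / f"{m.subject_id}_ed.ply",
                tmp_path / "bad_es.ply",
                tmp_path / f"{m.subject_id}_landmarks.json",
            )

    def test_missing_landmark_rejected(self, tmp_path, default_cohort):
        import json

        models, _, _ = default_cohort
        m = models[0]
        payload = {"ed": m.landmarks_ed.as_dict(), "es": m.landmarks_es.as_dict()}
        del payload["ed"]["pv_centroid"]
        p = tmp_path / "lm.json"
        p.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="pv_centroid"):
            read_landmarks(p)

    def test_landmark_round_trip(self, tmp_path, default_cohort):
        models, _, _ = default_cohort
        m = models[0]
        p = tmp_path / "lm.json"
        write_landmarks(p, m.landmarks_ed, m.landmarks_es)
        ed, es = read_landmarks(p)
        assert np.allclose(ed.mv_centroid, m.landmarks_ed.mv_centroid)
        assert np.allclose(es.tv_centroid, m.landmarks_es.tv_centroid)
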