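"""Calliper oracles on analytic shapes, frame properties and the
mode-association regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from bivatlas.calipers import (
    CaliperError,
    anatomical_frame,
    compute_calipers,
    regress_calipers_on_modes,
    top_associations,
)

from conftest import ellipsoid_lv_model


class TestAnatomicalFrame:
    def test_template_septal_normal_is_x(self, default_cohort):
        models, _, _ = default_cohort
        # build an unposed subject to check against the construction plane
        from bivatlas.synthetic_cohort import CohortSpec, generate_cohort

        flat, _, _ = generate_cohort(
            CohortSpec(n_subjects=2, seed=0, vertex_noise_sd=0.0,
                       pose_rotation_sd_deg=0.0, pose_translation_sd_mm=0.0,
                       latent_sd=(0.0, 0.0, 0.0))
        )
        frame = anatomical_frame(flat[0], "ed")
        angle = np.degrees(np.arccos(abs(frame.septal_normal @ np.array([1.0, 0, 0]))))
        assert angle < 1.0
        assert frame.septal_normal[0] > 0  # oriented LV -> RV

    def test_frame_axes_orthogonal_where_defined(self, default_cohort):
        models, _, _ = default_cohort
        frame = anatomical_frame(models[0], "ed")
        assert abs(frame.ap_axis @ frame.septal_normal) < 1e-6
        assert abs(frame.ap_axis @ frame.long_axis_lv) < 1e-6

    def test_frame_rotates_with_model(self, default_cohort):
        models, _, _ = default_cohort
        frame = anatomical_frame(models[0], "ed")
        R = Rotation.from_rotvec([0.7, -0.2, 0.4]).as_matrix()
        frame_rot = anatomical_frame(models[0].transformed(R, np.zeros(3)), "ed")
        for a, b in [
            (frame.long_axis_lv, frame_rot.long_axis_lv),
            (frame.septal_normal, frame_rot.septal_normal),
            (frame.ap_axis, frame_rot.ap_axis),
        ]:
            assert np.allclose(R @ a, b, atol=1e-6)


class TestCaliperOracles:
    def test_ellipsoid_mid_level_widths(self, lv_ellipsoid_model):
        # semi-axes: AP 20 (x), SL 15 (y), long 45 (z); height = 90
        cs = compute_calipers(lv_ellipsoid_model, ventricles=("lv",))
        assert cs["lv_width_sl_mid_ed"] == pytest.approx(30.0, rel=1e-2)
        assert cs["lv_width_ap_mid_ed"] == pytest.approx(40.0, rel=1e-2)
        assert cs.eccentricity("lv", "mid", "ed") == pytest.approx(4.0 / 3.0, rel=1e-2)
        assert cs.sphericity("lv", "mid", "ed") == pytest.approx(30.0 / 90.0, rel=1e-2)

    def test_ellipsoid_off_mid_levels_match_cross_sections(self, lv_ellipsoid_model):
        cs = compute_calipers(lv_ellipsoid_model, ventricles=("lv",))
        for level, r in (("apical", 0.25), ("basal", 0.75)):
            shrink = np.sqrt(1.0 - (2.0 * r - 1.0) ** 2)
            assert cs[f"lv_width_sl_{level}_ed"] == pytest.approx(30.0 * shrink, rel=1e-2)

    def test_sphere_eccentricity_is_one_everywhere(self):
        model = ellipsoid_lv_model(a_ap=25.0, b_sl=25.0, c_long=25.0)
        cs = compute_calipers(model, ventricles=("lv",))
        for level in ("apical", "mid", "basal"):
            assert cs.eccentricity("lv", level, "ed") == pytest.approx(1.0, rel=2e-2)

    def test_no_motion_means_no_displacement(self, lv_ellipsoid_model):
        cs = compute_calipers(lv_ellipsoid_model, ventricles=("lv",))
        assert cs["lv_apex_displacement"] == 0.0
        assert cs["mv_displacement"] == 0.0
        assert cs["lv_longitudinal_shortening"] == 0.0

    def test_all_measures_rigid_invariant(self, default_cohort):
        models, _, _ = default_cohort
        cs = compute_calipers(models[0])
        R = Rotation.from_rotvec([-0.3, 0.9, 0.2]).as_matrix()
        moved = models[0].transformed(R, np.array([40.0, 7.0, -15.0]))
        cs2 = compute_calipers(moved)
        for key, val in cs.values.items():
            assert cs2[key] == pytest.approx(val, rel=1e-6, abs=1e-9), key

    def test_heights_scale_linearly_sphericity_invariant(self, default_cohort):
        from bivatlas.mesh_core import BiventricularModel, SurfaceMesh, LandmarkSet

        m = default_cohort[0][0]
        s = 1.3
        scale = lambda mesh: SurfaceMesh(mesh.vertices * s, mesh.faces, mesh.vertex_labels)
        lm = lambda l: LandmarkSet(**{k: v * s for k, v in
                                      ((n, getattr(l, n)) for n in
                                       ("mv_centroid", "tv_centroid", "pv_centroid",
                                        "rv_apex", "lv_apex"))})
        scaled = BiventricularModel(m.subject_id, scale(m.ed), scale(m.es),
                                    lm(m.landmarks_ed), lm(m.landmarks_es))
        cs, cs_s = compute_calipers(m), compute_calipers(scaled)
        assert cs_s["lv_height_ed"] == pytest.approx(s * cs["lv_height_ed"], rel=1e-9)
        assert cs_s.sphericity("rv", "mid", "ed") == pytest.approx(
            cs.sphericity("rv", "mid", "ed"), rel=1e-9
        )

    def test_empty_slice_raises(self, lv_ellipsoid_model):
        m = lv_ellipsoid_model
        # landmark-implied height far beyond the mesh -> basal plane misses it
        lm = m.landmarks_ed
        from bivatlas.mesh_core import BiventricularModel, LandmarkSet

        far = LandmarkSet(
            mv_centroid=np.array([0.0, 0.0, 400.0]),
            tv_centroid=lm.tv_centroid,
            pv_centroid=lm.pv_centroid,
            rv_apex=lm.rv_apex,
            lv_apex=lm.lv_apex,
        )
        bad = BiventricularModel(m.subject_id, m.ed, m.es, far, far)
        with pytest.raises(CaliperError, match="empty slice"):
            compute_calipers(bad, ventricles=("lv",))


class TestModeRegression:
    def test_recovers_linear_dependence_on_one_mode(self):
        rng = np.random.default_rng(0)
        n, k = 300, 4
        Z = rng.normal(size=(n, k))
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        cal = pd.DataFrame({"w": 2.0 * Z[:, 0] + rng.normal(0, 0.01, n)})
        coef = regress_calipers_on_modes(cal, Z)
        # response is standardized, so the driving mode's coefficient is ~1
        assert coef.loc["w", "mode_1"] == pytest.approx(1.0, abs=0.02)
        assert np.abs(coef.loc["w"].values[1:]).max() < 0.05
        assert top_associations(coef)["mode_1"][0] == "w"

    def test_orthonormal_scores_give_covariance_coefficients(self):
        rng = np.random.default_rng(1)
        n = 400
        Z, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        Z = Z * np.sqrt(n - 1)  # columns: mean ~0, sd 1, exactly orthogonal
        y = 1.5 * Z[:, 1] + rng.normal(0, 0.1, n)
        cal = pd.DataFrame({"m": y})
        coef = regress_calipers_on_modes(cal, Z)
        ys = (y - y.mean()) / y.std(ddof=1)
        expected = Z.T @ ys / (n - 1)
        assert np.allclose(coef.loc["m"].values, expected, atol=5e-3)

    def test_permuted_response_gives_null_coefficients(self):
        rng = np.random.default_rng(2)
        n = 500
        Z = rng.normal(size=(n, 3))
        y = 2.0 * Z[:, 0]
        cal = pd.DataFrame({"w": rng.permutation(y)})
        coef = regress_calipers_on_modes(cal, Z)
        assert np.abs(coef.loc["w"].values).max() < 0.15

    def test_rank_deficient_design_rejected(self):
        Z = np.ones((30, 2))
        cal = pd.DataFrame({"w": np.arange(30.0)})
        with pytest.raises(ValueError, match="rank"):
            regress_calipers_on_modes(cal, Z)
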