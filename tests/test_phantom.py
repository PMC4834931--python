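import dataclasses

import numpy as np
import pytest

from pbvckit import phantom as ph


def sphere_spec(radius=60.0, **kw):
    base = dict(grid_shape=(48, 48, 48), voxel_spacing_mm=(3.0, 3.0, 3.0),
                brain_radii_mm=(radius,) * 3, gm_thickness_mm=0.0,
                ventricles=(), lesion_seeds=(), rng_seed=1,
                skull_radii_mm=(radius + 4.0,) * 3)
    base.update(kw)
    return ph.PhantomSpec(**base)


class TestAnalyticVolumes:
    def test_sphere_brain_volume_closed_form(self):
        # (4/3) pi 60^3 mm^3 = 904.78 ml
        assert sphere_spec().pv_ml == pytest.approx(904.78, abs=0.01)

    def test_lesions_do_not_change_parenchymal_volume(self):
        a = ph.preset_spec("T15")
        b = dataclasses.replace(a, lesion_seeds=())
        assert a.pv_ml == pytest.approx(b.pv_ml)
        assert a.lesion_ml > 0

    def test_default_spec_in_ms_population_range(self):
        # whole-brain volume range of the study population
        assert 891.75 <= ph.preset_spec("T15").pv_ml <= 1134.88

    def test_default_lesion_load_in_ms_population_range(self):
        assert 2.64 <= ph.preset_spec("T15").lesion_ml <= 60.96

    def test_pv_is_gm_plus_wm_plus_lesion(self):
        s = ph.preset_spec("T15")
        assert s.pv_ml == pytest.approx(s.gm_ml + s.wm_ml + s.lesion_ml)


class TestRasterization:
    def test_voxelized_volumes_match_analytic_within_boundary_bound(self,
                                                                    ms_spec):
        truth = ph.build_label_map(ms_spec)
        # bound: one supersampled voxel layer over the class boundary
        diag = np.linalg.norm(ms_spec.voxel_spacing_mm) / ms_spec.supersampling
        for cls, analytic in ((ph.GM, ms_spec.gm_ml),
                              (ph.WM, ms_spec.wm_ml),
                              (ph.LES, ms_spec.lesion_ml)):
            vox = truth.voxel_ml(cls)
            # generous ellipsoid surface-area bound (outer boundary)
            area = 6e4  # mm^2, exceeds any class interface area here
            assert abs(vox - analytic) * 1000 < area * diag

    def test_deterministic_given_spec_and_seed(self, ms_spec):
        a1, f1, _ = ph.render_session(ms_spec)
        a2, f2, _ = ph.render_session(ms_spec)
        assert np.array_equal(a1.data, a2.data)
        assert np.array_equal(f1.data, f2.data)

    def test_geometry_violation_names_component(self):
        with pytest.raises(ph.PhantomConfigError, match="lesion\\[0\\]"):
            ph.preset_spec("T15", lesion_seeds=(((0.0, 0.0, 0.0), 60.0),))


class TestAtrophy:
    def test_zero_atrophy_is_identity(self, ms_spec):
        out = ph.apply_atrophy(ms_spec, 0.0)
        assert ph.true_pbvc(ms_spec, out)[0] == pytest.approx(0.0, abs=1e-12)

    def test_minus_one_percent_scales_semi_axes_by_cube_root(self):
        s = sphere_spec(ventricles=())
        out = ph.apply_atrophy(s, -1.0, 0.0)
        ratio = np.asarray(out.brain_radii_mm) / np.asarray(s.brain_radii_mm)
        assert np.allclose(ratio, 0.99 ** (1 / 3), atol=1e-12)
        assert ph.true_pbvc(s, out)[0] == pytest.approx(-1.0, abs=1e-9)

    def test_gm_change_verified_by_supersampled_voxel_count(self):
        spec = ph.preset_spec("T15", scale=3.0)
        spec = dataclasses.replace(spec, supersampling=4)
        out = ph.apply_atrophy(spec, -0.5, -0.8)
        assert ph.true_pbvc(spec, out)[1] == pytest.approx(-0.8, abs=1e-9)
        gm_a = ph.build_label_map(spec).voxel_ml(ph.GM)
        gm_b = ph.build_label_map(out).voxel_ml(ph.GM)
        # voxel-count oracle at 4x supersampling: change agrees within the
        # rasterization jitter of one supersampled boundary layer
        assert 100 * (gm_b - gm_a) / gm_a == pytest.approx(-0.8, abs=0.25)

    def test_ventricles_kept_fixed_pv_still_exact(self):
        spec = ph.preset_spec("T15")
        out = ph.apply_atrophy(spec, -2.0)
        assert out.ventricle_ml == pytest.approx(spec.ventricle_ml)
        assert ph.true_pbvc(spec, out)[0] == pytest.approx(-2.0, abs=1e-9)

    def test_out_of_range_atrophy_rejected(self, ms_spec):
        with pytest.raises(ph.PhantomConfigError):
            ph.apply_atrophy(ms_spec, -7.0)


class TestContrastRendering:
    def test_noiseless_renders_one_intensity_per_pure_class(self,
                                                            clean_session):
        t1 = clean_session["t1"]
        truth = clean_session["truth"]
        table = ph.PRESET_CONTRAST["T15"]["t1"]
        for cls in (ph.CSF, ph.GM, ph.WM, ph.LES):
            pure = truth.fractions[cls].data > 0.999
            vals = np.unique(t1.data[pure])
            assert len(vals) == 1
            assert vals[0] == pytest.approx(table[cls])

    def test_preset_class_mean_differences_follow_tables(self, clean_spec):
        truth = ph.build_label_map(clean_spec)
        spec30 = dataclasses.replace(clean_spec, contrast_preset="T30")
        t15 = ph.render_contrast(truth, clean_spec, "t1")
        t30 = ph.render_contrast(truth, spec30, "t1")
        for cls in (ph.CSF, ph.GM, ph.WM):
            pure = truth.fractions[cls].data > 0.999
            d15 = ph.PRESET_CONTRAST["T15"]["t1"][cls]
            d30 = ph.PRESET_CONTRAST["T30"]["t1"][cls]
            assert t15.data[pure].mean() == pytest.approx(d15, abs=1e-6)
            assert t30.data[pure].mean() == pytest.approx(d30, abs=1e-6)

    def test_class_mean_ordering_survives_noise(self, ms_session):
        t1, truth = ms_session["t1"], ms_session["truth"]
        means = [t1.data[truth.fractions[c].data > 0.999].mean()
                 for c in (ph.CSF, ph.GM, ph.WM)]
        assert means[0] < means[1] < means[2]

    def test_lesions_hyperintense_on_noisy_flair(self):
        spec = ph.preset_spec("T15", scale=3.0, rng_seed=5, noise_sigma=0.05)
        _, flair, _ = ph.render_session(spec)
        truth_fl = ph.build_label_map(spec, "flair")
        wm = truth_fl.fractions[ph.WM].data > 0.999
        les = truth_fl.fractions[ph.LES].data > 0.999
        thr = flair.data[wm].mean() + 3 * flair.data[wm].std()
        assert np.all(flair.data[les] > thr)

    def test_unknown_preset_lists_valid_ones(self, clean_session):
        bad = dataclasses.replace(clean_session["spec"])
        object.__setattr__(bad, "contrast_preset", "T70")
        with pytest.raises(ph.PhantomConfigError, match="T15"):
            ph.render_contrast(clean_session["truth"], bad, "t1")


class TestSessionPairs:
    def test_same_seed_without_reposition_is_bit_identical(self, ms_spec):
        pair = ph.simulate_session_pair(ms_spec, ms_spec, reposition=False)
        assert np.array_equal(pair.t1_a.data, pair.t1_b.data)

    def test_cross_preset_pair_uses_both_acquisition_grids(self, ms_spec):
        spec_b = ph.to_preset_grid(ms_spec, "T30", scale=3.0)
        pair = ph.simulate_session_pair(ms_spec, spec_b, reposition=True)
        assert pair.t1_a.shape != pair.t1_b.shape
        ratio = (np.asarray(pair.t1_b.spacing_mm)
                 / np.asarray(pair.t1_a.spacing_mm))
        expected = (np.array([0.88, 1.19, 1.0])
                    / np.array([0.87, 1.25, 1.2]))
        assert np.allclose(ratio, expected, rtol=1e-6)

    def test_recorded_pose_is_applied(self, ms_spec):
        pair = ph.simulate_session_pair(ms_spec, ms_spec, reposition=True)
        assert not np.allclose(pair.pose_b.homogeneous(), np.eye(4))
        # rotation <= 5 deg, translation <= 5 mm per axis
        assert np.all(np.abs(pair.pose_b.rotation) <= np.deg2rad(5) + 1e-12)
        assert np.all(np.abs(pair.pose_b.translation_mm) <= 5.0 + 1e-12)

    def test_spec_json_round_trip(self, ms_spec):
        back = ph.PhantomSpec.from_json(ms_spec.to_json())
        assert back.to_json() == ms_spec.to_json()
        assert back.pv_ml == pytest.approx(ms_spec.pv_ml)
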