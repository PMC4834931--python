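import dataclasses

import numpy as np
import pytest

from pbvckit import phantom as ph
from pbvckit.grid import VolumeGrid, resample
from pbvckit.preproc import PriorSet, rigid_register
from pbvckit.segment import (LesionMask, SegmentConfig, em_segment,
                             detect_lesions, fill_lesions,
                             iterate_segmentation, tissue_volumes)


def flat_prior_volume(n, p):
    return VolumeGrid(np.full((n, 1, 1), p), (1.0, 1.0, 1.0))


@pytest.fixture(scope="module")
def two_class_mixture():
    """Seeded 1D two-population intensity sample wrapped as a volume."""
    rng = np.random.default_rng(99)
    y = np.concatenate([rng.normal(30, 5, 10000), rng.normal(70, 5, 10000)])
    n = y.size
    vol = VolumeGrid(y.reshape(n, 1, 1), (1.0, 1.0, 1.0))
    mask = flat_prior_volume(n, True)
    # flat, uninformative priors over three classes
    priors = PriorSet(flat_prior_volume(n, 1 / 3), flat_prior_volume(n, 1 / 3),
                      flat_prior_volume(n, 1 / 3))
    return vol, priors, mask


class TestEM:
    def test_two_class_mixture_means_recovered(self, two_class_mixture):
        vol, priors, mask = two_class_mixture
        _, model, trace = em_segment(vol, priors, mask)
        mus = sorted(model.means.values())
        assert mus[0] == pytest.approx(30.0, abs=0.5)
        assert mus[-1] == pytest.approx(70.0, abs=0.5)

    def test_log_likelihood_non_decreasing(self, two_class_mixture):
        vol, priors, mask = two_class_mixture
        _, _, trace = em_segment(vol, priors, mask)
        trace = np.asarray(trace)
        rel = np.diff(trace) / np.abs(trace[:-1])
        assert np.all(rel >= -1e-8)

    def test_noiseless_phantom_labels_match_truth(self, clean_session,
                                                  subject_priors):
        t1, truth = clean_session["t1"], clean_session["truth"]
        mask = truth.brain_mask
        seg, _, _ = em_segment(t1, subject_priors, mask)
        # voxels with unambiguous priors and pure tissue must be exact
        code = {1: ph.CSF, 2: ph.GM, 3: ph.WM}
        for hard, cls in code.items():
            pure = truth.fractions[cls].data > 0.999
            strong = getattr(subject_priors,
                             {1: "csf", 2: "gm", 3: "wm"}[hard]
                             + "_prior").data > 0.9
            sel = pure & strong
            if sel.any():
                assert np.all(seg.hard_labels.data[sel] == hard)

    def test_empty_mask_rejected(self, clean_session, subject_priors):
        empty = clean_session["t1"].with_data(
            np.zeros(clean_session["t1"].shape, bool))
        with pytest.raises(ValueError, match="empty mask"):
            em_segment(clean_session["t1"], subject_priors, empty)

    def test_probabilities_partition_the_mask(self, clean_session,
                                              subject_priors):
        t1, truth = clean_session["t1"], clean_session["truth"]
        seg, _, _ = em_segment(t1, subject_priors, truth.brain_mask)
        total = (seg.prob_gm.data + seg.prob_wm.data + seg.prob_csf.data
                 + seg.prob_lesion.data)
        m = truth.brain_mask.data.astype(bool)
        assert np.allclose(total[m], 1.0, atol=1e-6)
        assert np.all(total[~m] == 0.0)


@pytest.fixture(scope="module")
def noisy_pipeline_inputs(ms_session, subject_priors):
    from pbvckit.preproc import skull_strip

    t1 = ms_session["t1"]
    mask = skull_strip(t1)
    tx, _ = rigid_register(ms_session["flair"], t1)
    flair_t1 = resample(ms_session["flair"], t1, tx)
    return t1, flair_t1, mask


class TestLesions:
    def test_lesion_free_phantom_has_no_false_positives(self, subject_priors):
        vols = []
        for seed in range(5):
            spec = ph.preset_spec("T15", scale=3.0, rng_seed=seed,
                                  noise_sigma=0.05, lesion_seeds=())
            t1, flair, truth = ph.render_session(spec)
            tx, _ = rigid_register(flair, t1)
            flair_t1 = resample(flair, t1, tx)
            _, les, _, _, _ = iterate_segmentation(
                t1, flair_t1, subject_priors, truth.brain_mask)
            vols.append(les.lesion_volume_ml)
        assert np.median(vols) <= 0.1

    def test_single_lesion_detected_as_one_component(self, subject_priors):
        spec = ph.preset_spec("T15", scale=3.0, rng_seed=7, noise_sigma=0.05,
                              lesion_seeds=(((22.0, 18.0, 10.0), 8.0),))
        t1, flair, truth = ph.render_session(spec)
        tx, _ = rigid_register(flair, t1)
        flair_t1 = resample(flair, t1, tx)
        _, les, _, _, _ = iterate_segmentation(
            t1, flair_t1, subject_priors, truth.brain_mask)
        assert les.component_count == 1
        tl = truth.fractions[ph.LES].data > 0.5
        lm = np.asarray(les.mask.data, bool)
        d = 2 * np.sum(lm & tl) / (lm.sum() + tl.sum())
        assert d >= 0.7

    def test_ms_like_volume_within_thirty_percent(self, noisy_pipeline_inputs,
                                                  subject_priors, ms_session):
        t1, flair_t1, mask = noisy_pipeline_inputs
        _, les, _, _, _ = iterate_segmentation(t1, flair_t1, subject_priors,
                                               mask)
        true_ml = ms_session["truth"].lesion_ml
        assert 2.64 <= true_ml <= 60.96
        assert abs(les.lesion_volume_ml - true_ml) <= 0.3 * true_ml

    def test_filling_replaces_only_lesion_voxels(self, ms_session,
                                                 noisy_pipeline_inputs,
                                                 subject_priors):
        t1, flair_t1, mask = noisy_pipeline_inputs
        seg, model, _ = em_segment(t1, subject_priors, mask)
        les = detect_lesions(flair_t1, seg, model, subject_priors)
        filled = fill_lesions(t1, les, model, rng_seed=1)
        lm = np.asarray(les.mask.data, bool)
        assert np.array_equal(filled.data[~lm], t1.data[~lm])
        mu, sd = model.means["wm"], np.sqrt(model.variances["wm"])
        n = lm.sum()
        assert filled.data[lm].mean() == pytest.approx(
            mu, abs=2 * sd / np.sqrt(n) + 0.5)

    def test_empty_mask_fill_returns_input_object(self, ms_session):
        t1 = ms_session["t1"]
        empty = LesionMask(t1.with_data(np.zeros(t1.shape, bool)), 0.0, 0)

        class M:
            means = {"wm": 80.0}
            variances = {"wm": 4.0}

        assert fill_lesions(t1, empty, M()) is t1

    def test_refill_reclassifies_former_lesions_as_wm(
            self, noisy_pipeline_inputs, subject_priors):
        t1, flair_t1, mask = noisy_pipeline_inputs
        seg, model, _ = em_segment(t1, subject_priors, mask)
        les = detect_lesions(flair_t1, seg, model, subject_priors)
        filled = fill_lesions(t1, les, model, rng_seed=1)
        seg2, _, _ = em_segment(filled, subject_priors, mask)
        lm = np.asarray(les.mask.data, bool)
        assert np.mean(seg2.hard_labels.data[lm] == 3) >= 0.95


class TestIteration:
    def test_lesion_free_noiseless_converges_fast(self, clean_spec,
                                                  subject_priors):
        spec = dataclasses.replace(clean_spec, lesion_seeds=())
        t1, flair, truth = ph.render_session(spec)
        tx, _ = rigid_register(flair, t1)
        flair_t1 = resample(flair, t1, tx)
        _, _, _, _, info = iterate_segmentation(t1, flair_t1, subject_priors,
                                                truth.brain_mask)
        assert info["converged"]
        assert info["outer_iterations"] <= 2

    def test_parenchymal_volume_within_two_percent(self, ms_session,
                                                   noisy_pipeline_inputs,
                                                   subject_priors):
        t1, flair_t1, mask = noisy_pipeline_inputs
        seg, _, _, _, _ = iterate_segmentation(t1, flair_t1, subject_priors,
                                               mask)
        vols = tissue_volumes(seg)
        true_pv = ms_session["truth"].pv_ml
        assert vols["pv"] == pytest.approx(
            vols["gm"] + vols["wm"] + vols["lesion"])
        assert abs(vols["pv"] - true_pv) <= 0.02 * true_pv


class TestTissueVolumes:
    def test_unit_probability_volume(self):
        one = VolumeGrid(np.ones((100, 100, 100)), (1.0, 1.0, 1.0))
        zero = one.with_data(np.zeros(one.shape))
        from pbvckit.segment import Segmentation

        seg = Segmentation(prob_gm=one, prob_wm=zero, prob_csf=zero,
                           prob_lesion=zero,
                           hard_labels=one.with_data(
                               np.full(one.shape, 2, np.uint8)),
                           volumes_ml={"gm": 1000.0, "wm": 0.0, "csf": 0.0,
                                       "lesion": 0.0, "pv": 1000.0})
        assert tissue_volumes(seg)["gm"] == pytest.approx(1000.0)

    def test_volume_linearity_in_probabilities(self, clean_session,
                                               subject_priors):
        t1 = clean_session["t1"]
        mask = clean_session["truth"].brain_mask
        seg, _, _ = em_segment(t1, subject_priors, mask)
        half = seg.prob_gm.with_data(seg.prob_gm.data / 2)
        v_full = seg.prob_gm.data.sum() * t1.voxel_volume_ml
        v_half = half.data.sum() * t1.voxel_volume_ml
        assert v_half == pytest.approx(v_full / 2)
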