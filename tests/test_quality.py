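"""Image-similarity ECG grading, SQIs, and the SVD ABP pulse gate."""
import numpy as np
import pytest

from autonomiq import quality as q
from autonomiq.pipeline import default_quality_models
from autonomiq.synth import (NoiseSpec, SubjectSpec, corrupt, gen_tachogram,
                             render_waveforms)

FS = 250.0


def render_clean(seed=5, duration=12.0, n_leads=2, noise=None):
    spec = SubjectSpec(seed=seed)
    tach = gen_tachogram(spec, duration_s=duration)
    rec, _ = render_waveforms(tach, fs=FS, n_ecg_leads=n_leads)
    if noise is not None:
        rec = corrupt(rec, noise, seed=seed, roles=("ecg",))
    leads = np.array([c.samples for c in rec.by_role("ecg")])
    return q.render_ecg_image(leads, FS), rec


class TestRender:
    def test_deterministic(self):
        a, _ = render_clean(seed=1)
        b, _ = render_clean(seed=1)
        np.testing.assert_array_equal(a.strips, b.strips)

    def test_zero_signal_is_grid_only(self):
        img = q.render_ecg_image(np.zeros((1, int(10 * FS))), FS)
        grid_img = q.render_ecg_image(np.zeros((1, int(10 * FS))), FS)
        np.testing.assert_array_equal(img.strips, grid_img.strips)
        # the trace collapses onto the centre row
        H = img.strips.shape[1]
        assert np.all(img.strips[0, H // 2, :] == img.config.dynamic_range)

    def test_amplitude_doubles_vertical_extent(self):
        n = int(10 * FS)
        t = np.arange(n) / FS
        x = 0.4 * np.sin(2 * np.pi * 1.0 * t)
        img1 = q.render_ecg_image(x, FS)
        img2 = q.render_ecg_image(2 * x, FS)

        def extent(img):
            rows = np.flatnonzero((img.strips[0] == img.config.dynamic_range)
                                  .any(axis=1))
            return rows.max() - rows.min()
        assert extent(img2) == pytest.approx(2 * extent(img1), abs=3)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            q.render_ecg_image(np.empty((1, 0)), FS)


class TestSsim:
    def test_identity_on_single_lead(self):
        img, _ = render_clean(n_leads=1)
        assert q.ssim(img, img) == pytest.approx(1.0)

    def test_symmetry(self):
        a, _ = render_clean(seed=1)
        b, _ = render_clean(seed=2)
        assert q.ssim(a, b) == pytest.approx(q.ssim(b, a))

    def test_bounded(self):
        a, _ = render_clean(seed=1)
        b, _ = render_clean(seed=2, noise=NoiseSpec(white_sd=0.5))
        v = q.ssim(a, b)
        assert -1.0 <= v <= 1.0

    def test_constant_images_closed_form(self):
        x = np.full((8, 8), 2.0)
        y = np.full((8, 8), 4.0)
        c1 = (q.K1 * 1.0) ** 2
        assert q.ssim_pair(x, y) == pytest.approx((2 * 2 * 4 + c1) / (4 + 16 + c1))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            q.ssim_pair(np.zeros((4, 4)), np.zeros((5, 5)))


class TestTemplates:
    def test_cluster_representative_hand_example(self):
        # cluster {A, A, B} with SSIM(A,B)=0.5: A's mean similarity 0.833
        # beats B's 0.667, so A (lowest index on ties) is the representative
        A = q.EcgImage(np.ones((1, 4, 4)), q.RenderConfig())
        B = q.EcgImage(np.zeros((1, 4, 4)), q.RenderConfig())
        s_ab = q.ssim(A, B)
        members = [0, 1, 2]
        rep = q._cluster_representative([A, A, B], members)
        assert rep == 0
        mean_a = (1.0 + 1.0 + s_ab) / 3
        mean_b = (s_ab + s_ab + 1.0) / 3
        assert mean_a > mean_b

    def test_classifier_separates_clean_from_corrupt(self, quality_models):
        """Held-out clean/noisy images are graded with high accuracy."""
        lib, _ = quality_models
        correct = total = 0
        for seed in range(20, 30):
            img, _ = render_clean(seed=seed)
            correct += q.classify_ecg_quality(img, lib)[0] == "good"
            bad, _ = render_clean(seed=seed, noise=NoiseSpec(white_sd=0.6))
            correct += q.classify_ecg_quality(bad, lib)[0] == "poor"
            total += 2
        assert correct / total >= 0.95

    def test_training_template_maps_to_its_own_group(self, quality_models):
        lib, _ = quality_models
        for tmpl, group in zip(lib.templates, lib.template_groups):
            assert q.classify_ecg_quality(tmpl, lib)[0] == group

    def test_unfitted_library_rejected(self):
        img, _ = render_clean()
        with pytest.raises(ValueError, match="not fitted"):
            q.classify_ecg_quality(img, q.TemplateLibrary())

    def test_unsupervised_partition_separates_quality(self):
        images = [render_clean(seed=s)[0] for s in (1, 2, 3)]
        images += [render_clean(seed=s, noise=NoiseSpec(white_sd=0.8))[0]
                   for s in (4, 5, 6)]
        labels = q.partition_by_similarity(images)
        assert labels[:3] == ["good"] * 3
        assert labels[3:] == ["poor"] * 3


class TestSqis:
    def _lead(self, seed=0, noise=None):
        _, rec = render_clean(seed=seed, duration=20.0, n_leads=1, noise=noise)
        return rec.channel("II").samples

    def test_clean_ecg_has_high_bsqi(self):
        s = q.compute_sqis(self._lead(), FS)
        assert s.bsqi >= 0.95

    def test_white_noise_lowers_ssqi(self):
        rng = np.random.default_rng(0)
        clean = q.compute_sqis(self._lead(), FS)
        noise = q.compute_sqis(rng.normal(0, 1, int(20 * FS)), FS)
        assert noise.ssqi < clean.ssqi

    def test_gaussian_noise_has_near_zero_excess_kurtosis(self):
        rng = np.random.default_rng(1)
        s = q.compute_sqis(rng.normal(0, 1, int(60 * FS)), FS)
        assert abs(s.ksqi) < 0.2

    def test_constant_signal_bsqi_zero(self):
        s = q.compute_sqis(np.full(int(20 * FS), 1.0), FS)
        assert s.bsqi == 0.0

    def test_select_best_lead_prefers_clean(self):
        sqis = [q.compute_sqis(self._lead(seed=1,
                                          noise=NoiseSpec(white_sd=0.5)), FS),
                q.compute_sqis(self._lead(seed=1), FS)]
        best, combined = q.select_best_lead(sqis)
        assert best == 1
        assert all(np.isfinite(s.composite) for s in combined)

    def test_tie_breaks_to_lowest_index(self):
        s = q.compute_sqis(self._lead(), FS)
        best, _ = q.select_best_lead([s, s, s])
        assert best == 0

    def test_single_lead_selected(self):
        best, _ = q.select_best_lead([q.compute_sqis(self._lead(), FS)])
        assert best == 0

    def test_composite_monotone_in_each_sqi(self):
        base = [q.SqiVector(0.5, 0.5, 1.0), q.SqiVector(0.9, 0.5, 1.0)]
        combined = q.combine_sqis(base)
        assert combined[1].composite > combined[0].composite


class TestAbpSubspace:
    def test_reference_pulses_all_valid(self, quality_models):
        _, model = quality_models
        for p in q.make_reference_library(n=20):
            ratio, ok = q.score_abp_pulse(p, model)
            assert ok and ratio >= model.threshold

    def test_basis_orthonormal(self, quality_models):
        _, model = quality_models
        gram = model.basis @ model.basis.T
        np.testing.assert_allclose(gram, np.eye(model.rank), atol=1e-10)

    def test_rank_one_library(self):
        base = q.make_reference_library(n=1)[0]
        pulses = [c * base for c in (0.5, 1.0, 2.0, 3.0)]
        model = q.fit_abp_subspace(pulses, P=50)
        assert model.rank == 1

    def test_projection_energies_sum_to_total(self, quality_models):
        _, model = quality_models
        p = q._normalize_pulse(q.make_reference_library(n=1)[0],
                               model.pulse_len)
        coef = model.basis @ p
        sig = coef @ coef
        res = p @ p - sig
        assert sig + res == pytest.approx(p @ p)

    def test_noise_strictly_decreases_ratio_in_expectation(self, quality_models):
        _, model = quality_models
        base = q.make_reference_library(n=1)[0]
        rng = np.random.default_rng(0)
        clean_ratio = q.score_abp_pulse(base, model)[0]
        ratios = [q.score_abp_pulse(base + rng.normal(0, 5, len(base)),
                                    model)[0] for _ in range(20)]
        assert np.mean(ratios) < clean_ratio

    def test_white_noise_pulse_invalid(self, quality_models):
        _, model = quality_models
        rng = np.random.default_rng(3)
        invalid = sum(not q.score_abp_pulse(rng.normal(0, 1, 80), model)[1]
                      for _ in range(10))
        assert invalid >= 9

    def test_pulse_in_signal_subspace_valid_with_capped_ratio(self, quality_models):
        _, model = quality_models
        p = model.basis[0]  # already unit-norm, zero residual after scaling
        ratio, ok = q._energy_ratio(p, model.basis), True
        assert ratio == q.RATIO_SENTINEL and ok

    def test_too_short_pulse_rejected(self, quality_models):
        _, model = quality_models
        with pytest.raises(ValueError):
            q.score_abp_pulse(np.array([1.0, 2.0]), model)


class TestGate:
    def _segment(self, ecg_noise=None, abp_noise=None, seed=7, duration=30.0):
        spec = SubjectSpec(seed=seed)
        tach = gen_tachogram(spec, duration_s=duration)
        rec, _ = render_waveforms(tach, fs=FS)
        if ecg_noise:
            rec = corrupt(rec, ecg_noise, seed=seed, roles=("ecg",))
        if abp_noise:
            rec = corrupt(rec, abp_noise, seed=seed + 1, roles=("abp",))
        return rec

    def test_two_by_two_design(self, quality_models):
        """Only the clean/clean cell of the clean-corrupt design passes."""
        lib, sub = quality_models
        heavy_ecg = NoiseSpec(white_sd=0.6)
        heavy_abp = NoiseSpec(white_sd=25.0, burst_s=15.0, burst_amp=4.0)
        outcomes = {}
        for ecg_bad in (False, True):
            for abp_bad in (False, True):
                seg = self._segment(heavy_ecg if ecg_bad else None,
                                    heavy_abp if abp_bad else None)
                rep = q.gate_segment(seg, lib, sub)
                outcomes[(ecg_bad, abp_bad)] = rep.passed
        assert outcomes[(False, False)]
        assert not outcomes[(True, False)]
        assert not outcomes[(False, True)]
        assert not outcomes[(True, True)]

    def test_abp_only_mode_skips_ecg_criteria(self, quality_models):
        _, sub = quality_models
        seg = self._segment()
        rep = q.gate_segment(seg, None, sub, abp_only=True)
        assert rep.passed and rep.ecg_quality is None

    def test_report_serializes(self, quality_models):
        import json
        lib, sub = quality_models
        rep = q.gate_segment(self._segment(), lib, sub)
        parsed = json.loads(rep.to_json())
        assert parsed["passed"] == rep.passed


class TestTemplatePersistence:
    def test_archive_round_trip(self, quality_models, tmp_path):
        lib, _ = quality_models
        p = tmp_path / "templates.joblib"
        lib.save(p)
        back = q.TemplateLibrary.load(p)
        assert back.fitted and len(back.templates) == len(lib.templates)
        img, _ = render_clean(seed=33)
        assert q.classify_ecg_quality(img, back) == \
            q.classify_ecg_quality(img, lib)
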