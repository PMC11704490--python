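"""Variability and turbulence numerics against closed-form oracles."""
import numpy as np
import pytest

from autonomiq.hrt import HrtEvent, extract_hrt_events, hrt_onset, hrt_slope, segment_hrt
from autonomiq.hrv import lomb_psd, rmssd
from autonomiq.records import (IntervalSeries, beats_from_arrays,
                               derive_intervals)


def series_from_rr(rr_ms, t0=0.0):
    t = t0 + np.cumsum(rr_ms) / 1000.0
    return IntervalSeries(t, np.asarray(rr_ms, float))


class TestRmssd:
    def test_constant_series_is_zero(self):
        assert rmssd(series_from_rr([800.0] * 5)) == 0.0

    def test_hand_computed_value(self):
        # diffs +50, -50 -> sqrt((50^2+50^2)/2) = 50
        assert rmssd(series_from_rr([800.0, 850.0, 800.0])) == pytest.approx(50.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        rr = 800 + 30 * rng.standard_normal(50)
        assert rmssd(series_from_rr(rr)) == pytest.approx(
            rmssd(series_from_rr(rr + 123.0)), rel=1e-12)

    def test_too_few_intervals_is_missing(self):
        assert rmssd(series_from_rr([800.0, 810.0])) is None

    def test_gap_from_excluded_ectopy_breaks_adjacency(self):
        # N,N,N,V,N,N,N: dropping V-touching pairs leaves a gap; the large
        # jump across the gap must not enter the successive differences
        beats = beats_from_arrays(
            np.cumsum([0, 0.8, 0.8, 0.5, 1.1, 0.8, 0.8]),
            ["N", "N", "N", "V", "N", "N", "N"])
        iv = derive_intervals(beats)
        assert rmssd(iv) == 0.0  # all retained adjacent diffs are 800-800


class TestLombPsd:
    def _modulated(self, amp, freq, n=400, rr0=850.0, seed=0):
        rng = np.random.default_rng(seed)
        t, rr = 0.0, []
        for _ in range(n):
            v = rr0 + amp * np.sin(2 * np.pi * freq * t) + rng.normal(0, 1)
            rr.append(v)
            t += v / 1000.0
        return series_from_rr(rr)

    def test_hf_sinusoid_dominates_hf_band(self):
        res = lomb_psd(self._modulated(40.0, 0.25))
        assert res.hf_power_ms2 > 10 * res.lf_power_ms2
        assert res.lf_hf < 0.2

    def test_lf_sinusoid_dominates_lf_band(self):
        res = lomb_psd(self._modulated(40.0, 0.10))
        assert res.lf_hf > 5.0

    @pytest.mark.parametrize("freq", [0.08, 0.25, 0.33])
    def test_peak_at_generator_frequency(self, freq):
        res = lomb_psd(self._modulated(40.0, freq))
        assert abs(res.peak_hz - freq) <= 0.001 + 1e-9

    def test_near_constant_series_has_negligible_power(self):
        rng = np.random.default_rng(0)
        rr = 850.0 + 1e-6 * rng.standard_normal(200)
        res = lomb_psd(series_from_rr(rr))
        assert res.lf_power_ms2 < 1e-6 and res.hf_power_ms2 < 1e-6

    def test_total_power_approximates_variance(self):
        iv = self._modulated(30.0, 0.12, n=600, seed=3)
        res = lomb_psd(iv)
        var = np.var(iv.value_ms)
        assert res.total_power_ms2 == pytest.approx(var, rel=0.15)

    def test_short_span_is_missing(self):
        assert lomb_psd(series_from_rr([800.0] * 35)) is None  # 28 s < 2 LF periods


def make_event(pre, post, coupl=480.0, comp=1120.0, eligible=True):
    return HrtEvent(0, coupl, comp, np.asarray(pre, float),
                    np.asarray(post, float), eligible)


class TestTurbulenceOnset:
    def test_symmetric_context_is_zero(self):
        ev = make_event([800, 800], [800.0] * 15)
        assert hrt_onset(ev) == pytest.approx(0.0)

    def test_early_acceleration_is_negative(self):
        ev = make_event([800, 800], [760, 760] + [800.0] * 13)
        assert hrt_onset(ev) == pytest.approx(-5.0)

    def test_deceleration_is_positive(self):
        ev = make_event([800, 800], [840, 840] + [800.0] * 13)
        assert hrt_onset(ev) == pytest.approx(5.0)

    def test_ineligible_event_is_missing(self):
        ev = make_event([800, 800], [800.0] * 15, eligible=False)
        assert hrt_onset(ev) is None

    def test_scale_invariance(self):
        a = make_event([800, 810], [770, 780] + [800.0] * 13)
        b = make_event([1600, 1620], [1540, 1560] + [1600.0] * 13)
        assert hrt_onset(a) == pytest.approx(hrt_onset(b))


class TestTurbulenceSlope:
    def test_linear_ramp_recovers_slope(self):
        post = 800 + 10.0 * np.arange(1, 16)
        assert hrt_slope(make_event([800, 800], post)) == pytest.approx(10.0)

    def test_constant_post_series_is_zero(self):
        assert hrt_slope(make_event([800, 800], [800.0] * 15)) == pytest.approx(0.0)

    def test_monotone_decrease_gives_negative_slope(self):
        post = 800 - 5.0 * np.arange(1, 16)
        assert hrt_slope(make_event([800, 800], post)) == pytest.approx(-5.0)

    def test_scales_linearly_with_rr(self):
        post = 800 + 7.0 * np.arange(1, 16)
        s1 = hrt_slope(make_event([800, 800], post))
        s2 = hrt_slope(make_event([1600, 1600], 2 * post))
        assert s2 == pytest.approx(2 * s1)

    def test_insufficient_post_context_is_missing(self):
        assert hrt_slope(make_event([800, 800], [800.0] * 14)) is None


def single_pvc_beats(n_pre_beats=3, n_post=15, rr=800.0, coupling=0.6):
    """Beat series with one PVC: n_pre_beats sinus beats, the ectopic,
    the compensatory-terminating beat, then n_post further sinus beats."""
    rrs = [rr] * (n_pre_beats - 1)
    rrs.append(coupling * rr)          # coupling interval
    rrs.append((2 - coupling) * rr)    # compensatory interval
    rrs += [rr] * n_post
    labels = ["N"] * n_pre_beats + ["V"] + ["N"] * (n_post + 1)
    return beats_from_arrays(np.cumsum([0.0] + rrs) / 1000.0, labels)


class TestEventExtraction:
    def test_valid_single_pvc_event(self):
        evs = extract_hrt_events(single_pvc_beats())
        assert len(evs) == 1 and evs[0].eligible
        assert evs[0].coupl_ms == pytest.approx(480.0)
        assert evs[0].comp_ms == pytest.approx(1120.0)

    @pytest.mark.parametrize("m,expect", [(14, False), (15, True), (20, True)])
    def test_post_context_requirement(self, m, expect):
        evs = extract_hrt_events(single_pvc_beats(n_post=m))
        assert evs[0].eligible is expect

    def test_non_premature_coupling_rejected(self):
        evs = extract_hrt_events(single_pvc_beats(coupling=1.05))
        assert not evs[0].eligible


class TestSegmentHrt:
    def _beats_with_k_pvcs(self, k, rr=850.0):
        rrs, labels = [0.0], ["N"]
        for _ in range(k):
            rrs += [rr] * 4 + [0.6 * rr, 1.4 * rr] + [rr] * 16
            labels += ["N"] * 4 + ["V"] + ["N"] * 17
        return beats_from_arrays(np.cumsum(rrs) / 1000.0, labels[:len(rrs)])

    def test_ten_pvcs_is_skipped(self):
        assert segment_hrt(self._beats_with_k_pvcs(10)).status == "skipped"

    def test_eleven_pvcs_is_computed(self):
        s = segment_hrt(self._beats_with_k_pvcs(11))
        assert s.status == "computed" and s.n_events == 11

    def test_identical_events_mean_equals_event_value(self):
        s = segment_hrt(self._beats_with_k_pvcs(11))
        ev = extract_hrt_events(self._beats_with_k_pvcs(11))[0]
        assert s.mean_to_pct == pytest.approx(hrt_onset(ev), abs=1e-9)
        assert s.mean_ts_ms_per_beat == pytest.approx(hrt_slope(ev), abs=1e-9)

    def test_ineligible_events_excluded_from_mean(self):
        beats = self._beats_with_k_pvcs(12)
        # spoil the post context of the last 4 PVCs with unclassified beats
        lab = beats.labels.copy()
        for v in np.flatnonzero(lab == "V")[-4:]:
            lab[v + 10] = "X"
        spoiled = beats_from_arrays(beats.times_s, lab)
        s = segment_hrt(spoiled)
        assert s.n_pvc == 12 and s.n_events == 8

    def test_prv_equals_hrv_on_identical_series(self):
        """PPI-based indices equal RR-based ones on an identical series."""
        rng = np.random.default_rng(5)
        rr = 850 + 20 * rng.standard_normal(200)
        t = np.cumsum(rr) / 1000.0
        as_rr = IntervalSeries(t, rr, kind="RR")
        as_ppi = IntervalSeries(t, rr, kind="PPI")
        assert rmssd(as_rr) == pytest.approx(rmssd(as_ppi), rel=1e-12)
        r1, r2 = lomb_psd(as_rr), lomb_psd(as_ppi)
        assert r1.lf_power_ms2 == pytest.approx(r2.lf_power_ms2, rel=1e-12)


class TestStrictMode:
    def test_marginal_prematurity_rejected_only_in_strict_mode(self):
        beats = single_pvc_beats(coupling=0.9)  # premature but not by 20%
        assert extract_hrt_events(beats)[0].eligible
        assert not extract_hrt_events(beats, strict=True)[0].eligible

    def test_clearly_premature_event_passes_strict(self):
        beats = single_pvc_beats(coupling=0.6)
        assert extract_hrt_events(beats, strict=True)[0].eligible
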