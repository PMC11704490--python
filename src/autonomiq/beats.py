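"""Beat detection on ECG and ABP, rule-based PVC labelling, and metrics.

The R-peak detector follows a four-step pipeline: 2-s sliding windows,
0.5-17 Hz band-pass, an enhancement mask (a zero-sum kernel of -1 flanks
around a +2k centre, half-width k samples) that sharpens the QRS upstroke,
min-max normalization per window, then fiducial search over 0.3-s ranges
with a normalized amplitude threshold of 0.5 and R-peak refinement within
a 0.24-s interval centred at the fiducial. A 0.2-s refractory period
deduplicates beats across overlapping windows.

PVC labelling is two-stage and purely rule-based: stage 1 flags beats that
meet at least two of {QRS width > 120 ms, amplitude > 1.5x the median
beat, correlation with the median beat < 0.9}; stage 2 demotes a solitary
candidate that still resembles the median beat, and for multiple
candidates keeps only those whose morphology deviation exceeds the median
deviation and whose width at three-fourths the height of the smallest
candidate exceeds the mean such width. An external segment classifier can
be plugged in to pre-select which segments are scanned at all.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .records import BeatSeries

REFRACTORY_S = 0.2
SEARCH_RANGE_S = 0.3
R_WINDOW_S = 0.24
NORM_THRESHOLD = 0.5  # on the min-max normalized enhanced signal


def enhancement_mask(k: int) -> np.ndarray:
    """Zero-sum QRS enhancement kernel: -1 flanks, +2k centre, length 2k+1."""
    m = -np.ones(2 * k + 1)
    m[k] = 2.0 * k
    return m


def bandpass(x: np.ndarray, fs: float, lo: float = 0.5, hi: float = 17.0,
             order: int = 3) -> np.ndarray:
    sos = signal.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_r_peaks(ecg: np.ndarray, fs: float,
                   k: int | None = None,
                   window_s: float = 2.0,
                   hop_s: float = 1.0) -> BeatSeries:
    """R-peak detection; returns strictly increasing sinus-labelled beats."""
    x = np.asarray(ecg, float)
    if fs < 100:
        raise ValueError(f"sampling rate {fs} Hz too low for QRS detection (>=100)")
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if k is None:
        k = max(int(round(0.05 * fs)), 1)
    filt = bandpass(x, fs)
    enh = np.convolve(filt, enhancement_mask(k)[::-1], mode="same")
    win = int(window_s * fs)
    hop = int(hop_s * fs)
    rng_len = int(SEARCH_RANGE_S * fs)
    half_r = int(R_WINDOW_S * fs / 2)
    cands: list[tuple[int, float]] = []
    for a in range(0, max(len(x) - win, 0) + 1, hop):
        seg = enh[a:a + win]
        lo_v, hi_v = seg.min(), seg.max()
        if hi_v - lo_v <= 1e-12:
            continue  # all-constant window
        norm = (seg - lo_v) / (hi_v - lo_v)
        for r0 in range(0, len(seg), rng_len):
            sub = norm[r0:r0 + rng_len]
            if len(sub) == 0 or sub.max() < NORM_THRESHOLD:
                continue
            fid = a + r0 + int(np.argmax(sub))
            j0, j1 = max(fid - half_r, 0), min(fid + half_r + 1, len(x))
            w = filt[j0:j1]
            peak = j0 + (int(np.argmax(w)) if w.max() >= -w.min()
                         else int(np.argmin(w)))
            cands.append((peak, abs(enh[peak])))
    if not cands:
        return BeatSeries(np.empty(0), np.empty(0, dtype="<U1"))
    cands.sort()
    refr = int(REFRACTORY_S * fs)
    kept: list[tuple[int, float]] = []
    for s, amp in cands:
        if kept and s - kept[-1][0] < refr:
            if amp > kept[-1][1]:
                kept[-1] = (s, amp)
        else:
            kept.append((s, amp))
    times = np.array([s / fs for s, _ in kept])
    return BeatSeries(times, np.full(len(times), "N", dtype="<U1"))


def detect_systolic_peaks(abp: np.ndarray, fs: float,
                          smooth_s: float = 0.2, polyorder: int = 3,
                          refractory_s: float = 0.3,
                          min_range: float = 5.0) -> BeatSeries:
    """Systolic peaks on ABP: Savitzky-Golay smoothing then windowed maxima.

    Returns ABP-sourced beats carrying the smoothed systolic amplitude in
    input units. A non-pulsatile signal (range below ``min_range``) yields
    an empty series.
    """
    x = np.asarray(abp, float)
    if fs < 50:
        raise ValueError(f"sampling rate {fs} Hz too low for pulse detection")
    if np.ptp(x) < min_range:
        return BeatSeries(np.empty(0), np.empty(0, dtype="<U1"), source="abp",
                          sbp_mmHg=np.empty(0))
    wl = int(smooth_s * fs)
    wl = wl + 1 if wl % 2 == 0 else wl
    wl = max(wl, polyorder + 2 + ((polyorder + 2) % 2 == 0))
    sm = signal.savgol_filter(x, wl, polyorder)
    prom = 0.25 * np.ptp(sm)
    peaks, _ = signal.find_peaks(sm, distance=max(int(refractory_s * fs), 1),
                                 prominence=prom)
    return BeatSeries(peaks / fs, np.full(len(peaks), "N", dtype="<U1"),
                      source="abp", sbp_mmHg=sm[peaks])


def detect_pulse_onsets(abp: np.ndarray, fs: float,
                        peaks: BeatSeries | None = None,
                        lookback_s: float = 0.5) -> np.ndarray:
    """Pulse onsets: the minimum preceding each systolic peak within 0.5 s."""
    x = np.asarray(abp, float)
    if peaks is None:
        peaks = detect_systolic_peaks(x, fs)
    onsets = []
    for tp in peaks.times_s:
        i1 = int(tp * fs)
        i0 = max(i1 - int(lookback_s * fs), 0)
        if i1 <= i0:
            continue
        onsets.append((i0 + int(np.argmin(x[i0:i1]))) / fs)
    return np.asarray(onsets)


def extract_pulses(abp: np.ndarray, fs: float,
                   onsets: np.ndarray) -> list[np.ndarray]:
    """Slice the ABP trace into per-pulse segments between onsets."""
    idx = (np.asarray(onsets) * fs).round().astype(int)
    return [abp[i0:i1] for i0, i1 in zip(idx[:-1], idx[1:]) if i1 - i0 >= 3]


# ------------------------------------------------------------ PVC labelling

@dataclass(frozen=True)
class PvcCandidate:
    beat_index: int
    width_ms: float
    amplitude: float
    deviation: float        # 1 - correlation with the median beat
    cw_ms: float = float("nan")


def _beat_windows(x: np.ndarray, fs: float, times: np.ndarray,
                  half_s: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    half = int(half_s * fs)
    n = len(x)
    wins = np.full((len(times), 2 * half + 1), np.nan)
    ok = np.zeros(len(times), bool)
    for b, t in enumerate(times):
        c = int(round(t * fs))
        if c - half < 0 or c + half + 1 > n:
            continue
        wins[b] = x[c - half:c + half + 1]
        ok[b] = True
    return wins, ok


def _width_at(w: np.ndarray, fs: float, level: float) -> float:
    """Contiguous width (ms) around the window centre where |x - baseline|
    exceeds ``level``."""
    base = np.median(w)
    dev = np.abs(w - base)
    c = len(w) // 2
    c = c - 1 + int(np.argmax(dev[max(c - 1, 0):c + 2]))  # snap to local max
    if dev[c] <= level:
        return 0.0
    left = c
    while left > 0 and dev[left - 1] > level:
        left -= 1
    right = c
    while right < len(w) - 1 and dev[right + 1] > level:
        right += 1
    return (right - left + 1) / fs * 1000.0


def detect_pvc(ecg: np.ndarray, fs: float, beats: BeatSeries,
               width_threshold_ms: float = 120.0,
               amp_factor: float = 1.5,
               corr_threshold: float = 0.9,
               segment_classifier: Callable[[np.ndarray, float], bool] | None = None,
               ) -> BeatSeries:
    """Two-stage rule-based PVC labelling of detected beats.

    With fewer than 10 beats no stable median template exists and all
    labels are X. ``segment_classifier(ecg, fs) -> bool`` may veto the scan
    entirely (segment declared PVC-free); by default every segment is
    scanned.
    """
    x = bandpass(np.asarray(ecg, float), fs, 0.5, 40.0)
    t = beats.times_s
    if len(t) < 10:
        return BeatSeries(t, np.full(len(t), "X", dtype="<U1"))
    labels = np.full(len(t), "N", dtype="<U1")
    if segment_classifier is not None and not segment_classifier(ecg, fs):
        return BeatSeries(t, labels)
    wins, ok = _beat_windows(x, fs, t)
    valid = np.flatnonzero(ok)
    if len(valid) < 10:
        return BeatSeries(t, np.full(len(t), "X", dtype="<U1"))
    template = np.median(wins[valid], axis=0)
    tmpl_amp = np.max(np.abs(template - np.median(template)))

    feats: dict[int, PvcCandidate] = {}
    for b in valid:
        w = wins[b]
        base = np.median(w)
        amp = float(np.max(np.abs(w - base)))
        width = _width_at(w, fs, 0.5 * amp)
        r = float(np.corrcoef(w, template)[0, 1]) if np.std(w) > 0 else 0.0
        feats[b] = PvcCandidate(b, width, amp, 1.0 - r)

    med_amp = float(np.median([f.amplitude for f in feats.values()]))
    cands = [f for f in feats.values()
             if ((f.width_ms > width_threshold_ms)
                 + (f.amplitude > amp_factor * max(med_amp, 1e-12))
                 + (f.deviation > 1.0 - corr_threshold)) >= 2]
    if not cands:
        return BeatSeries(t, labels)
    if len(cands) == 1:
        c = cands[0]
        if 1.0 - c.deviation >= corr_threshold:
            return BeatSeries(t, labels)  # solitary look-alike: demoted
        labels[c.beat_index] = "V"
        return BeatSeries(t, labels)
    # stage 2: widths at 3/4 the height of the smallest candidate, compared
    # against the full beat population so a run of similar ectopics survives
    ref_level = 0.75 * min(c.amplitude for c in cands)
    cw_all = {b: _width_at(wins[b], fs, ref_level) for b in valid}
    mean_cw = float(np.mean(list(cw_all.values())))
    med_dev = float(np.median([f.deviation for f in feats.values()]))
    for c in cands:
        if c.deviation > med_dev and cw_all[c.beat_index] > mean_cw:
            labels[c.beat_index] = "V"
    return BeatSeries(t, labels)


# ----------------------------------------------------------------- metrics

@dataclass(frozen=True)
class DetectionMetrics:
    sen: float
    spec: float
    acc: float
    f1: float
    tp: int
    fn: int
    fp: int
    tn: int


def _match_beats(pred_t: np.ndarray, true_t: np.ndarray,
                 tol_s: float) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour one-to-one matching within tolerance."""
    pairs = []
    used = np.zeros(len(pred_t), bool)
    for i, tt in enumerate(true_t):
        if len(pred_t) == 0:
            break
        d = np.abs(pred_t - tt)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            pairs.append((i, j))
            used[j] = True
    return pairs


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> DetectionMetrics:
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spc = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / (tp + tn + fp + fn) if tp + tn + fp + fn else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return DetectionMetrics(sen, spc, acc, f1, tp, fn, fp, tn)


def detection_metrics(pred: BeatSeries, truth: BeatSeries,
                      positive: str = "V",
                      tol_s: float = 0.150) -> DetectionMetrics:
    """Beat-level Sen/Spec/Acc/F1 with matching within 150 ms.

    Positive class defaults to the PVC label. A predicted positive with no
    matching true beat counts as a false positive; an unmatched true
    positive as a false negative.
    """
    pairs = _match_beats(pred.times_s, truth.times_s, tol_s)
    matched_true = {i for i, _ in pairs}
    matched_pred = {j for _, j in pairs}
    tp = fn = tn = fp = 0
    for i, j in pairs:
        t_pos = truth.labels[i] == positive
        p_pos = pred.labels[j] == positive
        tp += t_pos and p_pos
        fn += t_pos and not p_pos
        fp += (not t_pos) and p_pos
        tn += (not t_pos) and (not p_pos)
    for i in range(len(truth)):
        if i not in matched_true and truth.labels[i] == positive:
            fn += 1
    for j in range(len(pred)):
        if j not in matched_pred and pred.labels[j] == positive:
            fp += 1
    return metrics_from_confusion(tp, fn, fp, tn)


def beat_sensitivity(pred: BeatSeries, truth: BeatSeries,
                     tol_s: float = 0.150) -> float:
    """Fraction of true beats (any label) matched by a detection."""
    pairs = _match_beats(pred.times_s, truth.times_s, tol_s)
    return len(pairs) / len(truth) if len(truth) else float("nan")


def amplitude_threshold_detector(ecg: np.ndarray, fs: float,
                                 frac: float = 0.6,
                                 refractory_s: float = 0.25) -> BeatSeries:
    """Simple second detector for the consensus quality index: band-passed
    absolute amplitude over a fixed fraction of its 98th percentile."""
    x = bandpass(np.asarray(ecg, float), fs)
    a = np.abs(x)
    thr = frac * np.percentile(a, 98)
    if thr <= 0:
        return BeatSeries(np.empty(0), np.empty(0, dtype="<U1"))
    peaks, _ = signal.find_peaks(a, height=thr,
                                 distance=max(int(refractory_s * fs), 1))
    return BeatSeries(peaks / fs, np.full(len(peaks), "N", dtype="<U1"))
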