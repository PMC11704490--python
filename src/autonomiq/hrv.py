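"""Time- and frequency-domain variability of beat-interval series.

RMSSD is the root mean square of successive differences of sinus
inter-beat intervals; because intervals adjacent to ectopic beats are
excluded upstream, successive differences are only taken across pairs of
intervals that are truly contiguous in time (a gap breaks adjacency).

Spectral analysis uses the Lomb-Scargle periodogram, which operates
directly on the unevenly sampled tachogram without resampling. The PSD is
scaled so that integrating it over frequency recovers the series variance
(ms^2), which makes LF/HF band powers comparable with conventional HRV
reports.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .records import IntervalSeries

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: HF power below this (ms^2) makes LF/HF numerically meaningless
MIN_HF_POWER_MS2 = 1e-6


def rmssd(intervals: IntervalSeries, adjacency_tol_ms: float = 0.5) -> float | None:
    """RMSSD (ms) over temporally adjacent interval pairs.

    Two successive entries are adjacent when the later interval starts at
    the beat that terminates the earlier one, i.e. the time step between
    their terminating beats equals the later interval's own length.
    Returns None (missing) with fewer than 3 intervals or no adjacent pair.
    """
    if len(intervals) < 3:
        return None
    v = intervals.value_ms
    dt_ms = np.diff(intervals.t_s) * 1000.0
    adjacent = np.abs(dt_ms - v[1:]) <= adjacency_tol_ms
    d = np.diff(v)[adjacent]
    if len(d) == 0:
        return None
    return float(np.sqrt(np.mean(d**2)))


@dataclass(frozen=True)
class SpectralResult:
    freq_hz: np.ndarray
    psd_ms2_hz: np.ndarray
    lf_power_ms2: float
    hf_power_ms2: float
    lf_hf: float | None
    total_power_ms2: float

    @property
    def peak_hz(self) -> float:
        return float(self.freq_hz[np.argmax(self.psd_ms2_hz)])


def _band_power(f: np.ndarray, psd: np.ndarray, lo: float, hi: float,
                closed_hi: bool = False) -> float:
    m = (f >= lo) & ((f <= hi) if closed_hi else (f < hi))
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], f[m]))


def lomb_psd(
    intervals: IntervalSeries,
    f_lo: float = 0.003,
    f_hi: float = 0.5,
    df: float = 0.001,
    min_intervals: int = 30,
) -> SpectralResult | None:
    """Lomb-Scargle PSD of a beat-interval series with LF/HF band powers.

    Requires at least ``min_intervals`` intervals spanning two LF periods
    (50 s); otherwise the result is missing. The raw periodogram is scaled
    by 2/f_mean (f_mean = mean beat rate) so the integral over the full
    grid approximates the interval variance.
    """
    n = len(intervals)
    if n < min_intervals:
        return None
    t = intervals.t_s
    span = t[-1] - t[0]
    if span < 2.0 / LF_BAND[0]:
        return None
    y = intervals.value_ms - np.mean(intervals.value_ms)
    f = np.arange(f_lo, f_hi + df / 2, df)
    pgram = lombscargle(t, y, 2 * np.pi * f)
    f_mean = n / span
    psd = 2.0 * pgram / f_mean
    lf = _band_power(f, psd, *LF_BAND)
    hf = _band_power(f, psd, *HF_BAND, closed_hi=True)
    total = _band_power(f, psd, f_lo, f_hi, closed_hi=True)
    lf_hf = (lf / hf) if hf >= MIN_HF_POWER_MS2 else None
    return SpectralResult(f, psd, lf, hf, lf_hf, total)
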