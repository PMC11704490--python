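"""Baroreflex sensitivity estimators and PRV-BPV coherence.

Two BRS estimators are provided:

* PRSA — phase-rectified signal averaging. Beats at which systolic
  pressure rises above its predecessor are anchor points; RR intervals in
  a window of L beats on either side of every anchor are averaged into a
  profile X(l), and BRS is the quarter-sum (X0 + X1 - X-1 - X-2)/4, i.e.
  the central slope of the averaged RR response to a pressure increase.
* ARX spectral gain — an autoregressive model with exogenous systolic
  pressure input is fit by least squares, and the LF-band (0.04-0.15 Hz)
  ratio of the model RR spectrum to the pressure spectrum gives the gain
  index alpha_LF. The ratio of spectral densities is reported as-is (units
  ms^2/mmHg^2); the conventional alpha index is its square root, reported
  alongside.

Coherence between pulse-rate variability and blood-pressure variability is
Welch magnitude-squared coherence on cubic-interpolated 4-Hz series.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .hrv import HF_BAND, LF_BAND
from .records import BeatSeries, IntervalSeries, derive_intervals


@dataclass(frozen=True)
class PrsaResult:
    n_anchors: int
    profile_ms: np.ndarray      # X(l), l = -L..L
    offsets: np.ndarray
    brs: float                  # quarter-sum central slope, ms per anchor step


@dataclass(frozen=True)
class ArxModel:
    order: int
    a: np.ndarray               # AR coefficients a_1..a_N
    b: np.ndarray               # exogenous coefficients b_0..b_N
    sigma2_e: float
    stable: bool


@dataclass(frozen=True)
class ArxResult:
    alpha_lf: float             # LF-band mean of P_RR / P_BP (as printed)
    alpha_lf_sqrt: float        # classical alpha index (square root)
    model: ArxModel


@dataclass(frozen=True)
class CoherenceResult:
    freq_hz: np.ndarray
    coherence: np.ndarray
    lf_mean: float
    hf_mean: float


def prsa_brs(rr: IntervalSeries, L: int = 15) -> PrsaResult | None:
    """PRSA baroreflex sensitivity from an RR series with paired sBP.

    Anchors are beats whose paired sBP strictly exceeds the previous
    beat's; anchors within L beats of either edge are excluded so every
    offset l in [-L, L] exists. Returns None when no usable anchor exists.
    """
    if rr.paired_sbp_mmHg is None:
        raise ValueError("PRSA requires RR intervals with paired sBP")
    n = len(rr)
    if n < 2 * L + 1:
        return None
    sbp = rr.paired_sbp_mmHg
    v = rr.value_ms
    rises = np.flatnonzero(np.diff(sbp) > 0) + 1
    anchors = rises[(rises >= L) & (rises <= n - 1 - L)]
    if len(anchors) == 0:
        return None
    offsets = np.arange(-L, L + 1)
    windows = v[anchors[:, None] + offsets[None, :]]
    profile = windows.mean(axis=0)
    x0, x1 = profile[L], profile[L + 1]
    xm1, xm2 = profile[L - 1], profile[L - 2]
    return PrsaResult(len(anchors), profile, offsets,
                      float(0.25 * (x0 + x1 - xm1 - xm2)))


def write_prsa_profile(result: PrsaResult, path) -> None:
    """Dump the averaged PRSA profile as CSV columns (l, X(l))."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["l", "x_l_ms"])
        for off, x in zip(result.offsets, result.profile_ms):
            w.writerow([int(off), float(x)])


def _fit_arx(rr: np.ndarray, sbp: np.ndarray, order: int) -> ArxModel:
    n = len(rr)
    rows = n - order
    cols = []
    for i in range(1, order + 1):
        cols.append(rr[order - i:n - i])
    for j in range(0, order + 1):
        cols.append(sbp[order - j:n - j])
    X = np.column_stack(cols)
    y = rr[order:]
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    a = theta[:order]
    b = theta[order:]
    resid = y - X @ theta
    dof = max(rows - len(theta), 1)
    sigma2 = float(resid @ resid / dof)
    ar_poly = np.concatenate(([1.0], -a))
    roots = np.roots(ar_poly) if order > 0 else np.empty(0)
    stable = bool(np.all(np.abs(roots) < 1.0)) if order > 0 else True
    return ArxModel(order, a, b, sigma2, stable)


def select_arx_order(rr_ms: np.ndarray, sbp_mmHg: np.ndarray,
                     candidates: range = range(2, 13)) -> int:
    """Model order minimizing AIC over candidate orders."""
    rr = np.asarray(rr_ms, float)
    rr = rr - rr.mean()
    sbp = np.asarray(sbp_mmHg, float)
    sbp = sbp - sbp.mean()
    best, best_aic = None, np.inf
    for n in candidates:
        if len(rr) < 10 * n:
            continue
        m = _fit_arx(rr, sbp, n)
        n_obs = len(rr) - n
        aic = n_obs * np.log(max(m.sigma2_e, 1e-300)) + 2 * (2 * n + 1)
        if aic < best_aic:
            best, best_aic = n, aic
    if best is None:
        raise ValueError("series too short for any candidate order")
    return best


def arx_brs(
    rr_ms: np.ndarray,
    sbp_mmHg: np.ndarray,
    order: int | str = 8,
    fs_hz: float | None = None,
    alpha_sqrt: bool = True,
) -> ArxResult | None:
    """LF-band spectral gain of the RR<-sBP transfer path.

    Both series are beat-indexed; the effective sampling rate defaults to
    the mean beat rate implied by the RR values. The model RR spectrum is
    |H(f)|^2 P_BP(f) plus the innovation spectrum shaped by 1/A(f); P_BP
    is the Welch estimate of the pressure series. Returns None for
    degenerate input (zero pressure variance, series too short) or an
    unstable AR fit.
    """
    rr = np.asarray(rr_ms, float)
    sbp = np.asarray(sbp_mmHg, float)
    if len(rr) != len(sbp):
        raise ValueError("RR and sBP series must have equal length")
    if order == "aic":
        order = select_arx_order(rr, sbp)
    n = len(rr)
    if n < 10 * order:
        return None
    if np.std(sbp) == 0:
        raise ValueError("sBP series has zero variance (degenerate input)")
    rr = rr - rr.mean()
    mean_rr_s = float(np.mean(rr_ms)) / 1000.0
    fs = fs_hz if fs_hz is not None else 1.0 / mean_rr_s
    sbp0 = sbp - sbp.mean()
    model = _fit_arx(rr, sbp0, order)
    if not model.stable:
        return None
    f_bp, p_bp = signal.welch(sbp0, fs=fs, nperseg=min(256, n))
    band = (f_bp >= LF_BAND[0]) & (f_bp < LF_BAND[1]) & (p_bp > 0)
    if band.sum() < 2:
        return None
    w = 2 * np.pi * f_bp[band] / fs
    z = np.exp(-1j * w)
    # A(z) = 1 - sum a_i z^-i and B(z) = sum b_j z^-j evaluated on the band
    A = 1.0 - sum(model.a[i - 1] * z**i for i in range(1, order + 1))
    B = sum(model.b[j] * z**j for j in range(0, order + 1))
    H2 = np.abs(B / A) ** 2
    p_e = 2.0 * model.sigma2_e / fs / np.abs(A) ** 2  # one-sided density
    p_rr_model = H2 * p_bp[band] + p_e
    ratio = float(np.mean(p_rr_model / p_bp[band]))
    return ArxResult(ratio, float(np.sqrt(ratio)) if alpha_sqrt else float("nan"),
                     model)


def prv_bpv_coherence(
    abp_beats: BeatSeries,
    fs_resample: float = 4.0,
    gauss_cutoff_hz: float = 10.0,
    seg_len_s: float = 120.0,
    min_duration_s: float = 300.0,
) -> CoherenceResult | None:
    """Magnitude-squared coherence between PPI and sBP variability.

    Both beat-domain series are cubic-interpolated onto a uniform grid,
    lightly smoothed with a Gaussian kernel whose -3 dB point is
    ``gauss_cutoff_hz`` on the continuous representation, and passed to
    Welch coherence (Hann window, 50% overlap). Requires at least
    ``min_duration_s`` of beats.
    """
    if abp_beats.sbp_mmHg is None:
        raise ValueError("coherence requires ABP beats with sBP values")
    ppi = derive_intervals(abp_beats, kind="PPI")
    if len(ppi) < 10 or (ppi.t_s[-1] - ppi.t_s[0]) < min_duration_s:
        return None
    t0, t1 = ppi.t_s[0], ppi.t_s[-1]
    grid = np.arange(t0, t1, 1.0 / fs_resample)
    x = CubicSpline(ppi.t_s, ppi.value_ms)(grid)
    sbp_t = abp_beats.times_s
    sbp_v = abp_beats.sbp_mmHg
    y = CubicSpline(sbp_t, sbp_v)(np.clip(grid, sbp_t[0], sbp_t[-1]))
    # Gaussian with -3 dB at f3: sigma_t = sqrt(ln 2) / (2 pi f3)
    sigma = np.sqrt(np.log(2.0)) / (2 * np.pi * gauss_cutoff_hz) * fs_resample
    x = gaussian_filter1d(x, sigma)
    y = gaussian_filter1d(y, sigma)
    nperseg = int(seg_len_s * fs_resample)
    nperseg = min(nperseg, len(grid))
    f, coh = signal.coherence(x, y, fs=fs_resample, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2)
    lf = (f >= LF_BAND[0]) & (f < LF_BAND[1])
    hf = (f >= HF_BAND[0]) & (f <= HF_BAND[1])
    return CoherenceResult(f, coh,
                           float(np.mean(coh[lf])) if lf.any() else float("nan"),
                           float(np.mean(coh[hf])) if hf.any() else float("nan"))
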