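"""Segment quality gating: ECG image-similarity grading, SQI lead
selection, and SVD subspace validation of ABP pulses.

ECG quality mimics a clinician's glance at a paper strip: leads are
rastered in the standard paper-ECG layout (25 mm/s, 10 mm/mV) over a
millimetre grid, compared to good/poor template images by the structural
similarity index (global statistics form)

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 cov_xy + C2) /
                 ((mu_x^2 + mu_y^2 + C1)(sd_x^2 + sd_y^2 + C2)),

and graded by a linear-discriminant classifier over the SSIM-to-template
feature vector. Templates come from agglomerative clustering (average
linkage on 1 - SSIM) within each quality group; each cluster is
represented by the member with maximal mean SSIM to the others.

ABP pulses are spline-resampled to a fixed length, standardized, and
scored by the ratio of their energy inside an SVD signal subspace (fit on
a reference pulse library) to the residual energy; the validity threshold
is the minimum ratio attained by the reference pulses themselves.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import squareform
from scipy.stats import kurtosis
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .beats import amplitude_threshold_detector, detect_r_peaks
from .records import WaveformRecord

# standard SSIM stabilizing constants (relative to dynamic range L)
K1, K2 = 0.01, 0.03


@dataclass(frozen=True)
class RenderConfig:
    mm_per_s: float = 25.0
    mm_per_mV: float = 10.0
    px_per_mm: int = 4
    strip_height_mm: float = 30.0
    duration_s: float = 10.0
    dynamic_range: float = 1.0  # grayscale levels span [0, L]


@dataclass(frozen=True)
class EcgImage:
    """Rastered multi-lead ECG: per-lead strips plus the stacked image."""

    strips: np.ndarray  # (M, H, W) grayscale in [0, L]
    config: RenderConfig

    @property
    def n_leads(self) -> int:
        return self.strips.shape[0]

    @property
    def image(self) -> np.ndarray:
        return self.strips.reshape(-1, self.strips.shape[2])

    def save_png(self, path: str | Path) -> Path:
        from PIL import Image
        arr = (255 * np.clip(self.image / self.config.dynamic_range, 0, 1))
        Image.fromarray(arr.astype(np.uint8)).save(path)
        return Path(path)


def render_ecg_image(leads: np.ndarray, fs: float,
                     config: RenderConfig | None = None) -> EcgImage:
    """Deterministic raster of one or more ECG leads on a paper-ECG grid.

    ``leads`` is (M, n) or (n,). The grid (1 mm light, 5 mm heavy) is drawn
    first and the trace overlaid at full intensity; amplitudes beyond the
    strip are clipped.
    """
    cfg = config or RenderConfig()
    leads = np.atleast_2d(np.asarray(leads, float))
    if leads.shape[1] == 0:
        raise ValueError("empty segment")
    H = int(cfg.strip_height_mm * cfg.px_per_mm)
    W = int(cfg.duration_s * cfg.mm_per_s * cfg.px_per_mm)
    L = cfg.dynamic_range
    grid = np.zeros((H, W))
    step = cfg.px_per_mm
    grid[::step, :] = 0.25 * L
    grid[:, ::step] = 0.25 * L
    grid[::5 * step, :] = 0.5 * L
    grid[:, ::5 * step] = 0.5 * L
    n_need = int(cfg.duration_s * fs)
    strips = np.empty((leads.shape[0], H, W))
    px_per_sample = cfg.mm_per_s * cfg.px_per_mm / fs
    amp_px = cfg.mm_per_mV * cfg.px_per_mm
    mid = H // 2
    for m, lead in enumerate(leads):
        x = lead[:n_need]
        img = grid.copy()
        cols = np.minimum((np.arange(len(x)) * px_per_sample).astype(int), W - 1)
        rows = np.clip(mid - np.round(x * amp_px).astype(int), 0, H - 1)
        # connect consecutive samples vertically so the trace is contiguous
        for i in range(len(x)):
            r0, r1 = rows[i], rows[i - 1] if i else rows[i]
            lo, hi = (r0, r1) if r0 <= r1 else (r1, r0)
            img[lo:hi + 1, cols[i]] = L
        strips[m] = img
    return EcgImage(strips, cfg)


def ssim_pair(x: np.ndarray, y: np.ndarray, L: float = 1.0) -> float:
    """Global-statistics SSIM between two equally sized images; in [-1, 1]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"image dimensions differ: {x.shape} vs {y.shape}")
    c1 = (K1 * L) ** 2
    c2 = (K2 * L) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = float(np.mean((x - mx) * (y - my)))
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx**2 + my**2 + c1) * (vx + vy + c2)))


def ssim(x: "EcgImage | np.ndarray", y: "EcgImage | np.ndarray",
         L: float | None = None) -> float:
    """SSIM between ECG images: the mean over all MxM lead-strip pairs."""
    if isinstance(x, EcgImage) and isinstance(y, EcgImage):
        if x.strips.shape != y.strips.shape:
            raise ValueError("image dimensions differ")
        Lv = L if L is not None else x.config.dynamic_range
        vals = [ssim_pair(a, b, Lv) for a in x.strips for b in y.strips]
        return float(np.mean(vals))
    return ssim_pair(np.asarray(x), np.asarray(y), L if L is not None else 1.0)


# ------------------------------------------------------------- templates

@dataclass
class TemplateLibrary:
    templates: list[EcgImage] = field(default_factory=list)
    template_groups: list[str] = field(default_factory=list)
    classifier: LinearDiscriminantAnalysis | None = None

    @property
    def fitted(self) -> bool:
        return self.classifier is not None and len(self.templates) > 0

    def features(self, image: EcgImage) -> np.ndarray:
        return np.array([ssim(image, t) for t in self.templates])

    def save(self, path: str | Path) -> Path:
        """Persist templates + classifier as one versioned archive."""
        import joblib
        joblib.dump({"format_version": 1, "templates": self.templates,
                     "template_groups": self.template_groups,
                     "classifier": self.classifier}, path)
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "TemplateLibrary":
        import joblib
        d = joblib.load(path)
        if d.get("format_version") != 1:
            raise ValueError(f"unsupported template archive version "
                             f"{d.get('format_version')}")
        return cls(d["templates"], d["template_groups"], d["classifier"])


def _cluster_representative(images: list[EcgImage],
                            members: list[int]) -> int:
    """Index (within ``members``) of the image with maximal mean SSIM to the
    cluster, ties broken by lowest index; singleton is its own representative."""
    if len(members) == 1:
        return members[0]
    best, best_val = members[0], -np.inf
    for j in members:
        mean_s = np.mean([ssim(images[i], images[j]) for i in members])
        if mean_s > best_val + 1e-12:
            best, best_val = j, mean_s
    return best


def build_templates(images: list[EcgImage], groups: list[str],
                    n_clusters: int = 3) -> TemplateLibrary:
    """Cluster each quality group on (1 - SSIM) and fit the LDA grader."""
    lib = TemplateLibrary()
    for g in ("good", "poor"):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        if len(idx) < 2:
            raise ValueError(f"need at least 2 images in group '{g}'")
        sub = [images[i] for i in idx]
        m = len(sub)
        D = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                D[a, b] = D[b, a] = 1.0 - ssim(sub[a], sub[b])
        kc = min(n_clusters, m)
        labels = fcluster(linkage(squareform(D, checks=False), method="average"),
                          kc, criterion="maxclust")
        for c in np.unique(labels):
            members = [int(i) for i in np.flatnonzero(labels == c)]
            rep = _cluster_representative(sub, members)
            lib.templates.append(sub[rep])
            lib.template_groups.append(g)
    feats = np.array([lib.features(img) for img in images])
    lda = LinearDiscriminantAnalysis()
    lda.fit(feats, groups)
    lib.classifier = lda
    return lib


def partition_by_similarity(images: list[EcgImage]) -> list[str]:
    """Unsupervised good/poor split: 2-means on mean pairwise SSIM; the
    mutually more similar group is taken as good quality."""
    from sklearn.cluster import KMeans
    m = len(images)
    S = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            S[a, b] = 1.0 if a == b else ssim(images[a], images[b])
    mean_sim = S.mean(axis=1, keepdims=True)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(mean_sim)
    good_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    return ["good" if l == good_cluster else "poor" for l in km.labels_]


def classify_ecg_quality(image: EcgImage,
                         library: TemplateLibrary) -> tuple[str, float]:
    """Grade an ECG image; returns (label, discriminant score for 'good')."""
    if not library.fitted:
        raise ValueError("template library is not fitted")
    f = library.features(image).reshape(1, -1)
    label = str(library.classifier.predict(f)[0])
    score = float(library.classifier.decision_function(f)[0])
    if list(library.classifier.classes_)[1] != "good":
        score = -score
    return label, score


# ------------------------------------------------------------------- SQIs

@dataclass(frozen=True)
class SqiVector:
    bsqi: float
    ssqi: float
    ksqi: float
    composite: float = float("nan")


def compute_sqis(lead: np.ndarray, fs: float) -> SqiVector:
    """Per-lead quality indices.

    bSQI: agreement (within 150 ms, Jaccard style) between the pipeline
    R-peak detector and an amplitude-threshold picker; 0 for a constant
    signal. sSQI: Welch power fraction in 5-14 Hz relative to 1-40 Hz
    (QRS-energy band convention). kSQI: excess kurtosis of the segment.
    """
    x = np.asarray(lead, float)
    if len(x) < 10 * fs:
        raise ValueError("need at least 10 s of signal for SQIs")
    if np.ptp(x) <= 1e-12:
        return SqiVector(0.0, 0.0, 0.0)
    from .beats import _match_beats
    b1 = detect_r_peaks(x, fs)
    b2 = amplitude_threshold_detector(x, fs)
    if len(b1) == 0 or len(b2) == 0:
        bsqi = 0.0
    else:
        m = len(_match_beats(b2.times_s, b1.times_s, 0.150))
        bsqi = m / (len(b1) + len(b2) - m)
    f, p = sps.welch(x - x.mean(), fs=fs, nperseg=min(len(x), int(8 * fs)))
    num = np.trapezoid(p[(f >= 5) & (f <= 14)], f[(f >= 5) & (f <= 14)])
    den = np.trapezoid(p[(f >= 1) & (f <= 40)], f[(f >= 1) & (f <= 40)])
    ssqi = float(num / den) if den > 0 else 0.0
    return SqiVector(float(bsqi), ssqi, float(kurtosis(x, fisher=True)))


def combine_sqis(sqis: list[SqiVector],
                 weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 ) -> list[SqiVector]:
    """Min-max scale each SQI across leads and attach the weighted composite."""
    arr = np.array([[s.bsqi, s.ssqi, s.ksqi] for s in sqis], float)
    scaled = np.empty_like(arr)
    for j in range(3):
        col = arr[:, j]
        rng_ = np.nanmax(col) - np.nanmin(col)
        scaled[:, j] = 0.5 if rng_ <= 1e-12 else (col - np.nanmin(col)) / rng_
    w = np.asarray(weights, float)
    comp = scaled @ w / w.sum()
    return [SqiVector(s.bsqi, s.ssqi, s.ksqi, float(c))
            for s, c in zip(sqis, comp)]


def select_best_lead(sqis: list[SqiVector],
                     weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     ) -> tuple[int, list[SqiVector]]:
    """Lead index with the highest composite SQI (ties: lowest index)."""
    if not sqis:
        raise ValueError("no leads")
    combined = combine_sqis(sqis, weights)
    comps = np.array([s.composite for s in combined])
    if not np.any(np.isfinite(comps)):
        raise ValueError("no lead has a finite composite SQI")
    return int(np.nanargmax(comps)), combined


# ------------------------------------------------------- ABP SVD subspace

RATIO_SENTINEL = 1e12


@dataclass(frozen=True)
class SubspaceModel:
    basis: np.ndarray       # (k, P) orthonormal signal-subspace rows
    pulse_len: int
    threshold: float        # minimum reference energy ratio

    @property
    def rank(self) -> int:
        return self.basis.shape[0]


def _normalize_pulse(pulse: np.ndarray, P: int) -> np.ndarray:
    pulse = np.asarray(pulse, float)
    if len(pulse) < 3:
        raise ValueError("pulse shorter than 3 samples")
    x = np.linspace(0.0, 1.0, len(pulse))
    y = CubicSpline(x, pulse)(np.linspace(0.0, 1.0, P))
    sd = y.std()
    if sd <= 1e-12:
        raise ValueError("flat pulse cannot be standardized")
    return (y - y.mean()) / sd


def _energy_ratio(p: np.ndarray, basis: np.ndarray) -> float:
    coef = basis @ p
    sig = float(coef @ coef)
    res = float(p @ p) - sig
    if res <= 1e-12 * max(sig, 1.0):
        return RATIO_SENTINEL
    return sig / res


def fit_abp_subspace(reference_pulses: list[np.ndarray], P: int = 100,
                     energy_fraction: float = 0.95) -> SubspaceModel:
    """SVD of the normalized reference pulse matrix; the signal subspace is
    the smallest set of leading right-singular directions holding the
    requested energy fraction, and the acceptance threshold is the minimum
    reference pulse's energy ratio."""
    mat = np.array([_normalize_pulse(p, P) for p in reference_pulses])
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 reference pulses")
    _, s, vt = np.linalg.svd(mat, full_matrices=False)
    frac = np.cumsum(s**2) / np.sum(s**2)
    k = int(np.searchsorted(frac, energy_fraction - 1e-12) + 1)
    k = min(k, mat.shape[1] - 1)
    basis = vt[:k]
    tau = min(_energy_ratio(row, basis) for row in mat)
    return SubspaceModel(basis, P, float(tau))


def score_abp_pulse(pulse: np.ndarray,
                    model: SubspaceModel) -> tuple[float, bool]:
    """(energy ratio, valid) for one pulse under the fitted subspace model."""
    p = _normalize_pulse(pulse, model.pulse_len)
    ratio = _energy_ratio(p, model.basis)
    return ratio, bool(ratio >= model.threshold)


def make_reference_library(n: int = 200, P: int = 120,
                           seed: int = 1729) -> list[np.ndarray]:
    """Synthetic stand-in for an expert-validated ABP pulse library.

    Pulses share the canonical arterial morphology (fast systolic upstroke,
    exponential diastolic decay, dicrotic bump) with physiological spread
    in timing and proportions. This is a synthetic library, not clinical
    reference data; any user-supplied library fits the same interface.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        phase = np.linspace(0, 1, P, endpoint=False)
        t_sys = rng.uniform(0.10, 0.20)
        decay = rng.uniform(0.25, 0.45)
        notch_amp = rng.uniform(0.05, 0.18)
        notch_pos = rng.uniform(0.38, 0.52)
        up = np.clip(phase / t_sys, 0, 1)
        y = (np.sin(up * np.pi / 2) ** 2
             * np.exp(-np.clip(phase - t_sys, 0, None) / decay)
             + notch_amp * np.exp(-0.5 * ((phase - notch_pos) / 0.05) ** 2))
        out.append(rng.uniform(30, 60) * y + rng.uniform(55, 85))
    return out


# --------------------------------------------------------------- gating

@dataclass(frozen=True)
class QualityReport:
    segment_index: int
    passed: bool
    ecg_quality: str | None        # good | poor | None (ABP-only mode)
    ecg_score: float | None
    best_lead: int | None
    sqis: tuple[SqiVector, ...]
    abp_valid_fraction: float | None
    n_pulses: int
    reasons: tuple[str, ...]

    def to_json(self) -> str:
        d = {
            "segment_index": self.segment_index,
            "passed": self.passed,
            "ecg_quality": self.ecg_quality,
            "ecg_score": self.ecg_score,
            "best_lead": self.best_lead,
            "sqis": [{"bsqi": s.bsqi, "ssqi": s.ssqi, "ksqi": s.ksqi,
                      "composite": s.composite} for s in self.sqis],
            "abp_valid_fraction": self.abp_valid_fraction,
            "n_pulses": self.n_pulses,
            "reasons": list(self.reasons),
        }
        return json.dumps(d)


def gate_segment(segment: WaveformRecord,
                 library: TemplateLibrary | None,
                 subspace: SubspaceModel,
                 segment_index: int = 0,
                 min_abp_valid_fraction: float = 0.8,
                 abp_only: bool = False,
                 render_config: RenderConfig | None = None) -> QualityReport:
    """Pass a segment only when the ECG image grades good (unless ABP-only)
    and the fraction of subspace-valid ABP pulses meets the minimum."""
    from .beats import detect_pulse_onsets, detect_systolic_peaks, extract_pulses
    reasons: list[str] = []
    ecg_quality = ecg_score = best = None
    sqis: list[SqiVector] = []
    ecg_leads = segment.by_role("ecg")
    if not abp_only and ecg_leads:
        leads = np.array([c.samples for c in ecg_leads])
        img = render_ecg_image(leads, segment.fs, render_config)
        if library is None:
            raise ValueError("ECG gating requires a fitted template library")
        ecg_quality, ecg_score = classify_ecg_quality(img, library)
        if ecg_quality != "good":
            reasons.append("ECG image classified poor")
        else:
            sqis = [compute_sqis(c.samples, segment.fs) for c in ecg_leads]
            best, sqis = select_best_lead(sqis)
    abp_frac = None
    n_pulses = 0
    abp = segment.by_role("abp")
    if abp:
        x = abp[0].samples
        peaks = detect_systolic_peaks(x, segment.fs)
        onsets = detect_pulse_onsets(x, segment.fs, peaks)
        pulses = extract_pulses(x, segment.fs, onsets)
        n_pulses = len(pulses)
        if n_pulses == 0:
            abp_frac = 0.0
            reasons.append("no ABP pulses detected")
        else:
            valid = 0
            for p in pulses:
                try:
                    _, ok = score_abp_pulse(p, subspace)
                except ValueError:
                    ok = False
                valid += ok
            abp_frac = valid / n_pulses
            if abp_frac < min_abp_valid_fraction:
                reasons.append(
                    f"ABP valid fraction {abp_frac:.2f} < {min_abp_valid_fraction}")
    else:
        reasons.append("no ABP channel")
    ecg_ok = abp_only or (ecg_quality == "good")
    abp_ok = abp_frac is not None and abp_frac >= min_abp_valid_fraction
    return QualityReport(segment_index, bool(ecg_ok and abp_ok), ecg_quality,
                         ecg_score, best, tuple(sqis), abp_frac, n_pulses,
                         tuple(reasons))
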