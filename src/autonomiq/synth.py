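"""Ground-truthed synthetic ECG/ABP generator.

The generator works in the beat domain first — a sinus tachogram with
additive LF and HF sinusoidal modulation plus white jitter:

    RR_k = RR0 + A_LF sin(2 pi f_LF t_k) + A_HF sin(2 pi f_HF t_k) + e_k

with beat times accumulated from the intervals. Additive RR-domain
modulation (rather than integral pulse frequency modulation) keeps every
downstream quantity available in closed form for testing; an IPFM mode is
available behind a flag for more realistic spectra. PVCs are injected with
a coupling interval that is a fixed fraction of the preceding sinus
interval and a fully compensatory pause (compI = 2 RR - couplI); the
post-ectopic recovery lengthens successive intervals by a per-beat
increment, so the true turbulence slope equals that increment. Systolic
pressure can be coupled to RR through a settable baroreflex gain, and
waveforms are rendered from per-beat templates so detector truth is exact.

Every stochastic draw is governed by the spec's seed; identical seeds give
identical outputs at every level.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import BeatSeries, Channel, IntervalSeries, WaveformRecord


@dataclass(frozen=True)
class PvcSpec:
    count: int = 20
    coupling_fraction: float = 0.6
    accel_depth_ms: float = 0.0         # extra shortening of RR1, RR2
    decel_increment_ms: float = 8.0     # per-beat lengthening during recovery
    decel_increment_range: tuple[float, float] | None = None  # uniform draw per event
    recovery_beats: int = 10
    min_spacing_beats: int = 20


@dataclass(frozen=True)
class NoiseSpec:
    white_sd: float = 0.0               # channel units
    wander_amp: float = 0.0             # baseline wander amplitude
    wander_freq_hz: float = 0.33
    flatline_s: float = 0.0             # total flatline duration
    burst_s: float = 0.0                # total motion-burst duration
    burst_amp: float = 0.0


@dataclass(frozen=True)
class SubjectSpec:
    """Parameters of one synthetic subject; defaults are a healthy adult."""

    mean_rr_ms: float = 850.0
    lf_amp_ms: float = 30.0
    lf_freq_hz: float = 0.10
    hf_amp_ms: float = 40.0
    hf_freq_hz: float = 0.25
    jitter_sd_ms: float = 5.0
    pvc: PvcSpec = field(default_factory=PvcSpec)
    brs_gain_ms_per_mmHg: float = 15.0
    sbp_mode: str = "walk"              # ramp | sinusoid | walk
    sbp_baseline_mmHg: float = 120.0
    sbp_amp_mmHg: float = 1.0
    ecg_noise: NoiseSpec = field(default_factory=NoiseSpec)
    abp_noise: NoiseSpec = field(default_factory=NoiseSpec)
    fs_hz: float = 250.0
    seed: int = 0


@dataclass(frozen=True)
class Tachogram:
    """Beat times + labels with the generating truth retained."""

    times_s: np.ndarray
    labels: np.ndarray
    truth: dict

    def beats(self, source: str = "ecg") -> BeatSeries:
        return BeatSeries(self.times_s, self.labels, source=source)  # type: ignore[arg-type]

    def intervals(self) -> IntervalSeries:
        from .records import derive_intervals
        return derive_intervals(self.beats())


def gen_tachogram(spec: SubjectSpec, duration_s: float | None = None,
                  n_beats: int | None = None,
                  rng: np.random.Generator | None = None,
                  ipfm: bool = False) -> Tachogram:
    """Sinus tachogram with LF/HF modulation and white jitter.

    ``ipfm=True`` switches to integral pulse frequency modulation: a beat
    fires whenever the integral of the instantaneous rate crosses an
    integer, which is more faithful to sinoatrial physiology but has no
    closed-form interval spectrum (the additive RR-domain default does).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if ipfm:
        return _gen_tachogram_ipfm(spec, duration_s, n_beats, rng)
    if n_beats is None:
        if duration_s is None:
            duration_s = 3600.0
        n_beats = int(np.ceil(duration_s * 1000.0 / max(spec.mean_rr_ms -
                      spec.lf_amp_ms - spec.hf_amp_ms, 300.0))) + 2
    times = np.empty(n_beats)
    rr = np.empty(n_beats - 1)
    t = 0.0
    times[0] = 0.0
    for k in range(n_beats - 1):
        v = (spec.mean_rr_ms
             + spec.lf_amp_ms * np.sin(2 * np.pi * spec.lf_freq_hz * t)
             + spec.hf_amp_ms * np.sin(2 * np.pi * spec.hf_freq_hz * t)
             + (rng.normal(0.0, spec.jitter_sd_ms) if spec.jitter_sd_ms > 0 else 0.0))
        v = max(v, 250.0)
        rr[k] = v
        t += v / 1000.0
        times[k + 1] = t
    if duration_s is not None:
        keep = times <= duration_s
        times = times[keep]
        rr = rr[:max(len(times) - 1, 0)]
    labels = np.full(len(times), "N", dtype="<U1")
    return Tachogram(times, labels, truth={"rr_ms": rr, "spec": spec})


def _gen_tachogram_ipfm(spec: SubjectSpec, duration_s: float | None,
                        n_beats: int | None,
                        rng: np.random.Generator) -> Tachogram:
    """Integral pulse frequency modulation: integrate the instantaneous
    rate r(t) = (1 + m(t)) / T0 on a fine grid; beats at integer crossings."""
    if duration_s is None:
        duration_s = (n_beats or 100) * spec.mean_rr_ms / 1000.0 * 1.2
    dt = 0.01
    t = np.arange(0.0, duration_s, dt)
    T0 = spec.mean_rr_ms / 1000.0
    m = (spec.lf_amp_ms * np.sin(2 * np.pi * spec.lf_freq_hz * t)
         + spec.hf_amp_ms * np.sin(2 * np.pi * spec.hf_freq_hz * t)) \
        / spec.mean_rr_ms
    rate = np.clip((1.0 + m) / T0, 1e-3, None)
    integral = np.concatenate([[0.0], np.cumsum(rate) * dt])
    times = []
    k = 1
    for i in range(1, len(integral)):
        while integral[i] >= k:
            frac = (k - integral[i - 1]) / (integral[i] - integral[i - 1])
            tb = (i - 1 + frac) * dt
            if spec.jitter_sd_ms > 0:
                tb += rng.normal(0.0, spec.jitter_sd_ms / 1000.0)
            times.append(tb)
            k += 1
    times = np.sort(np.asarray(times))
    if n_beats is not None:
        times = times[:n_beats]
    labels = np.full(len(times), "N", dtype="<U1")
    return Tachogram(times, labels,
                     truth={"rr_ms": np.diff(times) * 1000.0, "spec": spec,
                            "mode": "ipfm"})


def inject_pvc(tach: Tachogram, pvc: PvcSpec | None = None,
               rng: np.random.Generator | None = None,
               margin_beats: int = 18) -> Tachogram:
    """Inject PVCs with coupling/compensatory intervals and a recovery ramp.

    Returns a new tachogram whose beat count is unchanged: the beat at each
    site becomes the ectopic beat, its preceding interval the coupling
    interval and the following one the compensatory pause. The truth bundle
    records each event's site and per-beat deceleration increment (the true
    turbulence slope when jitter is small).
    """
    spec: SubjectSpec = tach.truth["spec"]
    if pvc is None:
        pvc = spec.pvc
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    rr = np.diff(tach.times_s) * 1000.0
    n_int = len(rr)
    labels = tach.labels.copy()
    lo = margin_beats + 2
    hi = n_int - (pvc.recovery_beats + margin_beats + 2)
    if hi <= lo:
        raise ValueError("tachogram too short for the requested PVC injection")
    # stride placement with bounded jitter: guarantees the exact count and
    # the minimum inter-site spacing, or fails loudly
    stride = (hi - lo) // pvc.count
    if stride < pvc.min_spacing_beats:
        raise ValueError(
            f"cannot place {pvc.count} PVCs {pvc.min_spacing_beats} beats "
            f"apart in {n_int} intervals")
    slack = stride - pvc.min_spacing_beats
    sites = [int(lo + k * stride + rng.integers(0, slack + 1))
             for k in range(pvc.count)]
    events = []
    for s in sites:
        prev = rr[s - 1]
        coupl = pvc.coupling_fraction * prev
        comp = 2.0 * prev - coupl
        rr[s] = coupl
        rr[s + 1] = comp
        if pvc.decel_increment_range is not None:
            inc = float(rng.uniform(*pvc.decel_increment_range))
        else:
            inc = pvc.decel_increment_ms
        for j in range(1, pvc.recovery_beats + 1):
            idx = s + 1 + j
            if idx < n_int:
                rr[idx] += inc * j
                if j <= 2 and pvc.accel_depth_ms:
                    rr[idx] -= pvc.accel_depth_ms
        labels[s + 1] = "V"
        events.append({"beat_index": s + 1, "coupl_ms": float(coupl),
                       "comp_ms": float(comp), "ts_increment_ms": inc})
    times = np.concatenate([[tach.times_s[0]],
                            tach.times_s[0] + np.cumsum(rr) / 1000.0])
    truth = dict(tach.truth)
    truth.update({"rr_ms": rr, "pvc_events": events,
                  "pvc_beat_indices": [e["beat_index"] for e in events]})
    return Tachogram(times, labels, truth)


def gen_coupled_sbp(tach: Tachogram, spec: SubjectSpec | None = None,
                    rng: np.random.Generator | None = None,
                    closed_loop: bool = True,
                    walk_bound_mmHg: float = 20.0) -> tuple[Tachogram, np.ndarray]:
    """Per-beat systolic pressure, optionally driving RR through gain G.

    In closed-loop mode the sinus intervals are regenerated as
    RR_k = RR0 + G (sBP_k - baseline) + jitter, so the true baroreflex
    gain is ``spec.brs_gain_ms_per_mmHg``. The random-walk mode takes
    ±``sbp_amp_mmHg`` steps reflected at ±``walk_bound_mmHg`` around the
    baseline so pressure (and hence RR) stays physiological.
    """
    if spec is None:
        spec = tach.truth["spec"]
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    n = len(tach.times_s)
    base = spec.sbp_baseline_mmHg
    if spec.sbp_mode == "ramp":
        sbp = base + spec.sbp_amp_mmHg * np.arange(n, dtype=float)
    elif spec.sbp_mode == "sinusoid":
        sbp = base + 10.0 * spec.sbp_amp_mmHg * np.sin(
            2 * np.pi * 0.1 * tach.times_s)
    elif spec.sbp_mode == "walk":
        steps = rng.choice([-1.0, 1.0], size=n) * spec.sbp_amp_mmHg
        sbp = np.empty(n)
        x = base
        for k in range(n):
            x = x + steps[k]
            if x > base + walk_bound_mmHg or x < base - walk_bound_mmHg:
                x = x - 2 * steps[k]
            sbp[k] = x
    else:
        raise ValueError(f"unknown sBP mode '{spec.sbp_mode}'")
    if not closed_loop:
        return tach, sbp
    g = spec.brs_gain_ms_per_mmHg
    rr = (spec.mean_rr_ms + g * (sbp[1:] - base)
          + (rng.normal(0.0, spec.jitter_sd_ms, n - 1)
             if spec.jitter_sd_ms > 0 else 0.0))
    rr = np.maximum(rr, 250.0)
    times = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    truth = dict(tach.truth)
    truth.update({"rr_ms": rr, "sbp_mmHg": sbp, "brs_gain": g})
    return Tachogram(times, tach.labels.copy(), truth), sbp


def paired_series(tach: Tachogram, sbp: np.ndarray) -> IntervalSeries:
    """RR intervals paired beat-for-beat with the sBP at the terminating beat."""
    rr = np.diff(tach.times_s) * 1000.0
    return IntervalSeries(tach.times_s[1:], rr, kind="RR",
                          paired_sbp_mmHg=np.asarray(sbp, float)[1:])


# ------------------------------------------------------------- waveforms

def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _ecg_beat(t: np.ndarray, t_r: float, ectopic: bool) -> np.ndarray:
    """P-QRS-T complex as Gaussian bumps; ectopic beats are wide and large."""
    if not ectopic:
        return (0.12 * _gauss(t, t_r - 0.19, 0.025)
                - 0.15 * _gauss(t, t_r - 0.026, 0.010)
                + 1.00 * _gauss(t, t_r, 0.012)
                - 0.25 * _gauss(t, t_r + 0.026, 0.010)
                + 0.30 * _gauss(t, t_r + 0.24, 0.045))
    # no P wave, broad high-amplitude QRS, discordant T
    return (1.80 * _gauss(t, t_r, 0.055)
            - 0.60 * _gauss(t, t_r + 0.10, 0.035)
            - 0.40 * _gauss(t, t_r + 0.32, 0.060))


def _abp_pulse(phase: np.ndarray) -> np.ndarray:
    """Normalized pulse shape on phase [0,1): fast systolic upstroke,
    exponential decay with a dicrotic bump; 0 at onset, 1 at systole."""
    up = np.clip(phase / 0.15, 0.0, 1.0)
    shape = np.sin(up * np.pi / 2) ** 2
    decay = np.exp(-np.clip(phase - 0.15, 0.0, None) / 0.35)
    dicrotic = 0.12 * _gauss(phase, 0.45, 0.05)
    return shape * decay + dicrotic


def render_waveforms(tach: Tachogram, sbp: np.ndarray | None = None,
                     fs: float | None = None, n_ecg_leads: int = 2,
                     pulse_pressure_mmHg: float = 40.0) -> tuple[WaveformRecord, BeatSeries]:
    """Render ECG lead(s) and an ABP channel from a labelled tachogram.

    All channels share one sampling rate (record invariant). The ABP pulse
    peak equals the requested per-beat systolic value; additional leads are
    scaled copies of lead II (lead ratio 0.7) so multi-lead image quality
    and lead selection are exercisable. Returns the record plus the truth
    beat annotations.
    """
    spec: SubjectSpec = tach.truth["spec"]
    if fs is None:
        fs = spec.fs_hz
    t_beats = tach.times_s
    dur = float(t_beats[-1]) + 1.0
    n = int(np.ceil(dur * fs))
    tt = np.arange(n) / fs
    ecg = np.zeros(n)
    for t_r, lab in zip(t_beats, tach.labels):
        i0 = max(int((t_r - 0.45) * fs), 0)
        i1 = min(int((t_r + 0.55) * fs), n)
        ecg[i0:i1] += _ecg_beat(tt[i0:i1], t_r, lab == "V")
    if sbp is None:
        sbp = np.full(len(t_beats), 120.0)
    abp = np.zeros(n)
    for k in range(len(t_beats) - 1):
        i0 = int(t_beats[k] * fs)
        i1 = min(int(t_beats[k + 1] * fs), n)
        if i1 <= i0:
            continue
        phase = (tt[i0:i1] - t_beats[k]) / (t_beats[k + 1] - t_beats[k])
        dia = sbp[k] - pulse_pressure_mmHg
        abp[i0:i1] = dia + pulse_pressure_mmHg * _abp_pulse(phase)
    abp[:int(t_beats[0] * fs)] = sbp[0] - pulse_pressure_mmHg
    abp[int(t_beats[-1] * fs):] = sbp[-1] - pulse_pressure_mmHg
    chans = [Channel(name="II", role="ecg", samples=ecg, units="mV")]
    for j in range(1, n_ecg_leads):
        chans.append(Channel(name=f"V{j}", role="ecg",
                             samples=0.7 * ecg, units="mV"))
    chans.append(Channel(name="ABP", role="abp", samples=abp, units="mmHg"))
    record = WaveformRecord(channels=tuple(chans), fs=fs)
    return record, tach.beats()


def corrupt(record: WaveformRecord, noise: NoiseSpec,
            seed: int = 0, roles: tuple[str, ...] = ("ecg", "abp")) -> WaveformRecord:
    """Add white noise, baseline wander, flatline and motion-burst artifacts.

    Returns a new record; the truth mask of corrupted sample ranges is not
    needed by callers (the quality gate is judged against clean/corrupt
    record pairs), so corruption parameters are the truth.
    """
    rng = np.random.default_rng(seed)
    n = record.n_samples
    tt = record.time()
    new_chans = []
    for ch in record.channels:
        x = ch.samples.copy()
        if ch.role in roles:
            if noise.white_sd > 0:
                x += rng.normal(0.0, noise.white_sd, n)
            if noise.wander_amp > 0:
                phase = rng.uniform(0, 2 * np.pi)
                x += noise.wander_amp * np.sin(
                    2 * np.pi * noise.wander_freq_hz * tt + phase)
            if noise.flatline_s > 0:
                i0 = rng.integers(0, max(n - int(noise.flatline_s * record.fs), 1))
                i1 = min(i0 + int(noise.flatline_s * record.fs), n)
                x[i0:i1] = x[i0] if i0 < n else 0.0
            if noise.burst_s > 0 and noise.burst_amp > 0:
                i0 = rng.integers(0, max(n - int(noise.burst_s * record.fs), 1))
                i1 = min(i0 + int(noise.burst_s * record.fs), n)
                x[i0:i1] += np.cumsum(rng.normal(0, noise.burst_amp, i1 - i0))
        new_chans.append(Channel(ch.name, ch.role, x, ch.units))
    return WaveformRecord(tuple(new_chans), record.fs, record.t0)


# ---------------------------------------------------------------- cohort

#: healthy parameter distributions (mean, sd) for cohort draws
HEALTHY_COHORT = {
    "mean_rr_ms": (850.0, 50.0),
    "lf_amp_ms": (30.0, 5.0),
    "hf_amp_ms": (40.0, 6.0),
    "jitter_sd_ms": (5.0, 1.0),
    "brs_gain_ms_per_mmHg": (15.0, 3.0),
    "ts_increment_ms": (8.0, 1.0),
}

#: dysfunctional draws: four of the five indices displaced far (>4 SD of the
#: healthy index spread): RMSSD (via HF amp + jitter), HRT slope, BRS, LF power
EAD_COHORT = {
    "mean_rr_ms": (850.0, 50.0),
    "lf_amp_ms": (4.0, 1.0),
    "hf_amp_ms": (6.0, 1.5),
    "jitter_sd_ms": (1.5, 0.3),
    "brs_gain_ms_per_mmHg": (2.0, 0.5),
    "ts_increment_ms": (0.3, 0.1),
}


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    age: int
    sex: str
    spec: SubjectSpec
    ead_truth: bool


def make_cohort(n: int, prevalence: float, seed: int = 0,
                effect: dict | None = None) -> list[CohortSubject]:
    """Draw a synthetic cohort with planted eAD prevalence.

    Healthy and dysfunctional subjects differ in the generator parameters
    that drive the five indices; ``effect`` may override any entry of the
    dysfunctional parameter table. Same seed, same cohort.
    """
    rng = np.random.default_rng(seed)
    ead_table = dict(EAD_COHORT)
    if effect:
        ead_table.update(effect)
    out = []
    for i in range(n):
        is_ead = bool(rng.random() < prevalence)
        table = ead_table if is_ead else HEALTHY_COHORT
        draw = {k: max(float(rng.normal(m, s)), 0.05) for k, (m, s) in table.items()}
        inc = draw.pop("ts_increment_ms")
        spec = SubjectSpec(
            mean_rr_ms=draw["mean_rr_ms"],
            lf_amp_ms=draw["lf_amp_ms"],
            hf_amp_ms=draw["hf_amp_ms"],
            jitter_sd_ms=draw["jitter_sd_ms"],
            brs_gain_ms_per_mmHg=draw["brs_gain_ms_per_mmHg"],
            pvc=PvcSpec(count=15, decel_increment_ms=inc),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(CohortSubject(
            subject_id=f"S{i:04d}",
            age=int(rng.integers(20, 80)),
            sex=str(rng.choice(["M", "F"])),
            spec=spec, ead_truth=is_ead))
    return out
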