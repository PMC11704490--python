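"""Core data model: waveform records, segment windows, beat series and interval series.

Conventions used throughout the package: time in seconds from record start
(0-based sample indexing), inter-beat intervals in milliseconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

ChannelRole = Literal["ecg", "abp"]

#: Beat labels: N = normal sinus, V = premature ventricular contraction,
#: X = unclassified (detector could not form a stable decision).
BEAT_LABELS = ("N", "V", "X")


class RecordError(ValueError):
    """Structured error for malformed waveform records."""


@dataclass(frozen=True)
class Channel:
    name: str
    role: ChannelRole
    samples: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


@dataclass(frozen=True)
class WaveformRecord:
    """Multi-channel sampled record with a single sampling rate.

    All channels share one sampling rate ``fs`` (Hz) and one length; ``t0``
    is the record start time in seconds (analysis times are relative to it).
    """

    channels: tuple[Channel, ...]
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise RecordError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise RecordError("record has no channels")
        n0 = len(self.channels[0].samples)
        if n0 < 1:
            raise RecordError(f"channel '{self.channels[0].name}' is empty")
        for ch in self.channels[1:]:
            if len(ch.samples) != n0:
                raise RecordError(
                    f"channel '{ch.name}' has {len(ch.samples)} samples, "
                    f"expected {n0} (channel '{self.channels[0].name}')"
                )

    @property
    def n_samples(self) -> int:
        return len(self.channels[0].samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel(self, name: str) -> Channel:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def by_role(self, role: ChannelRole) -> list[Channel]:
        return [c for c in self.channels if c.role == role]

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def extract(self, start_s: float, end_s: float) -> "WaveformRecord":
        """Sub-record covering [start_s, end_s) in record-relative seconds."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        chans = tuple(replace(c, samples=c.samples[i0:i1]) for c in self.channels)
        return WaveformRecord(channels=chans, fs=self.fs, t0=self.t0 + i0 / self.fs)


@dataclass(frozen=True)
class SegmentWindow:
    """A contiguous analysis window, by default one hour, tiled without overlap."""

    start_s: float
    end_s: float
    index: int
    partial: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def slice_segments(
    record_or_duration: WaveformRecord | float,
    length_s: float = 3600.0,
    include_partial: bool = False,
) -> list[SegmentWindow]:
    """Tile a record into consecutive non-overlapping windows of ``length_s``.

    A trailing remainder shorter than ``length_s`` is flagged partial and
    excluded unless ``include_partial`` is set.
    """
    if length_s <= 0:
        raise ValueError("segment length must be positive")
    if isinstance(record_or_duration, WaveformRecord):
        total = record_or_duration.duration_s
    else:
        total = float(record_or_duration)
    out: list[SegmentWindow] = []
    n_full = int(np.floor(total / length_s + 1e-9))
    for i in range(n_full):
        out.append(SegmentWindow(i * length_s, (i + 1) * length_s, index=i))
    rem = total - n_full * length_s
    if rem > 1e-9:
        w = SegmentWindow(n_full * length_s, total, index=n_full, partial=True)
        if include_partial:
            out.append(w)
    return out


@dataclass(frozen=True)
class BeatSeries:
    """Ordered beat fiducial times (s) with per-beat labels and provenance."""

    times_s: np.ndarray
    labels: np.ndarray  # array of 'N' / 'V' / 'X'
    source: Literal["ecg", "abp"] = "ecg"
    sbp_mmHg: np.ndarray | None = None  # systolic values for ABP-derived beats

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        lab = np.asarray(self.labels, dtype="<U1")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "labels", lab)
        if len(t) != len(lab):
            raise ValueError("labels must match times in length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")
        if self.sbp_mmHg is not None:
            s = np.asarray(self.sbp_mmHg, dtype=float)
            object.__setattr__(self, "sbp_mmHg", s)
            if len(s) != len(t):
                raise ValueError("sbp values must match times in length")

    def __len__(self) -> int:
        return len(self.times_s)

    def restrict(self, start_s: float, end_s: float) -> "BeatSeries":
        m = (self.times_s >= start_s) & (self.times_s < end_s)
        sbp = self.sbp_mmHg[m] if self.sbp_mmHg is not None else None
        return BeatSeries(self.times_s[m], self.labels[m], self.source, sbp)


@dataclass(frozen=True)
class IntervalSeries:
    """Inter-beat intervals timestamped at the terminating beat.

    ``kind='RR'`` keeps only intervals whose two bounding beats are both
    sinus (label N) — intervals touching an ectopic beat are omitted, so the
    series may contain temporal gaps. ``kind='PPI'`` uses all ABP fiducials.
    """

    t_s: np.ndarray
    value_ms: np.ndarray
    kind: Literal["RR", "PPI"] = "RR"
    paired_sbp_mmHg: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        v = np.asarray(self.value_ms, dtype=float)
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "value_ms", v)
        if len(t) != len(v):
            raise ValueError("times and values must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("interval times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("interval values must be positive")
        if self.paired_sbp_mmHg is not None:
            s = np.asarray(self.paired_sbp_mmHg, dtype=float)
            object.__setattr__(self, "paired_sbp_mmHg", s)
            if len(s) != len(t):
                raise ValueError("paired sBP must match interval count")

    def __len__(self) -> int:
        return len(self.t_s)


def derive_intervals(beats: BeatSeries, kind: str | None = None) -> IntervalSeries:
    """Derive the inter-beat interval series from a labelled beat series.

    RR intervals are formed only between consecutive beats that are both
    sinus; any pair containing a V (or X) beat is dropped. PPI intervals
    (ABP source) use every fiducial. Fewer than 2 usable beats yields an
    empty series rather than an error.
    """
    if kind is None:
        kind = "PPI" if beats.source == "abp" else "RR"
    t = beats.times_s
    if len(t) < 2:
        return IntervalSeries(np.empty(0), np.empty(0), kind=kind)
    dt_ms = np.diff(t) * 1000.0
    term_t = t[1:]
    if kind == "RR":
        ok = (beats.labels[:-1] == "N") & (beats.labels[1:] == "N")
    else:
        ok = np.ones(len(dt_ms), dtype=bool)
    return IntervalSeries(term_t[ok], dt_ms[ok], kind=kind)


def align_rr_sbp(
    rr: IntervalSeries,
    sbp_beats: BeatSeries,
    tolerance_s: float = 0.5,
) -> IntervalSeries:
    """Pair each RR interval with the sBP of the nearest ABP pulse.

    The match is nearest-neighbour between the interval's terminating beat
    time and the ABP fiducial times, accepted within ``tolerance_s``.
    Unmatched intervals are dropped (they cannot enter BRS analysis).
    """
    if sbp_beats.sbp_mmHg is None:
        raise ValueError("sbp_beats must carry systolic values")
    if len(rr) == 0 or len(sbp_beats) == 0:
        return IntervalSeries(np.empty(0), np.empty(0), kind=rr.kind,
                              paired_sbp_mmHg=np.empty(0))
    pt = sbp_beats.times_s
    idx = np.searchsorted(pt, rr.t_s)
    idx = np.clip(idx, 1, len(pt) - 1) if len(pt) > 1 else np.zeros(len(rr), dtype=int)
    lo = np.maximum(idx - 1, 0)
    pick = np.where(np.abs(pt[idx] - rr.t_s) < np.abs(pt[lo] - rr.t_s), idx, lo)
    dist = np.abs(pt[pick] - rr.t_s)
    m = dist <= tolerance_s
    return IntervalSeries(
        rr.t_s[m], rr.value_ms[m], kind=rr.kind,
        paired_sbp_mmHg=sbp_beats.sbp_mmHg[pick[m]],
    )


def beats_from_arrays(
    times_s: Sequence[float],
    labels: Sequence[str] | str = "N",
    source: str = "ecg",
    sbp: Sequence[float] | None = None,
) -> BeatSeries:
    """Convenience constructor; a single-character ``labels`` is broadcast."""
    t = np.asarray(times_s, dtype=float)
    if isinstance(labels, str):
        lab = np.full(len(t), labels, dtype="<U1")
    else:
        lab = np.asarray(labels, dtype="<U1")
    return BeatSeries(t, lab, source=source,  # type: ignore[arg-type]
                      sbp_mmHg=None if sbp is None else np.asarray(sbp, float))
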