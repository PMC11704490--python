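"""Heart rate turbulence: the biphasic sinus response after a PVC.

A premature ventricular beat shortens the interval to its predecessor
(the coupling interval) and is followed by a longer compensatory interval.
Turbulence onset (TO, %) quantifies the immediate post-ectopic heart-rate
acceleration:

    TO = 100 * [(RR1 + RR2) - (RR-1 + RR-2)] / (RR-1 + RR-2)

where RR1, RR2 are the first two sinus intervals after the compensatory
interval and RR-2, RR-1 the last two before the coupling interval.
Turbulence slope (TS, ms per beat) is the maximum least-squares slope over
any 5 consecutive intervals among the first 15 post-compensatory sinus
intervals. Segment-level HRT is only attempted when more than
``min_pvc_count`` PVCs were detected in the segment, and events lacking
the required sinus context are excluded from the means.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import BeatSeries

#: sinus context required by the turbulence definitions
N_PRE_RR = 2
N_POST_RR = 15
#: HRT runs only when the per-segment detected PVC count strictly exceeds this
MIN_PVC_COUNT = 10


@dataclass(frozen=True)
class HrtEvent:
    pvc_index: int
    coupl_ms: float
    comp_ms: float
    pre_rr_ms: np.ndarray   # [RR-2, RR-1]
    post_rr_ms: np.ndarray  # [RR1 ... RR15]
    eligible: bool
    reason: str = ""


@dataclass(frozen=True)
class HrtSummary:
    status: str                 # computed | skipped | missing
    reason: str = ""
    mean_to_pct: float | None = None
    mean_ts_ms_per_beat: float | None = None
    n_pvc: int = 0
    n_events: int = 0
    events: tuple[HrtEvent, ...] = field(default=())


def extract_hrt_events(beats: BeatSeries,
                       n_pre: int = N_PRE_RR,
                       n_post: int = N_POST_RR,
                       strict: bool = False) -> list[HrtEvent]:
    """Locate every PVC and collect its sinus RR context.

    An event is eligible when beats i-1-n_pre .. i-1 and i+1 .. i+1+n_post
    (i the PVC) are all sinus, the coupling interval is shorter than the
    preceding sinus interval and the compensatory interval longer.
    ``strict`` adds the classical turbulence filters: coupling at most 80%
    and compensatory at least 120% of the reference interval, and every
    context interval within 300-2000 ms.
    """
    t = beats.times_s
    lab = beats.labels
    out: list[HrtEvent] = []
    for i in np.flatnonzero(lab == "V"):
        i = int(i)
        empty = np.empty(0)
        if i - 1 - n_pre < 0 or i + 1 + n_post >= len(t):
            out.append(HrtEvent(i, np.nan, np.nan, empty, empty, False,
                                "insufficient surrounding beats"))
            continue
        pre_idx = np.arange(i - 1 - n_pre, i)      # n_pre+1 beats before PVC
        post_idx = np.arange(i + 1, i + 2 + n_post)  # compI terminator onward
        if not (np.all(lab[pre_idx] == "N") and np.all(lab[post_idx] == "N")):
            out.append(HrtEvent(i, np.nan, np.nan, empty, empty, False,
                                "non-sinus beat inside the HRT window"))
            continue
        coupl = (t[i] - t[i - 1]) * 1000.0
        comp = (t[i + 1] - t[i]) * 1000.0
        pre_rr = np.diff(t[pre_idx]) * 1000.0      # n_pre intervals
        post_rr = np.diff(t[post_idx]) * 1000.0    # n_post intervals
        ref = pre_rr[-1]
        if not (coupl < ref):
            out.append(HrtEvent(i, coupl, comp, pre_rr, post_rr, False,
                                "coupling interval not premature"))
            continue
        if not (comp > ref):
            out.append(HrtEvent(i, coupl, comp, pre_rr, post_rr, False,
                                "compensatory interval not prolonged"))
            continue
        if strict:
            ctx = np.concatenate([pre_rr, post_rr])
            if coupl > 0.8 * ref or comp < 1.2 * ref:
                out.append(HrtEvent(i, coupl, comp, pre_rr, post_rr, False,
                                    "outside classical 20% prematurity filter"))
                continue
            if np.any(ctx < 300.0) or np.any(ctx > 2000.0):
                out.append(HrtEvent(i, coupl, comp, pre_rr, post_rr, False,
                                    "context interval outside 300-2000 ms"))
                continue
        out.append(HrtEvent(i, coupl, comp, pre_rr, post_rr, True))
    return out


def hrt_onset(event: HrtEvent) -> float | None:
    """Turbulence onset (%) for one eligible event; None when ineligible."""
    if not event.eligible or len(event.post_rr_ms) < 2 or len(event.pre_rr_ms) < 2:
        return None
    pre = event.pre_rr_ms[-2] + event.pre_rr_ms[-1]
    post = event.post_rr_ms[0] + event.post_rr_ms[1]
    return float(100.0 * (post - pre) / pre)


def hrt_slope(event: HrtEvent, window: int = 5,
              n_post: int = N_POST_RR) -> float | None:
    """Turbulence slope (ms/beat): max least-squares slope over any
    ``window`` consecutive intervals among the first ``n_post`` post-
    compensatory sinus intervals. May be negative when all slopes are."""
    if not event.eligible or len(event.post_rr_ms) < n_post:
        return None
    rr = event.post_rr_ms[:n_post]
    x = np.arange(window, dtype=float)
    xc = x - x.mean()
    denom = float(np.sum(xc**2))
    slopes = [float(np.sum(xc * (rr[s:s + window] - rr[s:s + window].mean())) / denom)
              for s in range(n_post - window + 1)]
    return float(max(slopes))


def segment_hrt(beats: BeatSeries,
                min_pvc_count: int = MIN_PVC_COUNT,
                n_pre: int = N_PRE_RR,
                n_post: int = N_POST_RR) -> HrtSummary:
    """Segment-level HRT: mean TO and TS across eligible PVC events.

    HRT is attempted only when the detected PVC count (before eligibility
    filtering) strictly exceeds ``min_pvc_count``; otherwise the segment is
    reported skipped. With PVCs but no eligible events the result is
    missing with a reason.
    """
    n_pvc = int(np.sum(beats.labels == "V"))
    if n_pvc <= min_pvc_count:
        return HrtSummary("skipped",
                          f"{n_pvc} PVC beats (> {min_pvc_count} required)",
                          n_pvc=n_pvc)
    events = extract_hrt_events(beats, n_pre=n_pre, n_post=n_post)
    tos, tss, kept = [], [], []
    for ev in events:
        to = hrt_onset(ev)
        ts = hrt_slope(ev, n_post=n_post)
        if to is not None and ts is not None:
            tos.append(to)
            tss.append(ts)
            kept.append(ev)
    if not kept:
        return HrtSummary("missing", "no eligible HRT events", n_pvc=n_pvc,
                          events=tuple(events))
    return HrtSummary("computed", "",
                      mean_to_pct=float(np.mean(tos)),
                      mean_ts_ms_per_beat=float(np.mean(tss)),
                      n_pvc=n_pvc, n_events=len(kept), events=tuple(events))
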