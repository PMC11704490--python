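"""Subject-level aggregation, standardization, and the composite
early-autonomic-dysfunction (eAD) rule.

Per-segment indices from the first 24 h are aggregated (median by
default) into one value per index, standardized as z = (value - mean)/SD
against an age/sex-stratified reference table, flagged abnormal when
|z| > 2.5 (strict, two-sided — the literature is not unanimous on the
direction of LF-power and LF/HF changes, so directions are reported but
not used for classification), and the subject is classified eAD when 3 or
more of the five indices {RMSSD, HRT slope, BRS, LF power, LF/HF} are
abnormal. A missing index counts as non-abnormal.

The bundled reference table is a synthetic default derived from widely
quoted healthy ranges (e.g. RMSSD 19-75 ms read as mean +/- 2 SD); every
entry carries a provenance note and is meant to be replaced with
study-appropriate norms.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: the five classifier indices, in reporting order
EAD_INDICES = ("rmssd_ms", "hrt_ts", "brs", "lf_power_ms2", "lf_hf")
Z_THRESHOLD = 2.5
MIN_ABNORMAL_COUNT = 3


class ReferenceRanges:
    """Age/sex-stratified per-index mean and SD for z-standardization."""

    def __init__(self, table: pd.DataFrame):
        required = {"age_lo", "age_hi", "sex", "index", "mean", "sd"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        if (table["sd"] <= 0).any():
            raise ValueError("reference SDs must be positive")
        self.table = table

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceRanges":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "ReferenceRanges":
        with importlib.resources.as_file(
                importlib.resources.files("autonomiq") / "_refdata"
                / "reference_ranges.csv") as p:
            return cls.from_csv(p)

    def stratum(self, age: float, sex: str, index: str) -> tuple[float, float]:
        t = self.table
        m = ((t["age_lo"] <= age) & (age <= t["age_hi"])
             & (t["sex"] == sex) & (t["index"] == index))
        if not m.any():
            # fall back to the nearest age bin for the same sex and index
            m2 = (t["sex"] == sex) & (t["index"] == index)
            if not m2.any():
                raise KeyError(f"no reference entry for index '{index}', sex '{sex}'")
            sub = t[m2]
            j = (np.minimum(abs(sub["age_lo"] - age), abs(sub["age_hi"] - age))
                 ).idxmin()
            row = t.loc[j]
        else:
            row = t[m].iloc[0]
        return float(row["mean"]), float(row["sd"])


def standardize_index(value: float, mean: float, sd: float) -> float:
    return (value - mean) / sd


def flag_abnormal(z: float | None, threshold: float = Z_THRESHOLD) -> bool:
    """Two-sided strict threshold; missing z is non-abnormal."""
    if z is None or not np.isfinite(z):
        return False
    return abs(z) > threshold


@dataclass
class IndexProfile:
    subject_id: str
    age: float
    sex: str
    values: dict[str, float | None]
    z: dict[str, float | None] = field(default_factory=dict)
    abnormal: dict[str, bool] = field(default_factory=dict)
    n_segments: int = 0
    window: str = "first-24h"

    def standardize(self, ranges: ReferenceRanges,
                    threshold: float = Z_THRESHOLD) -> "IndexProfile":
        for idx in EAD_INDICES:
            v = self.values.get(idx)
            if v is None or not np.isfinite(v):
                self.z[idx] = None
                self.abnormal[idx] = False
                continue
            mean, sd = ranges.stratum(self.age, self.sex, idx)
            self.z[idx] = standardize_index(v, mean, sd)
            self.abnormal[idx] = flag_abnormal(self.z[idx], threshold)
        return self


@dataclass(frozen=True)
class EadResult:
    abnormal_count: int
    classified: bool
    contributions: dict[str, bool]
    z: dict[str, float | None]


def characterize_ead(profile: IndexProfile,
                     min_count: int = MIN_ABNORMAL_COUNT) -> EadResult:
    """Composite rule: eAD when >= min_count of the five indices are abnormal."""
    contributions = {idx: bool(profile.abnormal.get(idx, False))
                     for idx in EAD_INDICES}
    count = sum(contributions.values())
    return EadResult(count, count >= min_count, contributions, dict(profile.z))


def aggregate_subject(segment_table: pd.DataFrame,
                      subject_id: str = "", age: float = 50, sex: str = "M",
                      statistic: str = "median",
                      window: str = "first-24h") -> IndexProfile:
    """Aggregate per-segment index rows into one subject profile.

    Rows flagged ``passed == False`` are dropped; per index the median (or
    mean) over the passing segments is taken, ignoring missing entries. An
    index missing in every segment stays missing.
    """
    if "passed" in segment_table.columns:
        seg = segment_table[segment_table["passed"].astype(bool)]
    else:
        seg = segment_table
    values: dict[str, float | None] = {}
    agg = np.nanmedian if statistic == "median" else np.nanmean
    for idx in EAD_INDICES + ("hrt_to",):
        if idx not in seg.columns or seg[idx].dropna().empty:
            values[idx] = None
        else:
            values[idx] = float(agg(seg[idx].astype(float).values))
    return IndexProfile(subject_id, age, sex, values,
                        n_segments=len(seg), window=window)


def daily_trajectory(segment_table: pd.DataFrame, days: int = 5,
                     subject_id: str = "", age: float = 50, sex: str = "M",
                     statistic: str = "median") -> list[IndexProfile]:
    """Per-24-h-day profiles over the first ``days`` days.

    Requires a ``start_s`` column; a day with no passing segments yields a
    profile with every index missing.
    """
    out = []
    for d in range(days):
        lo, hi = d * 86400.0, (d + 1) * 86400.0
        rows = segment_table[(segment_table["start_s"] >= lo)
                             & (segment_table["start_s"] < hi)]
        p = aggregate_subject(rows, subject_id, age, sex, statistic,
                              window=f"day-{d + 1}")
        out.append(p)
    return out
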