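"""Pipeline configuration: one place for every tunable threshold.

Defaults reproduce the published analysis parameters (0.5-17 Hz QRS
band-pass, 0.3-s search range, 0.24-s R window, 2-s sliding window,
LF 0.04-0.15 Hz / HF 0.15-0.4 Hz, PRSA L = 15, HRT only above 10 PVCs,
2.5-SD abnormality, 3-of-5 composite rule, 1-h segments).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    segment_length_s: float = 3600.0
    allow_partial: bool = False
    mode: str = "ecg+abp"               # ecg+abp | abp-only

    # quality gate
    min_abp_valid_fraction: float = 0.8
    abp_pulse_len: int = 100
    abp_energy_fraction: float = 0.95
    n_template_clusters: int = 3
    sqi_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    # beat detection
    qrs_band_hz: tuple[float, float] = (0.5, 17.0)
    qrs_window_s: float = 2.0
    qrs_search_range_s: float = 0.3
    r_window_s: float = 0.24
    pvc_width_ms: float = 120.0
    pvc_amp_factor: float = 1.5
    pvc_corr_threshold: float = 0.9

    # variability / turbulence
    lf_band_hz: tuple[float, float] = (0.04, 0.15)
    hf_band_hz: tuple[float, float] = (0.15, 0.4)
    hrt_min_pvc: int = 10
    hrt_n_post: int = 15

    # baroreflex
    prsa_L: int = 15
    arx_order: int = 8
    alpha_sqrt: bool = True
    rr_sbp_tolerance_s: float = 0.5

    # classification
    z_threshold: float = 2.5
    min_abnormal_count: int = 3
    aggregate: str = "median"
    reference_ranges_path: str | None = None

    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.segment_length_s <= 0:
            raise ValueError("segment_length_s must be positive")
        if self.mode not in ("ecg+abp", "abp-only"):
            raise ValueError(f"unknown mode '{self.mode}'")
        if not (0 <= self.min_abp_valid_fraction <= 1):
            raise ValueError("min_abp_valid_fraction must be in [0, 1]")
        if self.aggregate not in ("median", "mean"):
            raise ValueError("aggregate must be 'median' or 'mean'")
        if self.z_threshold <= 0 or self.min_abnormal_count not in range(0, 6):
            raise ValueError("bad classification thresholds")
        if self.lf_band_hz[0] >= self.lf_band_hz[1]:
            raise ValueError("bad LF band")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("qrs_band_hz", "lf_band_hz", "hf_band_hz", "sqi_weights"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data).validate()

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d))
        return Path(path)
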