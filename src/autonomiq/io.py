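"""Readers and writers for waveform records and beat annotations.

Two dialects are supported:

* CSV — header ``time_s,<chan1>,<chan2>,...`` with the sampling rate either
  in a leading ``# fs=<Hz>`` comment line or in a YAML sidecar
  (``<base>.yaml``) that may also assign channel roles and units.
* WFDB — a native implementation of the PhysioNet signal format
  (``.hea`` header + format-16 ``.dat``) and MIT-style beat annotations,
  sufficient for records this package writes and for plain single-segment
  records. Digital conversion uses a per-channel gain stored in the header;
  round-trip precision is 1/gain in physical units.

Beat annotations are also round-tripped as CSV (``time_s,label``).
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import yaml

from .records import BeatSeries, Channel, RecordError, WaveformRecord

#: substrings used to infer a channel's role from its name
DEFAULT_ROLE_MAP = {"abp": "abp", "art": "abp", "bp": "abp", "pressure": "abp"}

_MIT_CODE = {"N": 1, "V": 5, "X": 13}
_MIT_SYMBOL = {v: k for k, v in _MIT_CODE.items()}


def infer_role(name: str, role_map: dict[str, str] | None = None) -> str:
    m = DEFAULT_ROLE_MAP if role_map is None else role_map
    low = name.lower()
    for key, role in m.items():
        if key in low:
            return role
    return "ecg"


# ---------------------------------------------------------------- CSV dialect

def write_csv(record: WaveformRecord, path: str | Path, sidecar: bool = True) -> Path:
    path = Path(path)
    t = record.time()
    cols = np.column_stack([t] + [c.samples for c in record.channels])
    header = "time_s," + ",".join(record.channel_names)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        fh.write(header + "\n")
        np.savetxt(fh, cols, delimiter=",", fmt="%.6f")
    if sidecar:
        meta = {
            "fs": float(record.fs),
            "t0": float(record.t0),
            "channels": {
                c.name: {"role": c.role, "units": c.units} for c in record.channels
            },
        }
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)
    return path


def read_csv(path: str | Path, role_map: dict[str, str] | None = None) -> WaveformRecord:
    path = Path(path)
    fs = None
    t0 = 0.0
    roles: dict[str, dict] = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        fs = float(meta.get("fs")) if meta.get("fs") is not None else None
        t0 = float(meta.get("t0", 0.0))
        roles = meta.get("channels", {}) or {}
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            for tok in first.lstrip("# ").replace(",", " ").split():
                if tok.startswith("fs="):
                    fs = float(tok[3:])
            header = fh.readline().strip()
        else:
            header = first
        names = header.split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if fs is None:
        raise RecordError("sampling rate unspecified (no '# fs=' line or YAML sidecar)")
    if names[0] != "time_s":
        raise RecordError("CSV header must start with 'time_s'")
    chans = []
    for j, name in enumerate(names[1:], start=1):
        info = roles.get(name, {})
        chans.append(Channel(
            name=name,
            role=info.get("role", infer_role(name, role_map)),
            samples=data[:, j],
            units=info.get("units", ""),
        ))
    return WaveformRecord(channels=tuple(chans), fs=fs, t0=t0)


# ------------------------------------------------------- WFDB signal dialect

def write_wfdb(record: WaveformRecord, base: str | Path) -> Path:
    """Write ``<base>.hea`` and format-16 ``<base>.dat``."""
    base = Path(base)
    name = base.name
    n = record.n_samples
    gains = []
    digs = []
    for c in record.channels:
        peak = float(np.max(np.abs(c.samples))) if n else 0.0
        gain = 32000.0 / peak if peak > 0 else 200.0
        gain = float(np.clip(gain, 1e-3, 32000.0))
        d = np.clip(np.round(c.samples * gain), -32768, 32767).astype("<i2")
        gains.append(gain)
        digs.append(d)
    interleaved = np.column_stack(digs).ravel()
    (base.parent / f"{name}.dat").write_bytes(interleaved.tobytes())
    lines = [f"{name} {len(record.channels)} {record.fs:g} {n}"]
    for c, gain, d in zip(record.channels, gains, digs):
        units = c.units or "mV"
        cks = int(np.sum(d.astype(np.int64)) % 65536)
        lines.append(
            f"{name}.dat 16 {gain:.6f}(0)/{units} 16 0 {int(d[0]) if n else 0} "
            f"{cks} 0 {c.name}"
        )
    lines.append(f"# role {' '.join(c.role for c in record.channels)}")
    (base.parent / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return base


def read_wfdb(base: str | Path, role_map: dict[str, str] | None = None) -> WaveformRecord:
    base = Path(base)
    hea = base.parent / f"{base.name}.hea"
    lines = [ln for ln in hea.read_text().splitlines() if ln.strip()]
    head = lines[0].split()
    nsig, fs, n = int(head[1]), float(head[2]), int(head[3])
    roles_comment: list[str] | None = None
    sig_lines = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            toks = ln.lstrip("# ").split()
            if toks and toks[0] == "role":
                roles_comment = toks[1:]
        else:
            sig_lines.append(ln)
    if len(sig_lines) < nsig:
        raise RecordError(f"header lists {nsig} signals but has {len(sig_lines)} lines")
    raw = np.frombuffer((base.parent / f"{base.name}.dat").read_bytes(), dtype="<i2")
    mat = raw.reshape(-1, nsig)
    if mat.shape[0] != n:
        raise RecordError(f"dat file holds {mat.shape[0]} frames, header says {n}")
    chans = []
    for j, ln in enumerate(sig_lines[:nsig]):
        toks = ln.split()
        fmt = toks[1]
        if fmt != "16":
            raise RecordError(f"unsupported WFDB format '{fmt}' (only 16)")
        gain_field = toks[2]
        units = "mV"
        if "/" in gain_field:
            gain_field, units = gain_field.split("/", 1)
        gain = float(gain_field.split("(")[0])
        if gain == 0:
            gain = 200.0
        name = toks[-1] if len(toks) > 8 else f"sig{j}"
        role = (roles_comment[j] if roles_comment and j < len(roles_comment)
                else infer_role(name, role_map))
        chans.append(Channel(name=name, role=role, samples=mat[:, j] / gain,  # type: ignore[arg-type]
                             units=units))
    return WaveformRecord(channels=tuple(chans), fs=fs)


# -------------------------------------------------------------- annotations

def write_annotations_csv(beats: BeatSeries, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s,label\n")
        for t, lab in zip(beats.times_s, beats.labels):
            fh.write(f"{t:.6f},{lab}\n")
    return path


def read_annotations_csv(path: str | Path, source: str = "ecg") -> BeatSeries:
    data = np.genfromtxt(path, delimiter=",", names=True, dtype=None, encoding="utf-8")
    t = np.atleast_1d(data["time_s"]).astype(float)
    lab = np.atleast_1d(data["label"]).astype("<U1")
    return BeatSeries(t, lab, source=source)  # type: ignore[arg-type]


def write_annotations_wfdb(beats: BeatSeries, base: str | Path, fs: float,
                           extension: str = "atr") -> Path:
    """Write MIT-format beat annotations (2-byte entries, SKIP for long gaps)."""
    base = Path(base)
    out = bytearray()
    prev = 0
    for t, lab in zip(beats.times_s, beats.labels):
        sample = int(round(t * fs))
        delta = sample - prev
        if delta > 1023 or delta < 0:
            out += struct.pack("<H", 59 << 10)  # SKIP
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        code = _MIT_CODE.get(str(lab), 13)
        out += struct.pack("<H", (code << 10) | delta)
        prev = sample
    out += struct.pack("<H", 0)
    path = base.parent / f"{base.name}.{extension}"
    path.write_bytes(bytes(out))
    return path


def read_annotations_wfdb(base: str | Path, fs: float, extension: str = "atr",
                          source: str = "ecg") -> BeatSeries:
    base = Path(base)
    raw = (base.parent / f"{base.name}.{extension}").read_bytes()
    times, labels = [], []
    sample = 0
    i = 0
    while i + 1 < len(raw):
        (word,) = struct.unpack_from("<H", raw, i)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:
            break
        if code == 59:  # SKIP: 4-byte interval follows (high word first)
            (hi,) = struct.unpack_from("<H", raw, i)
            (lo,) = struct.unpack_from("<H", raw, i + 2)
            i += 4
            sample += (hi << 16) | lo
            continue
        sample += delta
        if code in _MIT_SYMBOL:
            times.append(sample / fs)
            labels.append(_MIT_SYMBOL[code])
    return BeatSeries(np.array(times), np.array(labels, dtype="<U1"),
                      source=source)  # type: ignore[arg-type]


# ------------------------------------------------------------------ facade

def read_record(path: str | Path, format: str | None = None,
                role_map: dict[str, str] | None = None) -> WaveformRecord:
    """Read a waveform record, inferring the dialect from the path if needed."""
    path = Path(path)
    if format is None:
        if path.suffix == ".csv":
            format = "csv"
        elif path.suffix in (".hea", ".dat", ""):
            format = "wfdb"
        else:
            raise RecordError(f"cannot infer format of '{path}'")
    if format == "csv":
        return read_csv(path, role_map)
    if format == "wfdb":
        base = path.parent / path.stem if path.suffix else path
        return read_wfdb(base, role_map)
    raise RecordError(f"unknown format '{format}'")


def write_record(record: WaveformRecord, path: str | Path,
                 format: str = "csv") -> Path:
    path = Path(path)
    if format == "csv":
        return write_csv(record, path if path.suffix else path.with_suffix(".csv"))
    if format == "wfdb":
        return write_wfdb(record, path.parent / path.stem if path.suffix else path)
    raise RecordError(f"unknown format '{format}'")
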