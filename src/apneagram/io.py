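"""Waveform and annotation I/O.

Formats
-------
* CSV — native round-trip format. Either two columns (time s, amplitude mV)
  or one amplitude column with ``# fs=<Hz>`` in the header.
* WFDB — minimal single-channel codec (text ``.hea`` header + 16-bit
  little-endian ``.dat``), enough to exchange records with standard
  physiological-waveform tooling.
* EDF — read-only, through :mod:`mne` when it is installed; physical units
  are normalized to mV.

Events and hypnograms travel as CSV; screening reports as JSON or text.
Time convention everywhere: seconds from record start, half-open
``[start, end)`` intervals.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Unreadable or inconsistent input file."""


@dataclass
class EcgRecord:
    """Single-lead ECG waveform in mV at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    lead: str = "DII"
    start_time: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got fs={self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise FormatError("samples must be a non-empty 1-D array")
        if np.isnan(self.samples).any():
            # readers map missing samples to 0 and report them via quality masking
            self.samples = np.nan_to_num(self.samples, nan=0.0)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


VALID_KINDS = {"apnea", "hypopnea"}
VALID_MECHANISMS = {"obstructive", "central", "unknown"}


@dataclass
class EventAnnotation:
    """One scored respiratory event: ``[start, end)`` s, kind and mechanism."""

    start: float
    end: float
    kind: str
    mechanism: str = "unknown"
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"event end {self.end} must exceed start {self.start}")
        if self.start < 0:
            raise FormatError("event start must be >= 0")
        if self.kind not in VALID_KINDS:
            raise FormatError(f"unknown event kind {self.kind!r}")
        if self.mechanism not in VALID_MECHANISMS:
            raise FormatError(f"unknown mechanism {self.mechanism!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------- records

def read_record(path: str | Path, format: str | None = None) -> EcgRecord:
    """Read an ECG record; format inferred from the suffix when omitted."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".hea": "wfdb", ".dat": "wfdb", ".edf": "edf"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise FormatError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "csv":
        return _read_csv_record(path)
    if format == "wfdb":
        return _read_wfdb_record(path)
    if format == "edf":
        return _read_edf_record(path)
    raise FormatError(f"unsupported format {format!r}")


def write_record(rec: EcgRecord, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".hea": "wfdb", ".dat": "wfdb"}.get(path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "csv":
        header = f"fs={rec.fs:.10g} lead={rec.lead}"
        np.savetxt(path, rec.samples, fmt="%.9g", header=header)
        return path
    if format == "wfdb":
        return _write_wfdb_record(rec, path)
    raise FormatError(f"unsupported output format {format!r} (EDF is read-only)")


def _read_csv_record(path: Path) -> EcgRecord:
    header_fs = None
    lead = "DII"
    with open(path) as fh:
        first_data = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"fs\s*=\s*([0-9.eE+-]+)", line)
                if m:
                    header_fs = float(m.group(1))
                m = re.search(r"lead\s*=\s*(\S+)", line)
                if m:
                    lead = m.group(1)
                continue
            first_data = line
            break
    if first_data is None:
        raise FormatError(f"{path}: no data rows")
    ncols = len(re.split(r"[,\s]+", first_data))
    try:
        data = np.loadtxt(path, comments="#", delimiter="," if "," in first_data else None)
    except Exception as exc:  # pragma: no cover - loadtxt error text varies
        raise FormatError(f"{path}: cannot parse samples: {exc}") from exc
    data = np.atleast_2d(data.astype(float))
    if data.shape[0] == 1 and data.shape[1] > 2:
        data = data.T
    if ncols == 1:
        if header_fs is None:
            raise FormatError(f"{path}: single-column CSV requires 'fs=' in header")
        return EcgRecord(data.ravel(), fs=header_fs, lead=lead)
    t, amp = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    return EcgRecord(amp, fs=1.0 / float(np.median(dt)), lead=lead, start_time=float(t[0]))


_WFDB_GAIN = 1000.0  # adu per mV


def _write_wfdb_record(rec: EcgRecord, path: Path) -> Path:
    base = path.with_suffix("")
    n = rec.samples.size
    adu = np.clip(np.round(rec.samples * _WFDB_GAIN), -32768, 32767).astype("<i2")
    base.with_suffix(".dat").write_bytes(adu.tobytes())
    hea = (
        f"{base.name} 1 {rec.fs:.10g} {n}\n"
        f"{base.name}.dat 16 {_WFDB_GAIN:.10g}(0)/mV 16 0 {int(adu[0])} 0 0 {rec.lead}\n"
    )
    base.with_suffix(".hea").write_text(hea)
    return base.with_suffix(".hea")


def _read_wfdb_record(path: Path) -> EcgRecord:
    base = Path(path).with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"{hea}: header file not found")
    lines = [ln for ln in hea.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    try:
        nsig, fs, nsamp = int(head[1]), float(head[2]), int(head[3])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{hea}: malformed record line {lines[0]!r}") from exc
    if nsig != 1:
        raise FormatError(f"{hea}: only single-channel records supported (nsig={nsig})")
    sig = lines[1].split()
    if sig[1].split("x")[0] != "16":
        raise FormatError(f"{hea}: only format 16 supported, got {sig[1]!r}")
    m = re.match(r"([0-9.eE+-]+)(?:\(([0-9+-]+)\))?(?:/(\S+))?", sig[2])
    gain = float(m.group(1)) if m else _WFDB_GAIN
    baseline = int(m.group(2)) if m and m.group(2) else 0
    lead = sig[-1] if len(sig) > 9 else "DII"
    adu = np.frombuffer(base.with_suffix(".dat").read_bytes(), dtype="<i2")[:nsamp]
    if adu.size != nsamp:
        raise FormatError(f"{base}.dat: expected {nsamp} samples, found {adu.size}")
    return EcgRecord((adu.astype(float) - baseline) / (gain or _WFDB_GAIN), fs=fs, lead=lead)


def _read_edf_record(path: Path, channel: str | int = 0) -> EcgRecord:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise FormatError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if isinstance(channel, str):
        idx = raw.ch_names.index(channel)
    else:
        idx = int(channel)
    data = raw.get_data(picks=[idx])[0] * 1e3  # mne returns Volts; normalize to mV
    return EcgRecord(data, fs=float(raw.info["sfreq"]), lead=raw.ch_names[idx])


# ----------------------------------------------------------------- events

def read_events(path: str | Path) -> list[EventAnnotation]:
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return []
    need = {"start", "end", "kind"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {need - set(df.columns)}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            EventAnnotation(
                start=float(row.start),
                end=float(row.end),
                kind=str(row.kind),
                mechanism=str(getattr(row, "mechanism", "unknown")),
                confidence=(float(row.confidence)
                            if "confidence" in df.columns and pd.notna(row.confidence)
                            else None),
            )
        )
    return sorted(events, key=lambda e: e.start)


def write_events(events: list[EventAnnotation], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "start": e.start, "end": e.end, "kind": e.kind,
            "mechanism": e.mechanism, "confidence": e.confidence,
        }
        for e in sorted(events, key=lambda e: e.start)
    ]
    pd.DataFrame(rows, columns=["start", "end", "kind", "mechanism", "confidence"]).to_csv(
        path, index=False
    )
    return path


def read_hypnogram(path: str | Path) -> list[str]:
    df = pd.read_csv(path)
    return [str(x) for x in df["label"]]


def write_hypnogram(labels: list[str], path: str | Path, epoch_s: float = 30.0) -> Path:
    pd.DataFrame(
        {"epoch_index": range(len(labels)), "onset_s": [i * epoch_s for i in range(len(labels))],
         "label": labels}
    ).to_csv(path, index=False)
    return Path(path)


def write_report(report, path: str | Path) -> Path:
    """Serialize a ScreeningReport (or any dataclass/dict) to JSON."""
    path = Path(path)
    obj = dataclasses.asdict(report) if dataclasses.is_dataclass(report) else dict(report)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
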