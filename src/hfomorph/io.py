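"""File I/O: signals (CSV, EDF), event tables (CSV), JSON reports.

CSV signal files carry the sampling rate in a ``# fs=<Hz>`` comment line;
event tables use 0-based half-open sample intervals. Output files start
with provenance comment lines (tool version, config hash, seed). The EDF
path is a minimal self-contained reader/writer for single-channel
continuous recordings (16-bit, one data record per second).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import VALID_LABELS, EventWindow, Signal1D

__all__ = [
    "read_signal",
    "write_signal",
    "read_events",
    "write_events",
    "read_edf",
    "write_edf",
    "provenance_lines",
    "config_hash",
]

EVENT_COLUMNS = ("start_sample", "end_sample", "start_s", "end_s", "label", "score")


class FileFormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_lines(config: dict | None = None, seed: int | None = None) -> list[str]:
    from . import __version__

    lines = [f"# hfomorph {__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


# ---------------------------------------------------------------------------
# signals


def write_signal(
    path: str | Path,
    x: Signal1D,
    config: dict | None = None,
    seed: int | None = None,
    channel_name: str = "chan0",
) -> None:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_edf(path, x, channel_name=channel_name)
        return
    header = provenance_lines(config, seed) + [f"# fs={x.fs:g}"]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("sample_index,value\n")
        for i, v in enumerate(x.samples):
            fh.write(f"{i},{v:.10g}\n")


def read_signal(
    path: str | Path, fs_override: float | None = None, channel: str | int | None = None
) -> Signal1D:
    """Load a signal from CSV/TSV (needs fs header or override) or EDF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return read_edf(path, channel=channel)
    if suffix in (".csv", ".tsv", ".txt"):
        return _read_signal_csv(path, fs_override, sep="\t" if suffix == ".tsv" else ",")
    raise FileFormatError(f"unknown signal file extension {suffix!r} (expected .csv/.tsv/.edf)")


def _read_signal_csv(path: Path, fs_override: float | None, sep: str) -> Signal1D:
    fs = fs_override
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            if line.startswith("# fs=") and fs is None:
                fs = float(line.split("=", 1)[1])
    if fs is None:
        raise FileFormatError(
            f"{path}: sampling rate unknown; add a '# fs=<Hz>' header line or pass fs_override"
        )
    try:
        frame = pd.read_csv(path, comment="#", sep=sep)
    except pd.errors.EmptyDataError:
        raise FileFormatError(f"{path}: empty signal") from None
    if frame.shape[0] == 0:
        raise FileFormatError(f"{path}: empty signal")
    column = frame["value"] if "value" in frame.columns else frame.iloc[:, -1]
    return Signal1D(column.to_numpy(dtype=np.float64), fs)


# ---------------------------------------------------------------------------
# events


def write_events(
    events: Sequence[EventWindow],
    path: str | Path,
    fs: float,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    rows = [
        {
            "start_sample": e.start_sample,
            "end_sample": e.end_sample,
            "start_s": e.start_sample / fs,
            "end_s": e.end_sample / fs,
            "label": e.label,
            "score": "" if e.score is None else e.score,
        }
        for e in events
    ]
    frame = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    with open(path, "w") as fh:
        fh.write("\n".join(provenance_lines(config, seed) + [f"# fs={fs:g}"]) + "\n")
        frame.to_csv(fh, index=False)


def read_events(path: str | Path) -> list[EventWindow]:
    """Event table -> EventWindow list; validates schema row by row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event file not found: {path}")
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise FileFormatError(f"{path}: empty event file (missing header)") from None
    missing = [c for c in ("start_sample", "end_sample", "label") if c not in frame.columns]
    if missing:
        raise FileFormatError(f"{path}: missing required columns {missing}")
    events = []
    for i, row in frame.iterrows():
        start, end = int(row["start_sample"]), int(row["end_sample"])
        label = str(row["label"])
        if label not in VALID_LABELS:
            raise FileFormatError(f"{path}: row {i}: unknown label {label!r}")
        if start >= end or start < 0:
            raise FileFormatError(f"{path}: row {i}: invalid interval [{start}, {end})")
        score = row.get("score")
        score = None if score is None or (isinstance(score, float) and np.isnan(score)) else float(score)
        events.append(EventWindow(start_sample=start, end_sample=end, label=label, score=score))
    return events


# ---------------------------------------------------------------------------
# EDF (minimal: continuous, 16-bit, 1-second data records)


def _field(text: str, width: int) -> bytes:
    return text.ljust(width)[:width].encode("ascii")


def write_edf(path: str | Path, x: Signal1D, channel_name: str = "chan0") -> None:
    """Write a single-channel EDF file; requires an integer sampling rate."""
    fs = int(round(x.fs))
    if fs != x.fs or fs <= 0:
        raise FileFormatError(f"EDF writer needs an integer sampling rate, got {x.fs}")
    n = len(x)
    n_records = -(-n // fs)
    padded = np.zeros(n_records * fs)
    padded[:n] = x.samples
    pmax = float(np.max(np.abs(padded)))
    pmax = pmax if pmax > 0 else 1.0
    dmin, dmax = -32768, 32767
    digital = np.round((padded + pmax) / (2 * pmax) * (dmax - dmin) + dmin).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 + 256), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field("1", 4),
            # per-signal header fields
            _field(channel_name, 16),
            _field("", 80),
            _field("uV", 8),
            _field(f"{-pmax:.6g}", 8),
            _field(f"{pmax:.6g}", 8),
            _field(str(dmin), 8),
            _field(str(dmax), 8),
            _field("", 80),
            _field(str(fs), 8),
            _field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def read_edf(path: str | Path, channel: str | int | None = None) -> Signal1D:
    """Read one channel from an EDF file (16-bit continuous records)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FileFormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            n_signals = int(head[252:256].decode("ascii").strip())
        except ValueError:
            raise FileFormatError(f"{path}: malformed EDF header") from None
        sig_head = fh.read(256 * n_signals)
        labels = [
            sig_head[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(n_signals)
        ]
        off = 16 * n_signals

        def fields(width: int) -> list[str]:
            nonlocal off
            out = [
                sig_head[off + width * i : off + width * (i + 1)].decode("ascii").strip()
                for i in range(n_signals)
            ]
            off += width * n_signals
            return out

        fields(80)  # transducer
        fields(8)  # physical dimension
        pmins = [float(v) for v in fields(8)]
        pmaxs = [float(v) for v in fields(8)]
        dmins = [int(v) for v in fields(8)]
        dmaxs = [int(v) for v in fields(8)]
        fields(80)  # prefiltering
        spr = [int(v) for v in fields(8)]  # samples per record

        if channel is None:
            idx = 0
        elif isinstance(channel, int):
            idx = channel
        else:
            if channel not in labels:
                raise FileFormatError(f"{path}: channel {channel!r} not in {labels}")
            idx = labels.index(channel)
        if not 0 <= idx < n_signals:
            raise FileFormatError(f"{path}: channel index {idx} out of range ({n_signals} signals)")

        record_len = sum(spr)
        raw = np.frombuffer(fh.read(2 * record_len * n_records), dtype="<i2")
    if raw.size < record_len * n_records:
        raise FileFormatError(f"{path}: truncated EDF data section")
    records = raw.reshape(n_records, record_len)
    start = sum(spr[:idx])
    digital = records[:, start : start + spr[idx]].ravel().astype(np.float64)
    gain = (pmaxs[idx] - pmins[idx]) / (dmaxs[idx] - dmins[idx])
    physical = (digital - dmins[idx]) * gain + pmins[idx]
    return Signal1D(physical, spr[idx] / record_dur)
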