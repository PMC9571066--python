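"""RMS-envelope candidate event detection (Staba-2002 style rules).

The detector band-pass filters the trace, computes a short moving RMS, and
marks runs that stay a fixed number of standard deviations above the mean
of the baseline RMS. Nearby runs are clustered, short runs dropped, and
each surviving run must additionally show enough supra-threshold peaks in
the rectified filtered trace to count as an oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .core import EventWindow, Signal1D
from .preprocess import BandpassSpec, EnvelopeSpec, bandpass, rectify, rms_envelope

__all__ = ["DetectorParams", "detect_candidates", "confirm_hfo", "staba_detect"]


@dataclass(frozen=True)
class DetectorParams:
    """Detection rule constants.

    Defaults: 80-500 Hz band, 3 ms RMS window, candidate runs > mean + 5 SD
    lasting >= 6 ms after clustering runs separated by < 10 ms, confirmed by
    >= 6 rectified-signal peaks above mean + 3 SD.
    """

    band: tuple[float, float] = (80.0, 500.0)
    rms_window_ms: float = 3.0
    candidate_sd: float = 5.0
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 10.0
    peak_sd: float = 3.0
    min_peaks: int = 6

    def __post_init__(self) -> None:
        for name in ("rms_window_ms", "candidate_sd", "min_duration_ms", "merge_gap_ms", "peak_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")

    def bandpass_spec(self, fs: float) -> BandpassSpec:
        return BandpassSpec(low_hz=self.band[0], high_hz=self.band[1], fs=fs)


def _baseline_slice(n: int, baseline: tuple[int, int] | None) -> slice:
    if baseline is None:
        return slice(0, n)
    start, end = baseline
    if not 0 <= start < end <= n:
        raise ValueError(f"baseline interval {baseline} outside signal of length {n}")
    return slice(start, end)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean mask."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Cluster runs whose separation is strictly less than ``max_gap`` samples."""
    if not runs:
        return []
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def detect_candidates(
    x: Signal1D,
    p: DetectorParams = DetectorParams(),
    baseline: tuple[int, int] | None = None,
) -> list[EventWindow]:
    """Candidate events from the RMS envelope of the band-passed signal.

    ``baseline`` optionally restricts the interval used for the RMS
    mean/SD (defaults to the whole analyzed segment). A degenerate trace
    with zero RMS variance yields an empty list.
    """
    rms = rms_envelope(bandpass(x, p.bandpass_spec(x.fs)), EnvelopeSpec(p.rms_window_ms, "rms"))
    return _candidates_from_rms(rms, p, baseline)


def _candidates_from_rms(
    rms: Signal1D, p: DetectorParams, baseline: tuple[int, int] | None
) -> list[EventWindow]:
    values = rms.samples
    base = values[_baseline_slice(values.size, baseline)]
    sd = float(np.std(base))
    if sd == 0.0:
        return []
    threshold = float(np.mean(base)) + p.candidate_sd * sd
    runs = _runs_above(values > threshold)
    gap = int(round(p.merge_gap_ms * rms.fs / 1000.0))
    min_len = p.min_duration_ms * rms.fs / 1000.0
    merged = _merge_runs(runs, gap)
    return [
        EventWindow(start_sample=int(s), end_sample=int(e))
        for s, e in merged
        if (e - s) >= min_len
    ]


def confirm_hfo(
    x_filtered: Signal1D,
    e: EventWindow,
    p: DetectorParams = DetectorParams(),
    baseline: tuple[int, int] | None = None,
) -> bool:
    """True iff the rectified filtered event segment has enough peaks.

    A peak is a local maximum (plateau centers count once) strictly above
    mean + ``peak_sd`` * SD of the rectified filtered baseline.
    """
    n = len(x_filtered)
    if not 0 <= e.start_sample < e.end_sample <= n:
        raise ValueError(f"event [{e.start_sample}, {e.end_sample}) outside signal of length {n}")
    rect = rectify(x_filtered).samples
    base = rect[_baseline_slice(n, baseline)]
    threshold = float(np.mean(base)) + p.peak_sd * float(np.std(base))
    segment = rect[e.start_sample : e.end_sample]
    peaks, _ = find_peaks(segment)
    return int(np.sum(segment[peaks] > threshold)) >= p.min_peaks


def staba_detect(
    x: Signal1D,
    p: DetectorParams = DetectorParams(),
    baseline: tuple[int, int] | None = None,
) -> list[EventWindow]:
    """Full detection: candidate runs filtered by the peak-count check.

    Surviving events are labeled ``"unlabeled"`` with score = peak RMS value
    inside the event.
    """
    filtered = bandpass(x, p.bandpass_spec(x.fs))
    rms = rms_envelope(filtered, EnvelopeSpec(p.rms_window_ms, "rms"))
    out = []
    for e in _candidates_from_rms(rms, p, baseline):
        if confirm_hfo(filtered, e, p, baseline):
            score = float(np.max(rms.samples[e.start_sample : e.end_sample]))
            out.append(replace(e, score=score))
    return out
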