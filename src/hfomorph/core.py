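"""Shared domain types: sampled signals, event intervals, structuring windows."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

VALID_LABELS = ("ripple", "spike", "sharp_transient", "unlabeled")


def ms_to_odd_samples(width_ms: float, fs: float) -> int:
    """Convert a window length in milliseconds to the nearest odd sample count.

    The result is the odd integer nearest to ``width_ms * fs / 1000``; exact
    ties round upward, and the result is never smaller than 1, so windows are
    always symmetric around a center sample (1 ms at 5 kHz -> 5 samples).
    """
    if width_ms <= 0:
        raise ValueError(f"window length must be positive, got {width_ms} ms")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs} Hz")
    n = width_ms * fs / 1000.0
    # odd integers are 2k+1; pick k = round_half_up((n - 1) / 2)
    k = math.floor((n - 1.0) / 2.0 + 0.5)
    return max(1, 2 * k + 1)


@dataclass(frozen=True)
class StructuringWindow:
    """Flat (zero-height) symmetric structuring element for 1-D morphology.

    Attributes
    ----------
    width_ms
        Nominal window length in milliseconds.
    width_samples
        Realized length in samples; always odd and >= 1.
    """

    width_ms: float
    width_samples: int

    def __post_init__(self) -> None:
        if self.width_samples < 1 or self.width_samples % 2 == 0:
            raise ValueError(
                f"width_samples must be a positive odd integer, got {self.width_samples}"
            )

    @classmethod
    def from_ms(cls, width_ms: float, fs: float) -> "StructuringWindow":
        return cls(width_ms=width_ms, width_samples=ms_to_odd_samples(width_ms, fs))

    @classmethod
    def from_samples(cls, width_samples: int, fs: float | None = None) -> "StructuringWindow":
        width_ms = width_samples / fs * 1000.0 if fs else float(width_samples)
        return cls(width_ms=width_ms, width_samples=int(width_samples))

    @property
    def radius(self) -> int:
        return (self.width_samples - 1) // 2


@dataclass
class Signal1D:
    """A uniformly sampled single-channel signal.

    Attributes
    ----------
    samples
        1-D float array of amplitudes (arbitrary units, typically microvolts).
    fs
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {self.samples.shape}")
        if self.samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "Signal1D":
        return Signal1D(samples=samples, fs=self.fs)


@dataclass(frozen=True)
class EventWindow:
    """Half-open sample interval ``[start_sample, end_sample)`` with a label.

    Sample indices are 0-based. ``label`` is a ground-truth or predicted
    class; freshly detected events carry ``"unlabeled"``.
    """

    start_sample: int
    end_sample: int
    label: str = "unlabeled"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start_sample < 0:
            raise ValueError(f"start_sample must be >= 0, got {self.start_sample}")
        if self.end_sample <= self.start_sample:
            raise ValueError(
                f"end_sample must exceed start_sample "
                f"({self.start_sample}, {self.end_sample})"
            )
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {VALID_LABELS}")

    def duration_ms(self, fs: float) -> float:
        return (self.end_sample - self.start_sample) / fs * 1000.0

    def duration_samples(self) -> int:
        return self.end_sample - self.start_sample

    def overlap(self, other: "EventWindow") -> int:
        """Number of samples shared with ``other``."""
        return max(
            0, min(self.end_sample, other.end_sample) - max(self.start_sample, other.start_sample)
        )

    def relabel(self, label: str) -> "EventWindow":
        return replace(self, label=label)
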