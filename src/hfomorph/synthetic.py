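"""Synthetic labeled recordings: 1/f background, triangular spikes, ripple bursts.

Every stage of the pipeline is testable against these fixtures without any
patient data. All outputs are pure functions of the spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import EventWindow, Signal1D

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_background",
    "make_spike",
    "make_ripple",
    "generate_recording",
]

#: minimum gap enforced between inserted events, ms
EVENT_SEPARATION_MS = 200.0

#: spectral shape exponent of the background (amplitude ~ f^-exponent)
BACKGROUND_EXPONENT = 1.0

#: duration of a spike's fast upstroke, ms (capped at 1/4 of the duration)
SPIKE_RISE_MS = 10.0

#: width of the very fast apex component riding on the spike peak, ms
SPIKE_APEX_MS = 2.4

#: fraction of the peak amplitude carried by the apex component
SPIKE_APEX_FRACTION = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one labeled synthetic recording.

    Spike amplitudes are drawn uniformly from
    ``spike_amplitude_factor_range * background_sd`` (interictal spikes
    tower over the background by an order of magnitude; the lower end must
    stay at or above the ``spike_amplitude_factor_min`` floor). Ripple
    amplitudes get a +/-10% jitter around
    ``ripple_amplitude_factor * background_sd``.
    """

    duration_s: float = 60.0
    fs: float = 5000.0
    background_sd: float = 1.0
    n_spikes: int = 10
    spike_duration_ms_range: tuple[float, float] = (40.0, 200.0)
    spike_amplitude_factor_min: float = 2.0
    spike_amplitude_factor_range: tuple[float, float] = (28.0, 32.0)
    n_ripples: int = 20
    ripple_band_hz: tuple[float, float] = (80.0, 250.0)
    ripple_duration_ms_range: tuple[float, float] = (30.0, 100.0)
    ripple_amplitude_factor: float = 1.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0 or self.background_sd <= 0:
            raise ValueError("duration_s, fs and background_sd must be positive")
        if self.n_spikes < 0 or self.n_ripples < 0:
            raise ValueError("event counts must be non-negative")
        for name in ("spike_duration_ms_range", "ripple_band_hz", "ripple_duration_ms_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be a positive ordered range, got ({lo}, {hi})")
        if self.spike_amplitude_factor_min <= 0 or self.ripple_amplitude_factor <= 0:
            raise ValueError("amplitude factors must be positive")
        lo, hi = self.spike_amplitude_factor_range
        if not 0 < lo <= hi:
            raise ValueError("spike_amplitude_factor_range must be a positive ordered range")
        if lo < self.spike_amplitude_factor_min:
            raise ValueError(
                "spike_amplitude_factor_range must respect the "
                f"spike_amplitude_factor_min floor of {self.spike_amplitude_factor_min}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Labels of the inserted events, sorted by start sample."""

    events: tuple[EventWindow, ...]
    spec: SyntheticSpec

    def by_label(self, label: str) -> list[EventWindow]:
        return [e for e in self.events if e.label == label]


def generate_background(spec: SyntheticSpec) -> Signal1D:
    """Zero-mean 1/f-shaped Gaussian noise, normalized to ``background_sd``.

    Synthesized in the frequency domain: white spectrum shaped by
    ``f^-BACKGROUND_EXPONENT`` (frequencies below 1 Hz clamped), DC removed,
    then rescaled so the sample SD equals ``background_sd`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    shape = np.maximum(freqs, 1.0) ** (-BACKGROUND_EXPONENT)
    shape[0] = 0.0  # zero mean
    shaped = np.fft.irfft(spectrum * shape, n=n)
    sd = shaped.std()
    if sd == 0.0:
        raise ValueError("degenerate background (too short to carry noise)")
    return Signal1D(shaped * (spec.background_sd / sd), spec.fs)


def make_spike(duration_ms: float, amplitude: float, fs: float) -> Signal1D:
    """Asymmetric triangular pulse: fast rise, slow fall; peaks at ``amplitude``.

    The upstroke lasts ``SPIKE_RISE_MS`` (never more than 1/4 of the
    duration); the remainder is the slow falling wave. A fixed fast
    upstroke (rather than one proportional to duration) is what gives an
    interictal spike its sharp character: it makes the rectified first
    difference depend on amplitude alone and lets a band-pass filter ring
    on the apex regardless of how long the slow wave is. A very fast apex
    component (``SPIKE_APEX_MS`` wide, ``SPIKE_APEX_FRACTION`` of the peak)
    supplies the mid-band energy real spikes carry at their tip.
    """
    if duration_ms <= 0 or amplitude <= 0 or fs <= 0:
        raise ValueError("duration_ms, amplitude and fs must be positive")
    n = max(3, int(round(duration_ms * fs / 1000.0)))
    rise_ms = min(SPIKE_RISE_MS, duration_ms / 4.0)
    apex = min(n - 2, max(1, int(round(rise_ms * fs / 1000.0))))
    t = np.arange(n, dtype=np.float64)
    beta = SPIKE_APEX_FRACTION
    samples = np.interp(t, [0.0, float(apex), float(n - 1)], [0.0, (1.0 - beta) * amplitude, 0.0])
    half = max(1, int(round(SPIKE_APEX_MS * fs / 2000.0)))
    lo, hi = max(0, apex - half), min(n - 1, apex + half)
    samples[lo : hi + 1] += np.interp(
        np.arange(lo, hi + 1, dtype=np.float64),
        [float(lo), float(apex), float(hi)],
        [0.0, beta * amplitude, 0.0],
    )
    return Signal1D(samples, fs)


def make_ripple(freq_hz: float, duration_ms: float, amplitude: float, fs: float) -> Signal1D:
    """Hann-windowed cosine burst peaking at ``amplitude`` at its center."""
    if freq_hz <= 0 or duration_ms <= 0 or amplitude <= 0 or fs <= 0:
        raise ValueError("freq_hz, duration_ms, amplitude and fs must be positive")
    n = max(3, int(round(duration_ms * fs / 1000.0)))
    t = np.arange(n, dtype=np.float64)
    center = (n - 1) / 2.0
    hann = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / (n - 1)))
    carrier = np.cos(2.0 * np.pi * freq_hz * (t - center) / fs)
    return Signal1D(amplitude * hann * carrier, fs)


def _place_events(
    lengths: Sequence[int], n_total: int, fs: float, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping random starts with the minimum separation; seeded."""
    sep = int(round(EVENT_SEPARATION_MS * fs / 1000.0))
    starts: list[int] = []
    occupied: list[tuple[int, int]] = []
    for length in lengths:
        hi = n_total - length
        if hi <= 0:
            raise ValueError("recording too short for requested events; increase duration_s")
        for _ in range(10000):
            s = int(rng.integers(0, hi))
            # [s, s+length) must sit at least `sep` samples away from every [a, b)
            if all(s + length + sep <= a or b + sep <= s for a, b in occupied):
                starts.append(s)
                occupied.append((s, s + length))
                break
        else:
            raise ValueError(
                "could not place events with the required separation; increase duration_s"
            )
    return starts


def generate_recording(spec: SyntheticSpec) -> tuple[Signal1D, GroundTruth]:
    """Background plus inserted spikes and ripples, with exact ground truth.

    Event windows cover exactly the support of each inserted waveform.
    Spikes are drawn first, then ripples, from an rng seeded by
    ``spec.seed`` (the background uses the same seed independently).
    """
    bg = generate_background(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n_total = len(bg)

    waveforms: list[np.ndarray] = []
    labels: list[str] = []
    for _ in range(spec.n_spikes):
        dur = rng.uniform(*spec.spike_duration_ms_range)
        amp = rng.uniform(*spec.spike_amplitude_factor_range) * spec.background_sd
        waveforms.append(make_spike(dur, amp, spec.fs).samples)
        labels.append("spike")
    for _ in range(spec.n_ripples):
        freq = rng.uniform(*spec.ripple_band_hz)
        dur = rng.uniform(*spec.ripple_duration_ms_range)
        amp = rng.uniform(0.9, 1.1) * spec.ripple_amplitude_factor * spec.background_sd
        waveforms.append(make_ripple(freq, dur, amp, spec.fs).samples)
        labels.append("ripple")

    starts = _place_events([w.size for w in waveforms], n_total, spec.fs, rng)
    samples = bg.samples.copy()
    events = []
    for wave, label, start in zip(waveforms, labels, starts):
        samples[start : start + wave.size] += wave
        events.append(EventWindow(start_sample=start, end_sample=start + wave.size, label=label))
    events.sort(key=lambda e: e.start_sample)
    return Signal1D(samples, spec.fs), GroundTruth(events=tuple(events), spec=spec)
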