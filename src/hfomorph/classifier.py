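"""Spike-vs-ripple classification with a dynamic morphological threshold.

Per event, the raw trace around the event is reduced to a feature signal
(smoothed rectified first difference). A short closing envelopes it; an
opening truncates narrow peaks. The classification threshold is not fixed:
it is the maximum truncated level observed across a training set, so it
adapts to the spike shapes actually present. Events whose closing-envelope
peak exceeds the threshold are called spikes; the rest ripples.

The opening window size is the one free parameter; ``sweep_open_windows``
scores a grid of sizes by sensitivity / false detection rate so callers can
pick the ROC-optimal one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import EventWindow, Signal1D, StructuringWindow
from .morphology import closing, opening
from .preprocess import EnvelopeSpec, moving_average, rectified_first_difference

__all__ = [
    "MorphParams",
    "EventFeatures",
    "DynamicThreshold",
    "DEFAULT_SWEEP_MS",
    "feature_signal",
    "extract_features",
    "fit_threshold",
    "classify_event",
    "sweep_open_windows",
]

#: opening window sizes (ms) scored by default, 1-8 ms
DEFAULT_SWEEP_MS: tuple[float, ...] = (1, 2, 3, 3.4, 4, 4.6, 5, 5.4, 6, 7, 8)


@dataclass(frozen=True)
class MorphParams:
    """Feature-extraction constants (all in milliseconds).

    ``smooth_ms`` — moving-average width for the feature signal;
    ``close_ms`` — closing window (enveloping);
    ``open_ms`` — opening window (truncation), the swept parameter;
    ``context_ms`` — raw-signal context taken on each side of an event.
    """

    smooth_ms: float = 10.0
    close_ms: float = 1.0
    open_ms: float = 4.0
    context_ms: float = 100.0

    def __post_init__(self) -> None:
        for name in ("smooth_ms", "close_ms", "open_ms", "context_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EventFeatures:
    """Morphological features of one event.

    ``envelope_peak`` is the maximum of the closed feature signal over the
    core event; ``truncated_level`` the maximum of its opening. Opening is
    anti-extensive, so ``truncated_level <= envelope_peak`` always.
    """

    envelope_peak: float
    truncated_level: float
    open_ms_used: float

    def __post_init__(self) -> None:
        if self.truncated_level > self.envelope_peak + 1e-12:
            raise ValueError("truncated_level cannot exceed envelope_peak")


@dataclass(frozen=True)
class DynamicThreshold:
    """Spike threshold: the maximum truncated level over a training set."""

    value: float
    n_training_events: int
    open_ms: float

    def __post_init__(self) -> None:
        if self.n_training_events < 1:
            raise ValueError("threshold must be fitted on at least one event")


def _context_bounds(x: Signal1D, e: EventWindow, mp: MorphParams) -> tuple[int, int]:
    ctx = int(round(mp.context_ms * x.fs / 1000.0))
    if not 0 <= e.start_sample < e.end_sample <= len(x):
        raise ValueError(
            f"event [{e.start_sample}, {e.end_sample}) outside signal of length {len(x)}"
        )
    return max(0, e.start_sample - ctx), min(len(x), e.end_sample + ctx)


def feature_signal(x: Signal1D, e: EventWindow, mp: MorphParams = MorphParams()) -> Signal1D:
    """Smoothed rectified first difference of the event's raw context.

    The event plus ``context_ms`` on each side (clamped to the recording) is
    cut from the raw signal; |diff| manifests sharp transients against the
    background, and the moving average smooths it.
    """
    lo, hi = _context_bounds(x, e, mp)
    segment = Signal1D(x.samples[lo:hi], x.fs)
    d = rectified_first_difference(segment)
    return moving_average(d, EnvelopeSpec(mp.smooth_ms, "moving_average"))


def extract_features(
    x: Signal1D, e: EventWindow, mp: MorphParams = MorphParams()
) -> EventFeatures:
    """Closing-envelope peak and opened (truncated) level over the core event."""
    env, core = _envelope_and_core(x, e, mp)
    return _features_from_envelope(env, core, mp.open_ms)


def _envelope_and_core(
    x: Signal1D, e: EventWindow, mp: MorphParams
) -> tuple[Signal1D, slice]:
    """Closed feature signal plus the slice covering the core event samples.

    Split out so the opening-window sweep can reuse the (window-independent)
    envelope instead of recomputing it per window size.
    """
    lo, _ = _context_bounds(x, e, mp)
    s = feature_signal(x, e, mp)
    env = closing(s, StructuringWindow.from_ms(mp.close_ms, x.fs))
    return env, slice(e.start_sample - lo, e.end_sample - lo)


def _features_from_envelope(env: Signal1D, core: slice, open_ms: float) -> EventFeatures:
    truncated = opening(env, StructuringWindow.from_ms(open_ms, env.fs))
    return EventFeatures(
        envelope_peak=float(np.max(env.samples[core])),
        truncated_level=float(np.max(truncated.samples[core])),
        open_ms_used=open_ms,
    )


def fit_threshold(
    training: Sequence[tuple[Signal1D, EventWindow]], mp: MorphParams = MorphParams()
) -> DynamicThreshold:
    """Dynamic threshold: max truncated level over all training events."""
    if len(training) == 0:
        raise ValueError("cannot fit a threshold on an empty training set")
    levels = [extract_features(x, e, mp).truncated_level for x, e in training]
    return DynamicThreshold(
        value=float(max(levels)), n_training_events=len(training), open_ms=mp.open_ms
    )


def classify_event(f: EventFeatures, th: DynamicThreshold) -> str:
    """``"spike"`` iff the envelope peak strictly exceeds the threshold."""
    if f.open_ms_used != th.open_ms:
        raise ValueError(
            f"feature opening window {f.open_ms_used} ms does not match "
            f"threshold opening window {th.open_ms} ms"
        )
    return "spike" if f.envelope_peak > th.value else "ripple"


def sweep_open_windows(
    training: Sequence[tuple[Signal1D, EventWindow]],
    windows_ms: Sequence[float] = DEFAULT_SWEEP_MS,
    mp: MorphParams = MorphParams(),
):
    """Refit + self-classify the training set at each opening window size.

    Training events must carry ground-truth labels in {"spike", "ripple"}.
    Returns one :class:`~hfomorph.evaluation.ROCPoint` per window.
    """
    points, _ = sweep_with_counts(training, windows_ms, mp)
    return points


def sweep_with_counts(
    training: Sequence[tuple[Signal1D, EventWindow]],
    windows_ms: Sequence[float] = DEFAULT_SWEEP_MS,
    mp: MorphParams = MorphParams(),
):
    """Like :func:`sweep_open_windows` but also returns per-window confusion counts."""
    from .evaluation import ROCPoint, confusion, fdr, roc_distance, sensitivity

    truth = [e.label for _, e in training]
    if "spike" not in truth:
        raise ValueError("sweep needs at least one ground-truth spike (SE undefined otherwise)")
    bad = sorted(set(truth) - {"spike", "ripple"})
    if bad:
        raise ValueError(f"training labels must be 'spike' or 'ripple', got {bad}")

    cached = [_envelope_and_core(x, e, mp) for x, e in training]
    points, counts = [], []
    for w in windows_ms:
        feats = [_features_from_envelope(env, core, w) for env, core in cached]
        th = DynamicThreshold(
            value=max(f.truncated_level for f in feats),
            n_training_events=len(feats),
            open_ms=w,
        )
        predicted = [classify_event(f, th) for f in feats]
        c = confusion(predicted, truth)
        se = sensitivity(c)
        # no spike calls at all -> no false detections; avoid 0/0
        fd = fdr(c) if (c.fp + c.tp) > 0 else 0.0
        points.append(
            ROCPoint(window_ms=float(w), sensitivity=se, fdr=fd, distance=roc_distance(se, fd))
        )
        counts.append(c)
    return points, counts
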