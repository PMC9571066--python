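"""Event-level evaluation: confusion counts, SE/FDR, ROC point selection, CV.

Spikes are the positive class: a true positive is a spike detected as a
spike, a false positive a ripple detected as a spike. Sensitivity is
TP/(TP+FN); the false detection rate is FP/(FP+TP). The ROC operating
point for an opening-window size is its (FDR, SE) pair, and the best window
is the one nearest the ideal point (FDR=0, SE=1) in Euclidean distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EventWindow, Signal1D

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "ROCPoint",
    "CrossValidationSummary",
    "confusion",
    "sensitivity",
    "fdr",
    "roc_distance",
    "select_optimal_window",
    "cross_validate",
    "label_candidates",
    "round_percent",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with spike as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    fdr: float


@dataclass(frozen=True)
class ROCPoint:
    """(window size, SE, FDR) operating point with its distance to (0, 1)."""

    window_ms: float
    sensitivity: float
    fdr: float
    distance: float


def confusion(predicted: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Count TP/FP/TN/FN from parallel predicted and true label sequences."""
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if p not in ("spike", "ripple") or t not in ("spike", "ripple"):
            raise ValueError(f"labels must be 'spike' or 'ripple', got ({p!r}, {t!r})")
        if t == "spike":
            tp += p == "spike"
            fn += p == "ripple"
        else:
            fp += p == "spike"
            tn += p == "ripple"
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); raises on an empty positive class."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no ground-truth spikes (TP+FN=0)")
    return c.tp / (c.tp + c.fn)


def fdr(c: ConfusionCounts) -> float:
    """FP / (FP + TP); raises when nothing was called a spike."""
    if c.fp + c.tp == 0:
        raise ZeroDivisionError("FDR undefined: no spike detections (FP+TP=0)")
    return c.fp / (c.fp + c.tp)


def roc_distance(se: float, fdr_value: float) -> float:
    """Euclidean distance from the operating point (FDR, SE) to ideal (0, 1)."""
    if not 0.0 <= se <= 1.0:
        raise ValueError(f"sensitivity must lie in [0, 1], got {se}")
    if not 0.0 <= fdr_value <= 1.0:
        raise ValueError(f"FDR must lie in [0, 1], got {fdr_value}")
    return math.hypot(fdr_value, 1.0 - se)


def select_optimal_window(points: Sequence[ROCPoint]) -> ROCPoint:
    """Point with minimal distance to (0, 1); ties go to the smaller window."""
    if not points:
        raise ValueError("cannot select from an empty ROC point list")
    return min(points, key=lambda p: (p.distance, p.window_ms))


def round_percent(fraction: float) -> int:
    """Fraction -> integer percent, rounding half away from zero."""
    scaled = fraction * 100.0
    return int(math.floor(scaled + 0.5)) if scaled >= 0 else -int(math.floor(-scaled + 0.5))


def label_candidates(
    candidates: Sequence[EventWindow],
    truth: Sequence[EventWindow],
    min_overlap: float = 0.0,
) -> list[EventWindow]:
    """Copy candidates relabeled by their best-overlapping truth event.

    A candidate inherits the label of the truth event it shares the most
    samples with, provided the overlap covers more than ``min_overlap`` of
    that truth event; otherwise it stays ``"unlabeled"``.
    """
    out = []
    for c in candidates:
        best, best_ov = None, 0
        for t in truth:
            ov = c.overlap(t)
            if ov > best_ov:
                best, best_ov = t, ov
        if best is not None and best_ov > min_overlap * best.duration_samples():
            out.append(c.relabel(best.label))
        else:
            out.append(c.relabel("unlabeled"))
    return out


@dataclass(frozen=True)
class CrossValidationSummary:
    """Aggregate of repeated stratified train/test evaluation."""

    sensitivities: tuple[float, ...]
    fdrs: tuple[float, ...]
    optimal_windows_ms: tuple[float, ...]
    mean_sensitivity: float
    sd_sensitivity: float
    mean_fdr: float
    sd_fdr: float
    modal_window_ms: float


def _stratified_split(
    labels: Sequence[str], train_fraction: float, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    train, test = [], []
    labels = np.asarray(labels)
    for cls in ("spike", "ripple"):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = max(1, int(round(train_fraction * idx.size)))
        n_train = min(n_train, idx.size - 1) if idx.size > 1 else n_train
        train.extend(int(i) for i in idx[:n_train])
        test.extend(int(i) for i in idx[n_train:])
    return sorted(train), sorted(test)


def cross_validate(
    events: Sequence[tuple[Signal1D, EventWindow]],
    n_repeats: int = 10,
    train_fraction: float = 0.5,
    seed: int = 0,
    windows_ms: Sequence[float] | None = None,
    mp=None,
    max_retries: int = 20,
) -> CrossValidationSummary:
    """Repeated stratified split -> window sweep on train -> test SE/FDR.

    Each repeat sweeps the opening windows on the training half, picks the
    ROC-optimal window, refits the dynamic threshold at that window on the
    training half, and scores the held-out half. Fully determined by
    ``seed``.
    """
    from .classifier import (
        DEFAULT_SWEEP_MS,
        MorphParams,
        classify_event,
        extract_features,
        fit_threshold,
        sweep_open_windows,
    )

    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    labels = [e.label for _, e in events]
    if "spike" not in labels or "ripple" not in labels:
        raise ValueError("cross-validation needs both spike and ripple events")
    windows_ms = DEFAULT_SWEEP_MS if windows_ms is None else windows_ms
    mp = MorphParams() if mp is None else mp

    rng = np.random.default_rng(seed)
    ses, fds, wins = [], [], []
    for _ in range(n_repeats):
        for _attempt in range(max_retries):
            train_idx, test_idx = _stratified_split(labels, train_fraction, rng)
            test_labels = [labels[i] for i in test_idx]
            if "spike" in test_labels and any(l == "spike" for l in (labels[i] for i in train_idx)):
                break
        else:
            raise RuntimeError(f"no valid split with test spikes after {max_retries} retries")
        train = [events[i] for i in train_idx]
        test = [events[i] for i in test_idx]
        points = sweep_open_windows(train, windows_ms, mp)
        best = select_optimal_window(points)
        mp_best = MorphParams(
            smooth_ms=mp.smooth_ms,
            close_ms=mp.close_ms,
            open_ms=best.window_ms,
            context_ms=mp.context_ms,
        )
        th = fit_threshold(train, mp_best)
        predicted = [classify_event(extract_features(x, e, mp_best), th) for x, e in test]
        c = confusion(predicted, test_labels)
        ses.append(sensitivity(c))
        fds.append(fdr(c) if (c.fp + c.tp) > 0 else 0.0)
        wins.append(best.window_ms)

    values, counts = np.unique(wins, return_counts=True)
    modal = float(values[np.argmax(counts)])
    return CrossValidationSummary(
        sensitivities=tuple(ses),
        fdrs=tuple(fds),
        optimal_windows_ms=tuple(wins),
        mean_sensitivity=float(np.mean(ses)),
        sd_sensitivity=float(np.std(ses)),
        mean_fdr=float(np.mean(fds)),
        sd_fdr=float(np.std(fds)),
        modal_window_ms=modal,
    )
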