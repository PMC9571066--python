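"""Exact 1-D flat grayscale morphology.

Erosion and dilation are centered sliding minima/maxima under a flat
symmetric structuring element, with boundary samples replicated outside the
signal domain. The fast path uses the van Herk / Gil-Werman decomposition
(O(n), independent of window size); ``brute_force_extremum`` is the naive
O(n*w) reference the fast path must match sample-for-sample.
"""

from __future__ import annotations

import numpy as np

from .core import Signal1D, StructuringWindow

__all__ = [
    "erosion",
    "dilation",
    "opening",
    "closing",
    "brute_force_extremum",
    "sliding_extremum",
]


def _check(x: Signal1D, w: StructuringWindow) -> None:
    if len(x) < 1:
        raise ValueError("empty signal")
    if w.width_samples < 1:
        raise ValueError("non-positive structuring window")


def _van_herk(values: np.ndarray, width: int, mode: str) -> np.ndarray:
    """van Herk sliding extremum with edge replication; exact order statistics."""
    if width == 1:
        return values.copy()
    op = np.minimum if mode == "min" else np.maximum
    fill = np.inf if mode == "min" else -np.inf
    n = values.size
    r = (width - 1) // 2
    padded = np.pad(values, r, mode="edge")
    m = padded.size
    # pad to a whole number of blocks of `width` so the reshape is legal
    n_blocks = -(-m // width)
    buf = np.full(n_blocks * width, fill)
    buf[:m] = padded
    blocks = buf.reshape(n_blocks, width)
    prefix = op.accumulate(blocks, axis=1).ravel()
    suffix = op.accumulate(blocks[:, ::-1], axis=1)[:, ::-1].ravel()
    # window starting at padded index i spans padded[i : i + width]
    return op(suffix[:n], prefix[width - 1 : width - 1 + n])


def sliding_extremum(values: np.ndarray, width: int, mode: str) -> np.ndarray:
    """Centered sliding min/max over raw samples (array-level fast path)."""
    if mode not in ("min", "max"):
        raise ValueError(f"mode must be 'min' or 'max', got {mode!r}")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty signal")
    if width < 1 or width % 2 == 0:
        raise ValueError(f"window width must be a positive odd integer, got {width}")
    return _van_herk(values, width, mode)


def erosion(x: Signal1D, w: StructuringWindow) -> Signal1D:
    """Sliding minimum of ``x`` over the centered window of ``w``."""
    _check(x, w)
    return x.with_samples(sliding_extremum(x.samples, w.width_samples, "min"))


def dilation(x: Signal1D, w: StructuringWindow) -> Signal1D:
    """Sliding maximum of ``x`` over the centered window of ``w``."""
    _check(x, w)
    return x.with_samples(sliding_extremum(x.samples, w.width_samples, "max"))


def closing(x: Signal1D, w: StructuringWindow) -> Signal1D:
    """Dilation followed by erosion: fills valleys narrower than the window.

    Extensive (result >= input pointwise) and idempotent.
    """
    return erosion(dilation(x, w), w)


def opening(x: Signal1D, w: StructuringWindow) -> Signal1D:
    """Erosion followed by dilation: truncates peaks narrower than the window.

    Anti-extensive (result <= input pointwise) and idempotent.
    """
    return dilation(erosion(x, w), w)


def brute_force_extremum(x: Signal1D, w: StructuringWindow, mode: str) -> Signal1D:
    """Naive O(n*w) centered sliding extremum; the reference semantics.

    Kept deliberately independent of the fast path: indexing into an
    edge-padded copy, one ``min``/``max`` per output sample.
    """
    _check(x, w)
    if mode not in ("min", "max"):
        raise ValueError(f"mode must be 'min' or 'max', got {mode!r}")
    reduce = np.min if mode == "min" else np.max
    r = w.radius
    padded = np.pad(x.samples, r, mode="edge")
    out = np.empty(len(x))
    for i in range(len(x)):
        out[i] = reduce(padded[i : i + w.width_samples])
    return x.with_samples(out)
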