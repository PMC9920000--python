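"""Low-pass filtering of inertial channels and rest/walking segmentation.

Human walking kinematics live below ~4 Hz, so channels are filtered with a
fourth-order Butterworth low-pass at 5 Hz before any event detection or
feature extraction.  Filtering is applied forward-backward (zero phase) so
gait-event timing is not shifted by group delay.

Rest detection uses the empirical rule that the rolling standard deviation of
the acceleration magnitude stays below 1 m/s^2 whenever the wearer is not
walking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt


@dataclass
class WalkMask:
    """Per-sample walking mask plus its run-length segments.

    ``segments`` is a list of (start, end) index pairs (half-open) exactly
    covering the True samples, disjoint and sorted.
    """

    mask: np.ndarray
    segments: list

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def walking_fraction(self) -> float:
        return float(self.mask.mean()) if len(self.mask) else 0.0


def _mask_to_segments(mask: np.ndarray) -> list:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(s), int(e)) for s, e in zip(idx[::2], idx[1::2])]


def butterworth_lowpass(channel: np.ndarray, fs: float, cutoff: float = 5.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter of one or more channels.

    ``channel`` may be 1-D or (n, k); filtering runs along axis 0.
    """
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist frequency {fs / 2} Hz")
    channel = np.asarray(channel, dtype=float)
    if channel.shape[0] <= 3 * (order + 1):
        raise ValueError("signal too short for the requested filter order")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return filtfilt(b, a, channel, axis=0)


def acceleration_magnitude(accel: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm ||a|| of an (n, 3) acceleration series."""
    return np.linalg.norm(np.asarray(accel, dtype=float), axis=-1)


def rolling_std(x: np.ndarray, n: int) -> np.ndarray:
    """Centered rolling population standard deviation over an ``n``-sample window.

    Edge windows shrink to the available samples.
    """
    x = np.asarray(x, dtype=float)
    half = n // 2
    c1 = np.cumsum(np.concatenate(([0.0], x)))
    c2 = np.cumsum(np.concatenate(([0.0], x * x)))
    i = np.arange(len(x))
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, len(x))
    cnt = hi - lo
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = np.maximum(s2 / cnt - (s1 / cnt) ** 2, 0.0)
    return np.sqrt(var)


def detect_walking(
    magnitude: np.ndarray,
    fs: float,
    threshold: float = 1.0,
    window: float = 1.0,
    min_walk: float = 2.0,
) -> WalkMask:
    """Label each sample walking/rest from the rolling std of ||a||.

    A sample is walking iff the centered rolling standard deviation (window
    ``window`` seconds) of the acceleration magnitude is at least
    ``threshold`` m/s^2.  Walking runs shorter than ``min_walk`` seconds are
    relabeled rest to suppress boundary flicker.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    n_win = int(round(window * fs))
    if n_win < 2:
        raise ValueError("window * fs must be >= 2")
    if len(magnitude) < n_win:
        warnings.warn("series shorter than one rolling window; returning all-rest mask")
        mask = np.zeros(len(magnitude), dtype=bool)
        return WalkMask(mask=mask, segments=[])

    mask = rolling_std(magnitude, n_win) >= threshold
    min_n = int(round(min_walk * fs))
    segments = []
    for s, e in _mask_to_segments(mask):
        if e - s < min_n:
            mask[s:e] = False
        else:
            segments.append((s, e))
    return WalkMask(mask=mask, segments=segments)
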