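"""Gait-event detection via singular spectrum analysis of Earth-frame acceleration.

The detector decomposes the vertical (Y) and anterior-posterior (Z)
acceleration with SSA (Hankel trajectory matrix, SVD, diagonal averaging),
removes low-frequency trend components, and exploits the step periodicity of
the dominant vertical oscillation:

1. local minima of the dominant Y oscillation locate one candidate interval
   per step;
2. within a refinement interval around each minimum, the sample minimizing
   the product of the reconstructed Y and Z signals is the heel contact;
3. right/left parity is decided once from the first three dominant-oscillation
   minima — if the mean of the reconstructed Y signal between the first and
   second minima exceeds the mean between the second and third, the first
   contact is a right heel contact — and then alternates;
4. the right toe-off is the first local minimum of reconstructed Y after a
   left heel contact, the left toe-off the last local maximum before it.

Left/right labels are phone-side-relative: the pocket side produces the
larger ipsilateral signal, and the parity rule keys on that asymmetry; no
anatomical left/right is claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema, periodogram


# ---------------------------------------------------------------------------
# Singular spectrum analysis

@dataclass
class SsaDecomposition:
    """SSA of a series: elementary components ordered by singular value.

    The sum of all components reconstructs the input exactly (diagonal
    averaging is a partition of the trajectory matrix).  ``eigenvalues`` are
    squared singular values of the trajectory matrix, sorted descending.
    """

    embedding_length: int
    eigenvalues: np.ndarray
    components: np.ndarray  # (n_components, n_samples)
    signal: np.ndarray
    fs: float

    def reconstruct(self, indices) -> np.ndarray:
        return self.components[list(indices)].sum(axis=0)


def ssa_decompose(signal: np.ndarray, L: int, fs: float = 50.0) -> SsaDecomposition:
    """Standard SSA: Hankel embedding, SVD, diagonal-averaged components."""
    x = np.asarray(signal, dtype=float)
    N = len(x)
    if not 2 <= L <= N // 2:
        raise ValueError(f"embedding length L={L} must satisfy 2 <= L <= N/2 (N={N})")
    K = N - L + 1
    # trajectory matrix X[i, j] = x[i + j], shape (L, K)
    X = np.lib.stride_tricks.sliding_window_view(x, K)  # (L, K) rows are lags
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # diagonal averaging of each rank-1 term sigma * u v^T: the anti-diagonal
    # means are a convolution of u and v divided by the diagonal lengths.
    counts = np.minimum(np.minimum(np.arange(1, N + 1), L), np.minimum(N - np.arange(N), K))
    comps = np.empty((len(s), N))
    for i in range(len(s)):
        comps[i] = np.convolve(s[i] * U[:, i], Vt[i]) / counts
    return SsaDecomposition(
        embedding_length=L,
        eigenvalues=s**2,
        components=comps,
        signal=x,
        fs=fs,
    )


def _dominant_frequency(component: np.ndarray, fs: float) -> float:
    f, p = periodogram(component, fs=fs, detrend=False)
    return float(f[np.argmax(p)])


def remove_trend(decomp: SsaDecomposition, trend_cutoff_hz: float = 0.5) -> tuple:
    """Split the series into (detrended, trend).

    Trend is the group of components whose periodogram peak lies below
    ``trend_cutoff_hz`` (sub-gait frequencies: posture drift, slow turns).
    An empty trend group is allowed.
    """
    trend = np.zeros_like(decomp.signal)
    total = float(np.sum(decomp.signal**2)) + 1e-30
    for i in range(decomp.components.shape[0]):
        comp = decomp.components[i]
        if np.sum(comp**2) / total < 1e-12:
            continue
        if _dominant_frequency(comp, decomp.fs) < trend_cutoff_hz:
            trend = trend + comp
    return decomp.signal - trend, trend


def dominant_oscillation(detrended: np.ndarray, L: int, fs: float = 50.0) -> np.ndarray:
    """Reconstruction from the leading SSA eigen-group of the detrended signal.

    A pure oscillation occupies a quadrature pair of nearly equal singular
    values; the partner component (singular-value ratio >= 0.7) is included so
    the reconstruction is phase-faithful to the input oscillation.
    """
    decomp = ssa_decompose(detrended, L, fs=fs)
    s = np.sqrt(decomp.eigenvalues)
    group = [0]
    if len(s) > 1 and s[1] >= 0.7 * s[0]:
        group.append(1)
    return decomp.reconstruct(group)


# ---------------------------------------------------------------------------
# Events

@dataclass
class GaitEvents:
    """Ordered sample indices of the four gait events."""

    rhc: np.ndarray
    lhc: np.ndarray
    rto: np.ndarray
    lto: np.ndarray
    fs: float

    def __post_init__(self):
        for name in ("rhc", "lhc", "rto", "lto"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))

    @property
    def n_heel_contacts(self) -> int:
        return len(self.rhc) + len(self.lhc)

    def merged_contacts(self) -> np.ndarray:
        return np.sort(np.concatenate([self.rhc, self.lhc]))


@dataclass
class GaitCycle:
    """One stride: between two consecutive right heel contacts."""

    start: int
    end: int
    fs: float
    rto: int | None = None
    lhc: int | None = None
    lto: int | None = None

    @property
    def stride_time(self) -> float:
        return (self.end - self.start) / self.fs

    @property
    def stance_time(self) -> float | None:
        if self.rto is None:
            return None
        return (self.rto - self.start) / self.fs

    @property
    def swing_time(self) -> float | None:
        if self.rto is None:
            return None
        return (self.end - self.rto) / self.fs


def _extrema(y: np.ndarray, order: int, kind: str) -> np.ndarray:
    comparator = np.less if kind == "min" else np.greater
    idx = argrelextrema(y, comparator, order=max(1, order))[0]
    return idx


def _step_period_samples(y_dom: np.ndarray, fs: float) -> float:
    f = _dominant_frequency(y_dom - y_dom.mean(), fs)
    if f <= 0:
        return fs  # fall back to 1 s
    return fs / f


def detect_heel_contacts(
    y_dom: np.ndarray,
    y_rec: np.ndarray,
    z_rec: np.ndarray,
    fs: float,
) -> np.ndarray:
    """Candidate heel-contact indices from the dominant-oscillation minima.

    Around each minimum of the dominant Y oscillation, the heel contact is
    the index minimizing ``y_rec * z_rec`` within a refinement interval of
    +/- 25% of the median inter-minimum spacing.  Returns an empty array when
    fewer than three minima exist (no usable gait in the window).
    """
    if len(y_dom) != len(y_rec) or len(y_rec) != len(z_rec):
        raise ValueError("series must be aligned and of equal length")
    period = _step_period_samples(y_dom, fs)
    order = max(2, int(round(0.25 * period)))
    minima = _extrema(y_dom, order, "min")
    if len(minima) < 3:
        return np.array([], dtype=int)
    half = max(1, int(round(0.25 * float(np.median(np.diff(minima))))))
    product = y_rec * z_rec
    contacts = []
    for m in minima:
        lo = max(0, m - half)
        hi = min(len(product), m + half + 1)
        contacts.append(lo + int(np.argmin(product[lo:hi])))
    contacts = np.unique(contacts)
    return contacts


def dominant_minima(y_dom: np.ndarray, fs: float) -> np.ndarray:
    """Order-filtered local minima of the dominant oscillation."""
    period = _step_period_samples(y_dom, fs)
    return _extrema(y_dom, max(2, int(round(0.25 * period))), "min")


def assign_left_right(
    contacts: np.ndarray,
    y_rec: np.ndarray,
    y_dom_minima: np.ndarray,
) -> tuple:
    """Split contacts into (rhc, lhc) by the mean-amplitude parity rule.

    Parity is decided once from the first three dominant-oscillation minima:
    if mean(y_rec) over [m0, m1) exceeds mean over [m1, m2), the first contact
    is a right heel contact; labels then alternate.  Ties default to
    first-is-right with a warning.
    """
    contacts = np.asarray(contacts, dtype=int)
    if len(contacts) < 3 or len(y_dom_minima) < 3:
        raise ValueError("need at least 3 contacts and 3 dominant minima")
    m0, m1, m2 = y_dom_minima[:3]
    mean1 = float(np.mean(y_rec[m0:m1]))
    mean2 = float(np.mean(y_rec[m1:m2]))
    if abs(mean1 - mean2) < 1e-9:
        warnings.warn("parity tie in left/right rule; defaulting to first-contact-is-right")
        first_is_right = True
    else:
        first_is_right = mean1 > mean2
    start = 0 if first_is_right else 1
    return contacts[start::2], contacts[1 - start::2]


def detect_toe_offs(
    rhc: np.ndarray,
    lhc: np.ndarray,
    y_rec: np.ndarray,
    fs: float = 50.0,
) -> tuple:
    """(rto, lto) from reconstructed-Y extrema around each left heel contact.

    For every LHC bracketed by right heel contacts: the right toe-off is the
    first local minimum of ``y_rec`` strictly after the LHC (before the next
    RHC); the left toe-off is the last local maximum strictly before the LHC
    (after the preceding RHC).  Cycles without a qualifying extremum simply
    carry no toe-off.
    """
    rhc = np.asarray(rhc, dtype=int)
    lhc = np.asarray(lhc, dtype=int)
    if len(rhc) < 2 or len(lhc) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    contacts = np.sort(np.concatenate([rhc, lhc]))
    spacing = float(np.median(np.diff(contacts))) if len(contacts) > 1 else fs
    order = max(2, int(round(0.25 * spacing)))
    minima = _extrema(y_rec, order, "min")
    maxima = _extrema(y_rec, order, "max")
    rto, lto = [], []
    for l in lhc:
        prev_r = rhc[rhc < l]
        next_r = rhc[rhc > l]
        if len(next_r):
            cand = minima[(minima > l) & (minima < next_r[0])]
            if len(cand):
                rto.append(int(cand[0]))
        if len(prev_r):
            cand = maxima[(maxima < l) & (maxima > prev_r[-1])]
            if len(cand):
                lto.append(int(cand[-1]))
    return np.array(sorted(rto), dtype=int), np.array(sorted(lto), dtype=int)


def segment_cycles(events: GaitEvents) -> list:
    """One :class:`GaitCycle` per consecutive pair of right heel contacts."""
    cycles = []
    rhc = events.rhc
    for a, b in zip(rhc[:-1], rhc[1:]):
        cyc = GaitCycle(start=int(a), end=int(b), fs=events.fs)
        inside_rto = events.rto[(events.rto > a) & (events.rto < b)]
        inside_lhc = events.lhc[(events.lhc > a) & (events.lhc < b)]
        inside_lto = events.lto[(events.lto > a) & (events.lto < b)]
        if len(inside_rto):
            cyc.rto = int(inside_rto[0])
        if len(inside_lhc):
            cyc.lhc = int(inside_lhc[0])
        if len(inside_lto):
            cyc.lto = int(inside_lto[0])
        cycles.append(cyc)
    return cycles


@dataclass
class EventDetectionResult:
    events: GaitEvents
    cycles: list
    y_detrended: np.ndarray = field(repr=False, default=None)
    z_detrended: np.ndarray = field(repr=False, default=None)
    y_dominant: np.ndarray = field(repr=False, default=None)


def detect_gait_events(
    ay: np.ndarray,
    az: np.ndarray,
    fs: float,
    L: int | None = None,
) -> EventDetectionResult:
    """Full event-detection chain for one window (or whole walk).

    SSA embedding length defaults to 2 s of samples, long enough to isolate
    the stride-periodic component at any plausible cadence.
    """
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if L is None:
        L = int(round(2.0 * fs))
    L = min(L, len(ay) // 2)
    empty = GaitEvents(rhc=[], lhc=[], rto=[], lto=[], fs=fs)
    if L < 2:
        return EventDetectionResult(events=empty, cycles=[])

    y_rec, _ = remove_trend(ssa_decompose(ay, L, fs=fs))
    z_rec, _ = remove_trend(ssa_decompose(az, L, fs=fs))
    y_dom = dominant_oscillation(y_rec, L, fs=fs)

    minima = dominant_minima(y_dom, fs)
    contacts = detect_heel_contacts(y_dom, y_rec, z_rec, fs)
    if len(contacts) < 3 or len(minima) < 3:
        return EventDetectionResult(
            events=empty, cycles=[], y_detrended=y_rec, z_detrended=z_rec, y_dominant=y_dom
        )
    rhc, lhc = assign_left_right(contacts, y_rec, minima)
    rto, lto = detect_toe_offs(rhc, lhc, y_rec, fs=fs)
    events = GaitEvents(rhc=rhc, lhc=lhc, rto=rto, lto=lto, fs=fs)
    return EventDetectionResult(
        events=events,
        cycles=segment_cycles(events),
        y_detrended=y_rec,
        z_detrended=z_rec,
        y_dominant=y_dom,
    )
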