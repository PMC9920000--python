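"""Time-domain gait features: 70 values per 10 s window.

Computed from the Earth-frame acceleration magnitude ``||a||`` and the three
components ``ax`` (medio-lateral), ``ay`` (vertical), ``az``
(anterior-posterior), plus the gait events/cycles detected in the window:

====================  ==================  ======
feature               signals             count
====================  ==================  ======
maximum               ||a||, ax, ay, az   4
minimum               ||a||, ax, ay, az   4
mean                  ||a||, ax, ay, az   4
median                ||a||, ax, ay, az   4
standard deviation    ||a||, ax, ay, az   4
10-bin histogram      ||a||, ax, ay, az   40
RMS ratio             ax, ay, az          3
signal magnitude area ax, ay, az          1
kurtosis              ||a||               1
skewness              ||a||               1
LCSS similarity       ||a||               1
cadence               events              1
mean stride time      cycles              1
swing/stance ratio    cycles              1
====================  ==================  ======

Features undefined on a window (e.g. fewer than two detected cycles for the
similarity) carry NaN; the dataset assembly decides whether to impute or drop
such rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gait_events import GaitEvents

SIGNAL_NAMES = ("mag", "ax", "ay", "az")


@dataclass
class WindowSignals:
    """Aligned per-window series plus the window's gait events and cycles."""

    magnitude: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    cycles: list = field(default_factory=list)
    events: GaitEvents | None = None

    def __post_init__(self):
        n = len(self.magnitude)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("all window series must have equal length")

    @property
    def duration(self) -> float:
        return len(self.magnitude) / self.fs

    def signal(self, name: str) -> np.ndarray:
        return {"mag": self.magnitude, "ax": self.ax, "ay": self.ay, "az": self.az}[name]


# ---------------------------------------------------------------------------
# statistics

def basic_stats(series: np.ndarray) -> dict:
    """max, min, mean, median and sample standard deviation (N-1)."""
    x = np.asarray(series, dtype=float)
    return {
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "std": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
    }


def histogram10(series: np.ndarray) -> np.ndarray:
    """Frequencies over 10 equal-width bins spanning the window's own range.

    A constant series puts all mass in the first bin.
    """
    x = np.asarray(series, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        out = np.zeros(10)
        out[0] = 1.0
        return out
    counts, _ = np.histogram(x, bins=10, range=(lo, hi))
    return counts / counts.sum()


def rmsr(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Per-axis RMS divided by the total RMS; squares sum to one."""
    rms = np.array([
        np.sqrt(np.mean(np.square(ax))),
        np.sqrt(np.mean(np.square(ay))),
        np.sqrt(np.mean(np.square(az))),
    ])
    total = np.sqrt(np.sum(rms**2))
    if total == 0.0:
        return np.full(3, np.nan)
    return rms / total


def sma(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> float:
    """Signal magnitude area: mean of summed absolute per-axis accelerations."""
    return float(np.mean(np.abs(ax) + np.abs(ay) + np.abs(az)))


def kurtosis(series: np.ndarray) -> float:
    """Non-excess kurtosis m4 / m2^2 (NaN on zero variance)."""
    x = np.asarray(series, dtype=float)
    d = x - x.mean()
    m2 = np.sum(d**2)
    if m2 == 0.0:
        return float("nan")
    return float(len(x) * np.sum(d**4) / m2**2)


def skewness(series: np.ndarray) -> float:
    """Central-moment skewness g = m3 / m2^(3/2) (NaN on zero variance)."""
    x = np.asarray(series, dtype=float)
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0.0:
        return float("nan")
    m3 = np.mean(d**3)
    return float(m3 / m2**1.5)


# ---------------------------------------------------------------------------
# gait-cycle features

def lcss_length(a: np.ndarray, b: np.ndarray, eps: float, delta: int) -> int:
    """Longest common subsequence length between two series.

    Samples match when their values differ by at most ``eps`` and their index
    offset by at most ``delta`` (classic LCSS time-series similarity).
    """
    n, m = len(a), len(b)
    prev = np.zeros(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        jlo = max(1, i - delta)
        jhi = min(m, i + delta)
        if jlo > m:
            continue  # no in-band cells; the row equals the previous one
        cur = np.zeros(m + 1, dtype=np.int32)
        cur[:jlo] = prev[:jlo]  # no matches left of the band
        for j in range(jlo, jhi + 1):
            if abs(a[i - 1] - b[j - 1]) <= eps:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        for j in range(jhi + 1, m + 1):  # propagate maxima right of the band
            cur[j] = max(cur[j - 1], prev[j])
        prev = cur
    return int(prev[m])


def lcss_similarity(
    cycle_segments: list,
    eps: float | None = None,
    delta_frac: float = 0.1,
) -> float:
    """Mean LCSS similarity over consecutive gait-cycle pairs, in [0, 1].

    Each pair's LCSS length is normalized by the shorter cycle length.  By
    default ``eps`` is half the pooled standard deviation of the segments and
    the warping band ``delta`` is 10% of the shorter cycle.  NaN with fewer
    than two cycles.
    """
    segs = [np.asarray(s, dtype=float) for s in cycle_segments if len(s)]
    if len(segs) < 2:
        return float("nan")
    if eps is None:
        pooled = np.concatenate(segs)
        eps = 0.5 * float(np.std(pooled))
    sims = []
    for a, b in zip(segs[:-1], segs[1:]):
        shorter = min(len(a), len(b))
        delta = max(1, int(round(delta_frac * shorter)))
        sims.append(lcss_length(a, b, eps, delta) / shorter)
    return float(np.mean(sims))


def cadence(events: GaitEvents | None, duration: float) -> float:
    """Steps per minute: total heel contacts over the window duration."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if events is None:
        return 0.0
    return events.n_heel_contacts / duration * 60.0


def mean_stride_time(cycles: list) -> float:
    """Mean stride time in seconds (NaN when no cycle was detected)."""
    if not cycles:
        return float("nan")
    return float(np.mean([c.stride_time for c in cycles]))


def swing_stance_ratio(cycles: list, mode: str = "stance_pct") -> float:
    """Stance percentage of the gait cycle, averaged over cycles (typ. ~60%).

    ``mode="swing_minus_stance"`` returns instead the difference between the
    swing and stance percentages.  NaN when no cycle carries a toe-off.
    """
    vals = []
    for c in cycles:
        if c.stance_time is None or c.stride_time <= 0:
            continue
        stance_pct = 100.0 * c.stance_time / c.stride_time
        if mode == "stance_pct":
            vals.append(stance_pct)
        elif mode == "swing_minus_stance":
            vals.append((100.0 - stance_pct) - stance_pct)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if not vals:
        return float("nan")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# block assembly

def time_feature_names() -> list:
    names = []
    for stat in ("max", "min", "mean", "median", "std"):
        names += [f"{stat}_{s}" for s in SIGNAL_NAMES]
    for s in SIGNAL_NAMES:
        names += [f"hist{b:02d}_{s}" for b in range(1, 11)]
    names += ["rmsr_ax", "rmsr_ay", "rmsr_az", "sma",
              "kurtosis_mag", "skewness_mag", "similarity_mag",
              "cadence", "stride_time", "swing_stance"]
    return names


def extract_time_features(w: WindowSignals, swing_stance_mode: str = "stance_pct") -> dict:
    """The full ordered 70-entry time-domain block for one window."""
    out = {}
    stats = {s: basic_stats(w.signal(s)) for s in SIGNAL_NAMES}
    for stat in ("max", "min", "mean", "median", "std"):
        for s in SIGNAL_NAMES:
            out[f"{stat}_{s}"] = stats[s][stat]
    for s in SIGNAL_NAMES:
        freqs = histogram10(w.signal(s))
        for b in range(10):
            out[f"hist{b + 1:02d}_{s}"] = float(freqs[b])
    ratios = rmsr(w.ax, w.ay, w.az)
    out["rmsr_ax"], out["rmsr_ay"], out["rmsr_az"] = map(float, ratios)
    out["sma"] = sma(w.ax, w.ay, w.az)
    out["kurtosis_mag"] = kurtosis(w.magnitude)
    out["skewness_mag"] = skewness(w.magnitude)
    segments = [w.magnitude[c.start:c.end] for c in w.cycles]
    out["similarity_mag"] = lcss_similarity(segments)
    out["cadence"] = cadence(w.events, w.duration)
    out["stride_time"] = mean_stride_time(w.cycles)
    out["swing_stance"] = swing_stance_ratio(w.cycles, mode=swing_stance_mode)
    assert list(out.keys()) == time_feature_names()
    return out
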