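"""Overlapping-window segmentation, IC labeling and dataset assembly.

Walks are sliced into 10 s windows with 50% overlap, anchored within walking
segments so rest periods create no phantom windows.  Each window gets the
155-feature vector (70 time + 85 frequency) and a binary label: 1 when at
least half of the window lies at or after the patient-reported pain onset
(claudication present), else 0.  Windows in which no complete gait cycle was
detected are dropped, mirroring the exclusion step of the target protocol.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features_freq import extract_freq_features, freq_feature_names
from .features_time import WindowSignals, extract_time_features, time_feature_names
from .gait_events import detect_gait_events
from .orientation import EarthFrameRecording
from .preprocess import WalkMask, acceleration_magnitude

log = logging.getLogger(__name__)

ID_COLUMNS = ["patient_id", "trial_id", "window_start_s", "label"]


def feature_schema() -> list:
    """Ordered machine-readable schema of the 155 feature columns."""
    names = time_feature_names() + freq_feature_names()
    return [{"index": i, "name": n, "block": "time" if i < 70 else "frequency"}
            for i, n in enumerate(names)]


@dataclass
class WalkRecord:
    """One processed walk: Earth-frame acceleration + mask + pain onset."""

    patient_id: str
    trial_id: str
    earth: EarthFrameRecording
    walk_mask: WalkMask
    pain_onset: float | None = None

    def __post_init__(self):
        if self.pain_onset is not None:
            if not 0.0 <= self.pain_onset <= self.earth.duration + 1e-9:
                raise ValueError("pain_onset must lie within the recording")


@dataclass
class Window:
    """One raw 10 s slice of a walk, before event detection."""

    start_index: int
    start_s: float
    signals: WindowSignals


def make_windows(walk: WalkRecord, window_s: float = 10.0, overlap: float = 0.5) -> list:
    """Slice the walking portions of a walk into overlapping windows.

    Windows start every ``(1-overlap)*window_s`` seconds within each walking
    segment and must lie fully inside it; a rest-free recording of duration D
    yields floor((D - window_s) / ((1-overlap)*window_s)) + 1 windows.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    fs = walk.earth.rate
    n_win = int(round(window_s * fs))
    stride = int(round((1.0 - overlap) * window_s * fs))
    if stride < 1:
        raise ValueError("window stride must be at least one sample")
    accel = walk.earth.accel_earth
    mag = acceleration_magnitude(accel)

    segments = walk.walk_mask.segments or []
    windows = []
    for seg_start, seg_end in segments:
        start = seg_start
        while start + n_win <= seg_end:
            sl = slice(start, start + n_win)
            windows.append(Window(
                start_index=start,
                start_s=walk.earth.start_time + start / fs,
                signals=WindowSignals(
                    magnitude=mag[sl],
                    ax=accel[sl, 0],
                    ay=accel[sl, 1],
                    az=accel[sl, 2],
                    fs=fs,
                ),
            ))
            start += stride
    return windows


def attach_events(windows: list, L: int | None = None) -> list:
    """Run gait-event detection per window, filling cycles/events in place."""
    for w in windows:
        res = detect_gait_events(w.signals.ay, w.signals.az, w.signals.fs, L=L)
        w.signals.events = res.events
        w.signals.cycles = res.cycles
    return windows


def drop_cycleless(windows: list) -> tuple:
    """Remove windows with zero complete gait cycles; returns (kept, n_dropped)."""
    kept = [w for w in windows if len(w.signals.cycles) > 0]
    dropped = len(windows) - len(kept)
    if kept == [] and windows:
        warnings.warn("all windows of a walk were dropped (no gait cycles detected)")
    return kept, dropped


def label_window(start_s: float, window_s: float, pain_onset: float | None) -> int:
    """1 iff at least 50% of the window lies at or after the pain onset."""
    if pain_onset is None:
        return 0
    return int(pain_onset <= start_s + window_s / 2.0)


@dataclass
class WindowDataset:
    """Feature matrix + labels + identifiers, one row per retained window."""

    features: pd.DataFrame          # columns = 155 feature names, ordered
    labels: np.ndarray              # 0/1
    patient_ids: np.ndarray
    trial_ids: np.ndarray
    window_start_s: np.ndarray
    counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def class_balance(self) -> float:
        return float(np.mean(self.labels)) if len(self.labels) else float("nan")

    def to_csv(self, path, schema_path=None) -> None:
        df = self.features.copy()
        df.insert(0, "patient_id", self.patient_ids)
        df.insert(1, "trial_id", self.trial_ids)
        df.insert(2, "window_start_s", self.window_start_s)
        df.insert(3, "label", self.labels)
        df.to_csv(path, index=False)
        if schema_path is not None:
            with open(schema_path, "w") as fh:
                json.dump(feature_schema(), fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "WindowDataset":
        df = pd.read_csv(path)
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset file missing column(s): {missing}")
        feat_cols = [c for c in df.columns if c not in ID_COLUMNS]
        expected = time_feature_names() + freq_feature_names()
        if feat_cols != expected:
            raise ValueError("feature columns do not match the exported schema")
        return cls(
            features=df[feat_cols],
            labels=df["label"].to_numpy(dtype=int),
            patient_ids=df["patient_id"].to_numpy(dtype=str),
            trial_ids=df["trial_id"].to_numpy(dtype=str),
            window_start_s=df["window_start_s"].to_numpy(dtype=float),
        )


def assemble(
    walks: list,
    window_s: float = 10.0,
    overlap: float = 0.5,
    nan_policy: str = "drop",
    ssa_embedding: int | None = None,
) -> WindowDataset:
    """Run the per-window pipeline over a list of walks and stack rows.

    ``nan_policy`` controls rows whose features are flagged missing (NaN):
    "drop" removes them, "impute" replaces NaN with the column median.
    """
    if not walks:
        raise ValueError("need at least one walk")
    if nan_policy not in ("drop", "impute"):
        raise ValueError("nan_policy must be 'drop' or 'impute'")

    rows, labels, pids, tids, starts = [], [], [], [], []
    counts = {"walks": len(walks), "windows_created": 0, "windows_dropped_cycleless": 0,
              "rows_dropped_nan": 0}
    for walk in walks:
        windows = make_windows(walk, window_s=window_s, overlap=overlap)
        counts["windows_created"] += len(windows)
        windows = attach_events(windows, L=ssa_embedding)
        windows, dropped = drop_cycleless(windows)
        counts["windows_dropped_cycleless"] += dropped
        for w in windows:
            feats = extract_time_features(w.signals)
            feats.update(extract_freq_features(w.signals.magnitude, w.signals.fs))
            rows.append(feats)
            labels.append(label_window(w.start_s, window_s, walk.pain_onset))
            pids.append(walk.patient_id)
            tids.append(walk.trial_id)
            starts.append(w.start_s)
        log.info("walk %s: %d windows retained (%d dropped)", walk.trial_id, len(windows), dropped)

    if not rows:
        raise ValueError("zero retained windows across all walks")

    features = pd.DataFrame(rows, columns=time_feature_names() + freq_feature_names())
    labels = np.asarray(labels, dtype=int)
    pids = np.asarray(pids, dtype=str)
    tids = np.asarray(tids, dtype=str)
    starts = np.asarray(starts, dtype=float)

    nan_rows = features.isna().any(axis=1).to_numpy()
    if nan_policy == "drop" and nan_rows.any():
        counts["rows_dropped_nan"] = int(nan_rows.sum())
        keep = ~nan_rows
        features = features.loc[keep].reset_index(drop=True)
        labels, pids, tids, starts = labels[keep], pids[keep], tids[keep], starts[keep]
    elif nan_policy == "impute":
        features = features.fillna(features.median())

    counts["rows_retained"] = len(features)
    counts["class_balance"] = float(labels.mean()) if len(labels) else float("nan")
    return WindowDataset(
        features=features,
        labels=labels,
        patient_ids=pids,
        trial_ids=tids,
        window_start_s=starts,
        counts=counts,
    )
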