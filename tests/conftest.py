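"""Shared fixtures: simulated walks processed through the full pipeline.

Expensive artifacts (sensor-fusion runs, cohort datasets) are session-scoped
and shared across test modules.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from claudigait.gait_events import EventDetectionResult, detect_gait_events
from claudigait.pipeline import PipelineConfig, build_dataset, process_recording
from claudigait.synthetic_data import (
    GaitSimConfig,
    GroundTruth,
    simulate_cohort,
    simulate_walk,
)
from claudigait.windows_dataset import WalkRecord


@dataclass
class ProcessedWalk:
    """A simulated walk pushed through resample/filter/fusion/rotation."""

    sim_config: GaitSimConfig
    truth: GroundTruth
    walk: WalkRecord
    detection: EventDetectionResult
    analysis_start_s: float  # fusion warmup excluded from `detection`

    @property
    def fs(self) -> float:
        return self.walk.earth.rate

    def detected_contact_times(self) -> np.ndarray:
        ev = self.detection.events
        merged = np.sort(np.concatenate([ev.rhc, ev.lhc]))
        return merged / self.fs + self.analysis_start_s

    def true_contact_times(self, margin: float = 0.5) -> np.ndarray:
        t = self.truth.heel_contact_times
        lo = self.analysis_start_s + margin
        hi = self.sim_config.duration - margin
        return t[(t > lo) & (t < hi)]


def process_walk(cfg: GaitSimConfig, pipe: PipelineConfig | None = None) -> ProcessedWalk:
    pipe = pipe or PipelineConfig()
    rec, truth = simulate_walk(cfg)
    walk = process_recording(rec, pipe, pain_onset=truth.pain_onset)
    warm = int(round(pipe.fusion_warmup_s * pipe.rate_hz))
    accel = walk.earth.accel_earth[warm:]
    detection = detect_gait_events(accel[:, 1], accel[:, 2], pipe.rate_hz)
    return ProcessedWalk(
        sim_config=cfg,
        truth=truth,
        walk=walk,
        detection=detection,
        analysis_start_s=pipe.fusion_warmup_s,
    )


@pytest.fixture(scope="session")
def walk60() -> ProcessedWalk:
    """A 60 s default walk (stride 1.1 s, stance 0.60) through the pipeline."""
    return process_walk(GaitSimConfig(duration=60.0, seed=3))


@pytest.fixture(scope="session")
def cohort_dataset():
    """A 16-patient x 2-trial cohort dataset with per-patient idiosyncrasies.

    Returns (WindowDataset, list_of_SimulatedTrial).
    """
    pipe = PipelineConfig()
    trials = simulate_cohort(
        16, 2, seed=2024, base_config=GaitSimConfig(duration=150.0)
    )
    walks = [
        process_recording(t.recording, pipe, patient_id=t.patient_id,
                          trial_id=t.trial_id, pain_onset=t.truth.pain_onset)
        for t in trials
    ]
    return build_dataset(walks, pipe), trials


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
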