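"""End-to-end orchestration: raw IMU logs -> dataset -> classifier report.

Stages run in the fixed order resample -> low-pass filter -> sensor fusion ->
Earth-frame rotation -> walking detection -> windowing -> gait events ->
features -> labels -> classification.  A JSON run manifest records the
configuration hash, the seed, and per-stage counts (trials in, windows
created / dropped / retained, class balance) so runs are auditable and
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import classify
from .imu_io import RawImuRecording, resample_linear
from .orientation import estimate_orientation, rotate_to_earth
from .preprocess import acceleration_magnitude, butterworth_lowpass, detect_walking
from .synthetic_data import CohortPriors, GaitSimConfig, simulate_cohort
from .windows_dataset import WalkRecord, WindowDataset, assemble

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage's tunables plus the global seed.

    The global seed fans out to per-stage seeds by stable hashing, so a stage
    re-run in isolation reproduces its in-pipeline behavior.
    """

    rate_hz: float = 50.0
    filter_order: int = 4
    filter_cutoff_hz: float = 5.0
    walk_threshold_ms2: float = 1.0
    walk_window_s: float = 1.0
    walk_min_walk_s: float = 2.0
    fusion_beta: float = 0.1
    fusion_warmup_s: float = 5.0
    fusion_remove_gravity: bool = True
    window_s: float = 10.0
    overlap: float = 0.5
    ssa_embedding_s: float = 2.0
    nan_policy: str = "drop"
    split: str = "records"
    test_frac: float = 0.2
    k_folds: int = 10
    models: tuple = tuple(sorted(classify.MODEL_REGISTRY))
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "models" in d:
            d = {**d, "models": tuple(d["models"])}
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).hexdigest()
        return int(h[:8], 16) % (2**31 - 1)


def process_recording(
    raw: RawImuRecording,
    config: PipelineConfig,
    patient_id: str = "P000",
    trial_id: str = "P000_T0",
    pain_onset: float | None = None,
) -> WalkRecord:
    """Raw irregular log -> Earth-frame walk record with walking mask.

    The fusion warm-up period is marked non-walking so no analysis window
    overlaps the filter's convergence phase.
    """
    uni = resample_linear(raw, rate=config.rate_hz)
    uni.accel = butterworth_lowpass(uni.accel, config.rate_hz,
                                    cutoff=config.filter_cutoff_hz, order=config.filter_order)
    uni.gyro = butterworth_lowpass(uni.gyro, config.rate_hz,
                                   cutoff=config.filter_cutoff_hz, order=config.filter_order)
    uni.mag = butterworth_lowpass(uni.mag, config.rate_hz,
                                  cutoff=config.filter_cutoff_hz, order=config.filter_order)
    ori = estimate_orientation(uni, beta=config.fusion_beta, warmup=config.fusion_warmup_s)
    earth = rotate_to_earth(uni, ori, remove_gravity=config.fusion_remove_gravity)

    # rest detection runs on the measured (gravity-included) magnitude, which
    # is orientation-invariant, so the body frame serves directly
    mag = acceleration_magnitude(uni.accel)
    mask = detect_walking(mag, config.rate_hz, threshold=config.walk_threshold_ms2,
                          window=config.walk_window_s, min_walk=config.walk_min_walk_s)
    warm = min(ori.warmup_samples, len(mask.mask))
    if warm > 0:
        mask.mask[:warm] = False
        mask.segments = [
            (max(s, warm), e) for s, e in mask.segments if e > warm
        ]
    if pain_onset is not None:
        pain_onset = float(min(pain_onset, earth.duration))
    return WalkRecord(patient_id=patient_id, trial_id=trial_id, earth=earth,
                      walk_mask=mask, pain_onset=pain_onset)


def build_dataset(walks: list, config: PipelineConfig) -> WindowDataset:
    return assemble(
        walks,
        window_s=config.window_s,
        overlap=config.overlap,
        nan_policy=config.nan_policy,
        ssa_embedding=int(round(config.ssa_embedding_s * config.rate_hz)),
    )


@dataclass
class PipelineResult:
    dataset: WindowDataset
    report: "classify.pd.DataFrame"
    manifest: dict


def run_pipeline(
    config: PipelineConfig,
    n_patients: int = 10,
    trials_per_patient: int = 2,
    sim_config: GaitSimConfig | None = None,
    priors: CohortPriors | None = None,
    trials: list | None = None,
) -> PipelineResult:
    """Simulate (or accept) a cohort, build the dataset, compare models.

    ``trials`` may carry pre-simulated :class:`SimulatedTrial` objects; when
    omitted, a cohort is simulated from ``sim_config``/``priors`` with the
    pipeline's stage seed.
    """
    if trials is None:
        trials = simulate_cohort(
            n_patients, trials_per_patient, priors=priors,
            seed=config.stage_seed("simulate"), base_config=sim_config,
        )
    walks = [
        process_recording(t.recording, config, patient_id=t.patient_id,
                          trial_id=t.trial_id, pain_onset=t.truth.pain_onset)
        for t in trials
    ]
    ds = build_dataset(walks, config)

    split_seed = config.stage_seed("split")
    if config.split == "records":
        plan = classify.split_records(ds, test_frac=config.test_frac, seed=split_seed)
    elif config.split == "patients":
        plan = classify.split_patients(ds, test_frac=config.test_frac, seed=split_seed)
    else:
        raise ValueError(f"unknown split strategy {config.split!r}")
    report = classify.compare_models(ds, plan, models=config.models,
                                     K=config.k_folds, seed=config.stage_seed("train"))

    counts = dict(ds.counts)
    created = counts["windows_created"]
    retained = counts["rows_retained"]
    dropped = counts["windows_dropped_cycleless"] + counts["rows_dropped_nan"]
    assert created == retained + dropped, "window accounting violated"
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "trials_in": len(trials),
        "split": config.split,
        **counts,
        "labels_positive": int(np.sum(ds.labels)),
        "labels_negative": int(len(ds.labels) - np.sum(ds.labels)),
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    return PipelineResult(dataset=ds, report=report, manifest=manifest)
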