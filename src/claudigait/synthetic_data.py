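"""Synthetic pocket-smartphone IMU recordings of walking with a pain onset.

The generator emulates the data-collection protocol the pipeline targets:
~6-minute walks at self-selected speed with a free-oriented phone in a
trouser pocket, a per-walk claudication (pain) onset time, per-patient gait
idiosyncrasies, and optional rest blocks — with full ground truth (heel
contacts, toe-offs, stride times, orientation) so every pipeline stage can
be validated offline.

Signal model
------------
Gait is a stride-phase process: right heel contact (RHC) at phase 0, left
toe-off at ``stance_fraction - 0.5``, left heel contact at 0.5, right toe-off
at ``stance_fraction``.  The Earth-frame vertical acceleration follows a
band-limited per-stride template (monotone cubic through designed knots)
whose extrema encode those events — a deep pocket-side impact at RHC, a local
maximum at left toe-off, a steep descent through LHC into a local minimum at
right toe-off — plus a damped impact transient at each RHC.  The
anterior-posterior channel peaks sharply at every heel contact (plus a
phase-shifted stride-frequency component); medio-lateral is low-amplitude
sway.  The pocket side produces the larger ipsilateral signal, which is what
the left/right labeling rule downstream exploits.

Claudication is modeled as a change-point: after ``pain_onset`` the stride
time lengthens by ``1/cadence_factor``, stride-time variability scales by
``variability_factor`` and amplitudes by ``amp_factor``.

The Earth-frame signal (gravity added) is rotated into the body frame by the
phone orientation (optionally wobbling a few degrees at step frequency); the
gyroscope reports the exact angular rate of that orientation plus noise, and
the magnetometer the rotated Earth field plus noise.  Timestamps are jittered
to mimic OS-scheduled sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .imu_io import RawImuRecording
from .orientation import GRAVITY, euler_to_quat, quat_multiply, quat_normalize

# Earth magnetic field in the Earth frame (X ML, Y up, Z AP=north), uT.
# Downward-pointing vertical component, as in the northern hemisphere.
EARTH_FIELD = np.array([0.0, -30.0, 25.0])


@dataclass
class GaitSimConfig:
    """Study conditions for one simulated walk.

    Defaults emulate a six-minute walk at a self-selected, mildly impaired
    pace (stride 1.1 s ~ 109 steps/min) with smartphone-grade sensor noise.
    """

    duration: float = 360.0          # s
    fs_nominal: float = 50.0         # Hz
    timestamp_jitter: float = 0.002  # s, uniform, mimics OS batching
    stride_time_mean: float = 1.1    # s
    stride_time_cv: float = 0.04     # fractional std of stride time
    stance_fraction: float = 0.60    # stance share of the stride
    step_impact_amp: float = 3.0     # m/s^2, pocket-side heel-strike transient
    ipsilateral_gain: float = 1.4    # >=1 multiplier on pocket-side peaks
    vertical_amp: float = 2.5        # m/s^2, vertical template scale
    ap_amp: float = 2.0              # m/s^2, anterior-posterior heel-contact peaks
    ml_amp: float = 0.5              # m/s^2, medio-lateral sway
    pain_onset: float | None = None  # s, None = no claudication in this walk
    cadence_factor: float = 0.90     # <1: cadence drops after onset
    variability_factor: float = 1.5  # >1: stride CV grows after onset
    amp_factor: float = 0.85         # amplitude scale after onset
    phone_orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )
    wobble_deg: float = 3.0          # in-pocket orientation wobble amplitude
    accel_noise_sd: float = 0.25     # m/s^2
    gyro_noise_sd: float = 0.02      # rad/s
    mag_noise_sd: float = 0.5        # uT
    rest_blocks: tuple = ()          # ((start_s, duration_s), ...)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.cadence_factor <= 0 or self.variability_factor <= 0 or self.amp_factor <= 0:
            raise ValueError("post-onset factors must be positive")
        q = np.asarray(self.phone_orientation, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValueError("phone_orientation must be a unit quaternion")
        blocks = sorted(self.rest_blocks)
        for (s1, d1), (s2, _) in zip(blocks, blocks[1:]):
            if s1 + d1 > s2:
                raise ValueError("rest blocks overlap")


@dataclass
class GroundTruth:
    """Per-walk ground truth for validating the detection pipeline."""

    heel_contact_times: np.ndarray   # seconds
    heel_contact_sides: np.ndarray   # 'R'/'L'
    toe_off_times: np.ndarray
    toe_off_sides: np.ndarray
    stride_times: np.ndarray         # per right-foot stride, seconds
    pain_onset: float | None
    phone_orientation: np.ndarray
    rest_blocks: tuple

    def to_json(self) -> str:
        return json.dumps({
            "heel_contact_times": self.heel_contact_times.tolist(),
            "heel_contact_sides": self.heel_contact_sides.tolist(),
            "toe_off_times": self.toe_off_times.tolist(),
            "toe_off_sides": self.toe_off_sides.tolist(),
            "stride_times": self.stride_times.tolist(),
            "pain_onset": self.pain_onset,
            "phone_orientation": np.asarray(self.phone_orientation).tolist(),
            "rest_blocks": [list(b) for b in self.rest_blocks],
        })


def _stride_template(stance_fraction: float) -> PchipInterpolator:
    """Band-limited per-stride vertical waveform with event-encoding extrema.

    Monotone cubic (PCHIP) through knots at stride phase s in [0, 1):
    deep minimum at RHC (s=0), local maximum at left toe-off (s=c-0.5),
    steep monotone descent through LHC (s=0.5) into a local minimum at right
    toe-off (s=c), recovery maximum mid left-step, descent back into the next
    RHC.  Monotone interpolation guarantees extrema occur only at the knots
    where the direction changes.
    """
    c = float(stance_fraction)
    lto = max(c - 0.5, 0.04)
    knots = [
        (0.0, -1.1),
        (lto, 0.9),
        ((lto + 0.5) / 2, 0.1),
        (0.5, -0.7),
        (c, -1.3),
        ((c + 1.0) / 2, 0.6),
        (0.94, -0.5),
        (1.0, -1.1),
    ]
    s = np.array([k[0] for k in knots])
    v = np.array([k[1] for k in knots])
    # periodic extension so evaluation near the stride edges is smooth
    s_ext = np.concatenate([s[:-1] - 1.0, s, s[1:] + 1.0])
    v_ext = np.concatenate([v[:-1], v, v[1:]])
    return PchipInterpolator(s_ext, v_ext)


def _stride_schedule(cfg: GaitSimConfig, rng: np.random.Generator):
    """Right-heel-contact times and per-stride parameters covering the walk."""
    rhc = [0.0]
    stride_times = []
    post = []
    t = 0.0
    while t < cfg.duration:
        after = cfg.pain_onset is not None and t >= cfg.pain_onset
        mean = cfg.stride_time_mean / cfg.cadence_factor if after else cfg.stride_time_mean
        cv = cfg.stride_time_cv * (cfg.variability_factor if after else 1.0)
        T = max(0.4, rng.normal(mean, cv * mean))
        stride_times.append(T)
        post.append(after)
        t += T
        rhc.append(t)
    return np.array(rhc), np.array(stride_times), np.array(post, dtype=bool)


def _in_rest(t: np.ndarray, rest_blocks) -> np.ndarray:
    mask = np.zeros(len(t), dtype=bool)
    for start, dur in rest_blocks:
        mask |= (t >= start) & (t < start + dur)
    return mask


def simulate_walk(cfg: GaitSimConfig) -> tuple:
    """Simulate one walk; returns (RawImuRecording, GroundTruth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    rhc_times, stride_times, post = _stride_schedule(cfg, rng)
    n_strides = len(stride_times)
    c = cfg.stance_fraction

    # ground-truth events (strides whose RHC falls in a rest block are dropped)
    hc_t, hc_side, to_t, to_side = [], [], [], []
    for i in range(n_strides):
        t0, T = rhc_times[i], stride_times[i]
        events = [
            (t0, "R", "hc"),
            (t0 + max(c - 0.5, 0.04) * T, "L", "to"),
            (t0 + 0.5 * T, "L", "hc"),
            (t0 + c * T, "R", "to"),
        ]
        for t_ev, side, kind in events:
            if t_ev >= cfg.duration or _in_rest(np.array([t_ev]), cfg.rest_blocks)[0]:
                continue
            if kind == "hc":
                hc_t.append(t_ev)
                hc_side.append(side)
            else:
                to_t.append(t_ev)
                to_side.append(side)

    # sample clock: nominal grid with jittered interior timestamps
    n = int(round(cfg.duration * cfg.fs_nominal)) + 1
    ts = np.arange(n) / cfg.fs_nominal
    if cfg.timestamp_jitter > 0:
        jit = rng.uniform(-cfg.timestamp_jitter, cfg.timestamp_jitter, size=n)
        jit[0] = jit[-1] = 0.0
        ts = ts + np.clip(jit, -0.45 / cfg.fs_nominal, 0.45 / cfg.fs_nominal)

    # stride phase and per-sample stride index
    idx = np.clip(np.searchsorted(rhc_times, ts, side="right") - 1, 0, n_strides - 1)
    phase = (ts - rhc_times[idx]) / stride_times[idx]
    phase = np.clip(phase, 0.0, 1.0 - 1e-9)
    amp_scale = np.where(post[idx], cfg.amp_factor, 1.0)

    template = _stride_template(c)
    side_gain = 1.0 + (cfg.ipsilateral_gain - 1.0) * (0.5 + 0.5 * np.cos(2 * np.pi * (phase - 0.25)))
    a_y = cfg.vertical_amp * amp_scale * side_gain * template(phase)

    # pocket-side (right) heel-strike impact transient: damped cosine
    tau, f_imp = 0.05, 4.5
    for i in range(n_strides):
        t0 = rhc_times[i]
        if t0 >= cfg.duration:
            continue
        sel = (ts >= t0) & (ts < t0 + 0.25)
        dt_ = ts[sel] - t0
        amp = cfg.step_impact_amp * (cfg.amp_factor if post[i] else 1.0)
        a_y[sel] += -amp * np.exp(-dt_ / tau) * np.cos(2 * np.pi * f_imp * dt_)

    ap_peak = (0.5 + 0.5 * np.cos(4 * np.pi * phase)) ** 4
    a_z = cfg.ap_amp * amp_scale * (ap_peak + 0.25 * np.sin(2 * np.pi * phase + 0.8))
    a_x = cfg.ml_amp * amp_scale * np.sin(2 * np.pi * phase + 0.5)

    rest = _in_rest(ts, cfg.rest_blocks)
    a_x[rest] = a_y[rest] = a_z[rest] = 0.0

    accel_earth = np.column_stack([a_x, a_y, a_z])

    # orientation: constant pocket pose plus a small step-frequency wobble
    q0 = quat_normalize(np.asarray(cfg.phone_orientation, dtype=float))

    def quat_of(phase_arr, rest_arr):
        theta = np.radians(cfg.wobble_deg) * np.sin(2 * np.pi * phase_arr)
        theta = np.where(rest_arr, 0.0, theta)
        out = np.empty((len(phase_arr), 4))
        half = theta / 2.0
        for k in range(len(phase_arr)):
            q_w = np.array([np.cos(half[k]), np.sin(half[k]), 0.0, 0.0])
            out[k] = quat_multiply(q0, q_w)
        return out

    quats = quat_of(phase, rest)

    # exact body angular rate by central differences of the quaternion path
    h = 1e-4
    idx_p = np.clip(np.searchsorted(rhc_times, ts + h, side="right") - 1, 0, n_strides - 1)
    idx_m = np.clip(np.searchsorted(rhc_times, ts - h, side="right") - 1, 0, n_strides - 1)
    ph_p = np.clip((ts + h - rhc_times[idx_p]) / stride_times[idx_p], 0.0, 1.0)
    ph_m = np.clip((ts - h - rhc_times[idx_m]) / stride_times[idx_m], 0.0, 1.0)
    q_p = quat_of(ph_p, _in_rest(ts + h, cfg.rest_blocks))
    q_m = quat_of(ph_m, _in_rest(ts - h, cfg.rest_blocks))
    gyro = np.empty((n, 3))
    from .orientation import quat_conj
    for k in range(n):
        qdot = (q_p[k] - q_m[k]) / (2 * h)
        w = 2.0 * quat_multiply(quat_conj(quats[k]), qdot)
        gyro[k] = w[1:]

    # body-frame sensor signals
    from .orientation import quat_to_matrix
    accel_body = np.empty((n, 3))
    mag_body = np.empty((n, 3))
    g_vec = np.array([0.0, GRAVITY, 0.0])
    for k in range(n):
        Rt = quat_to_matrix(quats[k]).T
        accel_body[k] = Rt @ (accel_earth[k] + g_vec)
        mag_body[k] = Rt @ EARTH_FIELD

    accel_body += rng.normal(0.0, cfg.accel_noise_sd, size=(n, 3))
    gyro += rng.normal(0.0, cfg.gyro_noise_sd, size=(n, 3))
    mag_body += rng.normal(0.0, cfg.mag_noise_sd, size=(n, 3))

    rec = RawImuRecording(
        timestamps=ts,
        accel=accel_body,
        gyro=gyro,
        mag=mag_body,
        meta={"simulated": True, "seed": cfg.seed, "fs_nominal": cfg.fs_nominal},
    )
    order = np.argsort(hc_t)
    order_to = np.argsort(to_t)
    truth = GroundTruth(
        heel_contact_times=np.array(hc_t)[order],
        heel_contact_sides=np.array(hc_side)[order],
        toe_off_times=np.array(to_t)[order_to],
        toe_off_sides=np.array(to_side)[order_to],
        stride_times=stride_times[rhc_times[:-1] < cfg.duration],
        pain_onset=cfg.pain_onset,
        phone_orientation=q0,
        rest_blocks=tuple(cfg.rest_blocks),
    )
    return rec, truth


@dataclass
class CohortPriors:
    """Population distributions for per-patient latent gait parameters.

    Patients are internally consistent across trials (one latent draw per
    patient), which is what makes patient-wise generalization measurably
    harder than record-wise evaluation.
    """

    stride_time_mean: tuple = (1.1, 0.15)
    stride_time_cv: tuple = (0.045, 0.015)
    stance_fraction: tuple = (0.60, 0.02)
    ipsilateral_gain: tuple = (1.4, 0.2)
    vertical_amp: tuple = (2.6, 0.5)
    cadence_factor: tuple = (0.93, 0.035)
    variability_factor: tuple = (1.4, 0.2)
    amp_factor: tuple = (0.88, 0.06)
    onset_fraction: tuple = (0.33, 0.67)  # uniform over walk duration
    pose_roll_sd: float = 8.0             # deg, pocket pose scatter
    pose_pitch_sd: float = 8.0


@dataclass
class SimulatedTrial:
    """One simulated walk of one patient, with ground truth."""

    patient_id: str
    trial_id: str
    recording: RawImuRecording
    truth: GroundTruth
    config: GaitSimConfig


def simulate_cohort(
    n_patients: int,
    trials_per_patient: int = 2,
    priors: CohortPriors | None = None,
    seed: int = 0,
    base_config: GaitSimConfig | None = None,
    with_onset: bool = True,
) -> list:
    """Simulate a cohort; per-patient latents are drawn once and shared across
    that patient's trials, per-trial onset times are drawn independently."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    priors = priors or CohortPriors()
    base = base_config or GaitSimConfig()
    rng = np.random.default_rng(seed)
    trials = []
    for p in range(n_patients):
        lat = {
            "stride_time_mean": max(0.7, rng.normal(*priors.stride_time_mean)),
            "stride_time_cv": max(0.01, rng.normal(*priors.stride_time_cv)),
            "stance_fraction": float(np.clip(rng.normal(*priors.stance_fraction), 0.54, 0.68)),
            "ipsilateral_gain": max(1.05, rng.normal(*priors.ipsilateral_gain)),
            "vertical_amp": max(1.6, rng.normal(*priors.vertical_amp)),
            "cadence_factor": float(np.clip(rng.normal(*priors.cadence_factor), 0.75, 0.98)),
            "variability_factor": max(1.0, rng.normal(*priors.variability_factor)),
            "amp_factor": float(np.clip(rng.normal(*priors.amp_factor), 0.6, 1.0)),
        }
        for t in range(trials_per_patient):
            roll = rng.normal(0.0, priors.pose_roll_sd)
            pitch = rng.normal(0.0, priors.pose_pitch_sd)
            yaw = rng.uniform(-180.0, 180.0)
            onset = None
            if with_onset:
                onset = float(rng.uniform(*priors.onset_fraction) * base.duration)
            cfg = replace(
                base,
                **lat,
                pain_onset=onset,
                phone_orientation=euler_to_quat(roll, pitch, yaw),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec, truth = simulate_walk(cfg)
            trials.append(SimulatedTrial(
                patient_id=f"P{p:03d}",
                trial_id=f"P{p:03d}_T{t}",
                recording=rec,
                truth=truth,
                config=cfg,
            ))
    return trials


def simulate_pose_sequence(
    poses,
    segment_s: float = 30.0,
    transition_s: float = 1.0,
    fs: float = 50.0,
    wobble_deg: float = 2.0,
    accel_noise_sd: float = 0.25,
    gyro_noise_sd: float = 0.02,
    mag_noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple:
    """Stationary-plus-slight-motion recording holding a sequence of poses.

    Reproduces the rotation-validation protocol: the phone holds each pose in
    ``poses`` (scalar-first quaternions) for ``segment_s`` seconds, turning to
    the next pose over a ``transition_s`` spherical interpolation, with a
    small wobble and sensor noise throughout.  Returns
    ``(RawImuRecording, quaternions)`` where the second element is the exact
    per-sample orientation ground truth.
    """
    from scipy.spatial.transform import Rotation, Slerp

    rng = np.random.default_rng(seed)
    n_seg = len(poses)
    duration = n_seg * segment_s
    n = int(round(duration * fs)) + 1
    ts = np.arange(n) / fs

    key_times, key_quats = [], []
    for i, q in enumerate(poses):
        q = quat_normalize(np.asarray(q, dtype=float))
        start = i * segment_s + (transition_s if i > 0 else 0.0)
        end = (i + 1) * segment_s
        key_times += [start, end]
        key_quats += [q, q]
    key_rots = Rotation.from_quat([[q[1], q[2], q[3], q[0]] for q in key_quats])
    slerp = Slerp(key_times, key_rots)

    def rot_at(t):
        t = np.clip(t, key_times[0], key_times[-1])
        base = slerp(t)
        theta = np.radians(wobble_deg) * np.sin(2 * np.pi * 1.0 * t)
        wob = Rotation.from_rotvec(np.column_stack(
            [theta, np.zeros_like(theta), np.zeros_like(theta)]))
        return base * wob

    rots = rot_at(ts)
    quats_xyzw = rots.as_quat()
    quats = np.column_stack([quats_xyzw[:, 3], quats_xyzw[:, :3]])
    # enforce sign continuity for finite differencing
    for k in range(1, n):
        if np.dot(quats[k], quats[k - 1]) < 0:
            quats[k] = -quats[k]

    h = 1e-4
    q_p = rot_at(ts + h).as_quat()
    q_m = rot_at(ts - h).as_quat()
    gyro = np.empty((n, 3))
    g_vec = np.array([0.0, GRAVITY, 0.0])
    accel = np.empty((n, 3))
    mag = np.empty((n, 3))
    from .orientation import quat_conj, quat_to_matrix
    for k in range(n):
        qp = np.array([q_p[k, 3], *q_p[k, :3]])
        qm = np.array([q_m[k, 3], *q_m[k, :3]])
        if np.dot(qp, quats[k]) < 0:
            qp = -qp
        if np.dot(qm, quats[k]) < 0:
            qm = -qm
        qdot = (qp - qm) / (2 * h)
        gyro[k] = 2.0 * quat_multiply(quat_conj(quats[k]), qdot)[1:]
        Rt = quat_to_matrix(quats[k]).T
        accel[k] = Rt @ g_vec
        mag[k] = Rt @ EARTH_FIELD

    accel += rng.normal(0.0, accel_noise_sd, size=(n, 3))
    gyro += rng.normal(0.0, gyro_noise_sd, size=(n, 3))
    mag += rng.normal(0.0, mag_noise_sd, size=(n, 3))

    rec = RawImuRecording(
        timestamps=ts, accel=accel, gyro=gyro, mag=mag,
        meta={"simulated": True, "pose_test": True, "seed": seed},
    )
    return rec, quats
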