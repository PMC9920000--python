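# claudigait

Smartphone pocket-IMU gait analysis for detecting the onset of **intermittent
claudication (IC)** — the exercise-induced lower-limb pain of peripheral
arterial disease (PAD) that appears after walking some distance and resolves
with rest.

Outpatient exercise programs for PAD ask patients to walk in the community;
clinicians then want to know *when* claudication set in during each walk.
`claudigait` turns a raw six-minute-walk log from a phone riding free in a
trouser pocket — triaxial accelerometer (m/s²), gyroscope (rad/s) and
magnetometer (μT) at a nominal, unstable 50 Hz — into windowed gait features
and a binary per-window decision: walking unaffected (0) vs. walking modified
by claudication pain (1).

## Pipeline

1. **Ingest & resample** (`imu_io`) — HyperIMU-style CSV, one row per sample;
   linear interpolation onto a uniform 50 Hz grid.
2. **Filter** (`preprocess`) — zero-phase 4th-order Butterworth low-pass at
   5 Hz (human walking kinematics live below ~4 Hz); rest segments detected
   where the rolling std of ‖a‖ drops below 1 m/s².
3. **Orient** (`orientation`) — Madgwick gradient-descent MARG fusion
   estimates the phone's quaternion; body-frame acceleration is rotated into
   an Earth-fixed frame (X medio-lateral, Y vertical, Z anterior–posterior)
   and gravity (0, 9.8, 0) removed. Roll/pitch/yaw are rotations about the
   device Z/X/Y axes.
4. **Gait events** (`gait_events`) — singular spectrum analysis (SSA:
   Hankel-matrix SVD + diagonal averaging) detrends the vertical and
   anterior–posterior channels; minima of the dominant vertical oscillation
   locate step intervals, the minimum of the Y·Z product refines each heel
   contact, a mean-amplitude parity rule assigns (phone-side-relative)
   right/left, and reconstructed-Y extrema give toe-offs. Strides are
   segmented between consecutive right heel contacts.
5. **Windows & features** (`windows_dataset`, `features_time`,
   `features_freq`) — 10 s windows with 50 % overlap; 70 time-domain + 85
   frequency-domain = **155 features** per window (statistics, 10-bin
   histograms, RMS ratios RMSRₓ = RMSₓ/RMS_T, signal magnitude area
   (1/N)Σ(|aₓ|+|a_y|+|a_z|), kurtosis m₄/m₂², skewness m₃/m₂^{3/2}, LCSS
   cycle similarity, cadence, stride time, swing/stance ratio; Welch PSD
   summaries, spectral entropy, spectral energy, 40 FFT and 40 DCT
   coefficients covering 0.1–4.0 Hz at 0.1 Hz resolution). Windows whose
   midpoint falls at/after the patient-reported pain onset are labeled 1.
6. **Classify** (`classify`) — six fixed-hyperparameter tree ensembles
   (XGBoost, LightGBM, histogram gradient boosting, random forest, extra
   trees, gradient boosting) under two split strategies with 10-fold CV and
   five metrics (accuracy, AUC, recall, precision, F1). *Record-wise* splits
   mix each patient's windows across train/test; *patient-wise* splits hold
   out whole patients and measure generalization to unseen subjects.

Because real patient recordings are private, `synthetic_data` provides a
pocket-IMU gait simulator with full ground truth (heel contacts, toe-offs,
stride times, orientation, pain onset) so every stage is testable offline;
see `docs/methods.md` for the signal model and its limits.

## Worked example

```python
from claudigait.pipeline import PipelineConfig, run_pipeline
from claudigait.synthetic_data import GaitSimConfig

config = PipelineConfig(seed=7, k_folds=5, models=("lightgbm", "random_forest"))
result = run_pipeline(config, n_patients=8, trials_per_patient=2,
                      sim_config=GaitSimConfig(duration=120.0))
print(result.report.round(3).to_string(index=False))
```

```
        model     side  accuracy   auc  recall  precision    f1
     lightgbm train_cv     0.971 0.993   0.965      0.980 0.972
     lightgbm     test     0.986 0.999   0.972      1.000 0.986
random_forest train_cv     0.968 0.998   0.972      0.966 0.968
random_forest     test     1.000 1.000   1.000      1.000 1.000
```

Sixteen simulated 2-minute walks produced 351 ten-second windows (about half
labeled claudication-positive, the manifest records the exact accounting);
`train_cv` rows are 5-fold cross-validation means on the 80 % training side,
`test` rows the held-out 20 %. This is a *record-wise* split — accuracies near
1.0 reflect that overlapping windows from every patient appear on both sides.
Re-running with `split="patients"` holds out whole patients and scores
visibly lower: the models lean on per-patient idiosyncrasies, which is
precisely what the two strategies are designed to expose.

The same flow is available from the shell:

```bash
claudigait simulate --out-dir data/ --n-patients 4 --seed 7
claudigait process  --in-dir data/ --out dataset.csv
claudigait compare  --dataset dataset.csv --split patients --k 10 --seed 42 --out report.csv
```

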