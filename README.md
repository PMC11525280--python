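# pdmotion

Quantitative motor assessment for Parkinson's disease from multimodal
sensor recordings.

Clinician-rated exams such as the UPDRS-III (14 motor items Q18–Q31, each
0–4, summed to a 0–56 total) are the standard of care for tracking PD motor
symptoms, but they are coarse and rater-dependent. `pdmotion` implements the
alternative: a standardized 7-task instrumented exam — elbow
flexion–extension, hand opening–closing, a complex multi-joint sequence,
hand-to-nose, hand-at-rest and hand-held-still tremor holds, a modified
Romberg balance test, and four 10 m walks — recorded by a 20-joint camera
skeleton (30 Hz), wearable 3-axis gyroscope + accelerometer IMUs (64 Hz,
on the index finger, L5, and ankles), and a force plate measuring the
center of pressure (CoP, 98 Hz). From each session it computes a canonical
**62-metric motor feature vector** and runs the analysis layer on top:

* **Signal primitives** — zero-phase FIR/Butterworth lowpass filters,
  central-difference differentiation, DPSS multitaper and Hann-periodogram
  spectra.
* **Movement segmentation** — elementary reaches from speed-profile minima
  (with a gyroscope fallback for severely bradykinetic profiles),
  hand-open gyro peaks, stride peaks from ankle z-rotation.
* **Metrics** — per-movement mean/max speed, duration, and smoothness
  (mean/max speed ratio; a minimum-jerk reach gives 1/1.875 ≈ 0.533), wrist
  path length, movement times and inter-peak intervals, rest (3–6 Hz) and
  postural (5–8 Hz) tremor band-power ratios of the accelerometer
  amplitude, CoP path length / component SDs / 95% covariance-ellipse
  geometry, trunk jerk, normalized gait jerk, and stride timing.
* **Dimensionality** — standardized PCA variance-explained curves for the
  exam items, the sensor metrics, and their union.
* **Prediction** — elastic net
  `(1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` over an α × λ grid,
  with every candidate's degrees of freedom (nonzero coefficients) capped
  at 50% of the cohort size, scored by leave-one-out CV R² with
  within-fold re-standardization; frozen-model transfer to a second visit;
  cluster-indicator augmentation.
* **Phenotyping** — t-SNE + K-means, a self-organizing map followed by
  Ward clustering of its neuron weights (subjects inherit their
  best-matching unit's cluster), random-forest out-of-bag permutation
  importance, a median-dominance table after ANOVA + Bonferroni screening,
  and ratio-based tremor-dominant / akinetic-rigid / mixed clinical
  subtyping for comparison.

Because no public recordings of this protocol exist, the package includes a
first-class **simulator**: severity-parameterized synthetic sessions
(minimum-jerk reaches slowed by bradykinesia, tremor oscillations, CoP
diffusion, stride-locked gait bursts) with UPDRS-III exams generated from
the same latent severities — so every analysis can be validated by
parameter recovery against known ground truth.

## Worked example

```python
from pdmotion.simulator import SeverityProfile, SimConfig, simulate_subject, simulate_updrs
from pdmotion.motor_metrics import extract_all

profile = SeverityProfile(s_brady=0.6, s_trem_rest=0.7, s_trem_post=0.3,
                          s_postural=0.5, s_gait=0.4)
session = simulate_subject(profile, SimConfig(), seed=11, subject_id="P001")
exam = simulate_updrs(profile, rater_noise_sd=0.3, seed=11)
vec = extract_all(session)
print(f"UPDRS-III total: {exam.total}")
for name in ("t1a_mean_speed_mean", "t1a_duration_mean", "t1a_smoothness_mean",
             "t5a_power_ratio_multitaper", "t6_eo_cop_path_length",
             "gait_stride_duration_mean"):
    print(f"{name:28s} {vec.values[name]:8.3f}")
```

prints

```
UPDRS-III total: 29
t1a_mean_speed_mean             0.590
t1a_duration_mean               0.763
t1a_smoothness_mean             0.525
t5a_power_ratio_multitaper      0.877
t6_eo_cop_path_length          62.777
gait_stride_duration_mean       1.159
```

This moderately affected synthetic patient reaches at 0.59 m/s (a healthy
profile reaches ~1.1 m/s), takes 0.76 s per elbow movement, has 88% of the
resting-hand accelerometer power concentrated in the 3–6 Hz tremor band,
sways through a 63 cm CoP path in 15 s of quiet standing, and walks with
1.16 s strides. The exam total of 29 is generated from the same latent
severities through a fixed item-weight matrix plus rater noise.

A full cohort analysis from the shell:

```bash
pdmotion simulate --n 50 --seed 7 --out cohort/
pdmotion extract --sessions cohort/sessions --out cohort/metrics.csv
pdmotion pca     --metrics cohort/metrics.csv --updrs cohort/updrs.csv --out cohort/pca
pdmotion predict --metrics cohort/metrics.csv --updrs cohort/updrs.csv --out cohort/prediction.json
pdmotion cluster --metrics cohort/metrics.csv --method som-ward --k 3 --out cohort/clusters
```

or end-to-end via `pdmotion report --seed 7 --out run/`, which also writes
a run manifest (config hash, seed, library versions) for reproducibility.

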