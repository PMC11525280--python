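# Methods

This note documents the models and numerical choices behind `pdmotion`:
what each stage computes, the parameters that matter, what the synthetic
data generator does and does not emulate, and the limitations a user
should know before trusting numbers on real recordings.

## Data model and session format

A session is one subject-visit of a standardized 7-task motor exam
(14 recordings: two elbow flexion–extension variants, two hand
opening–closing variants, one complex sequence, hand-to-nose, two tremor
holds, balance with eyes open and closed, four 10 m walks). Streams are a
20-joint camera skeleton at a nominal 30 Hz (meters; x lateral +right,
y vertical +up, z depth +away from camera), IMUs at 64 Hz (gyroscope
rad/s, accelerometer m/s²), a force-plate CoP at 98 Hz (centimeters), and
a marker channel whose first and last events bound each task. All streams
share one session clock; synchronization is assumed done by the
acquisition software, and a skew of one nominal sample period is tolerated
at crop boundaries. On disk a session is a directory of UTF-8 CSVs plus a
`manifest.json`; the format is deliberately diff-able and language-
agnostic. Per-task stream requirements (camera + finger IMU for the seated
tasks, plate + L5 IMU for balance, L5 + ankle IMUs for walks) are enforced
at read time.

IMU axis conventions are fixed by the package, not inferred from data:
finger gyro x_rot is the hand/forearm flexion–extension axis; ankle gyro
z_rot is the sagittal-plane rotation axis; L5 accelerometer axes are
(x, y, z) = (antero-posterior, medio-lateral, vertical-with-gravity). The
simulator and the metric layer use the same conventions, which is what the
parameter-recovery tests actually verify.

Missing camera frames are flagged; gaps of at most 3 frames are linearly
interpolated, longer gaps exclude the enclosing movement from per-movement
statistics.

## Signal primitives

* Position lowpass: 31-tap Hamming-window FIR at 10 Hz, applied
  forward-backward (zero phase). Zero-phase filtering avoids biasing
  segmentation boundaries; the effective magnitude response is the squared
  design response.
* Gyro/accelerometer lowpass: 4th-order Butterworth at 5 Hz, also
  forward–backward ("4th order" refers to the designed order).
* Derivatives: central differences in the interior, one-sided at the
  ends — simple and exactly checkable against closed forms.
* Spectra: DPSS multitaper (time-bandwidth NW = 4, 7 tapers) on the
  demeaned signal, and a single Hann-taper periodogram as the FFT variant.
  Band-power ratios integrate the PSD over the band and divide by the
  integral from **0.5 Hz** to Nyquist; the 0.5 Hz floor keeps DC/gravity
  leakage out of the denominator.
* Peak statistics of filtered-then-differentiated signals exclude 0.25 s
  at each end (zero-phase filter transients).

## Movement segmentation

Reaching tasks are segmented on the wrist speed profile
v(t) = ‖d/dt (filtered position)‖:

1. activity detection at 10% of the global peak speed, merging active runs
   closer than the 0.25 s refractory;
2. outward extension of each run along strictly decreasing speed until a
   plateau or until speed falls below 0.2% of the local peak (the floor
   keeps zero-phase filter tails out of the movement, which would
   otherwise dilute mean speed and inflate duration);
3. splitting at interior speed minima that dip below θ = 0.2 of the
   smaller neighbouring peak (shallower minima are merged, weakest first).

When fewer segments than the protocol's expected repetitions (10) are
found and a finger gyroscope is available, boundaries are instead taken
from zero crossings of the filtered x_rot component — each half-cycle is
one flexion or extension. The expected count only triggers the fallback;
it never forces a segment count.

Per-movement statistics (mean speed, max speed, duration, smoothness =
mean/max speed) are computed on the segment's own samples. For an ideal
minimum-jerk reach the smoothness is 1/1.875 ≈ 0.533; the sampled,
floor-trimmed estimator lands within ±0.02 of this, which is the tolerance
the tests assert.

Hand-open events are positive x_rot peaks with prominence at least half
the median positive-peak prominence (computed on a min-padded signal so
edge peaks keep full prominence) and 0.25 s spacing. Stride events are
z_rot peaks above mean + 1 SD with 0.5 s spacing and an absolute 0.5 rad/s
floor so noise-only recordings yield zero strides. Ties between
equal-height candidates resolve to the earlier peak (the peak finder scans
left to right).

## The 62-metric inventory

The exam's published description never enumerates its 62 metrics; the
inventory here is a documented reconstruction constrained to that total:
10 metrics for each of the three reaching tasks ({mean speed, max speed,
duration, smoothness} × {mean, SD}, movement count, wrist path length);
3 for each opening–closing task (movement time = task time / number of
openings; inter-peak-interval mean and SD); 1 total completion time for
the complex sequence; 2 band-power ratios (multitaper and FFT) for each
tremor hold — rest band 3–6 Hz, postural band 5–8 Hz; 8 for each balance
condition (CoP path length, AP/ML SDs, 95% covariance-ellipse major/minor
axes and area, trunk jerk mean and peak); and 5 gait metrics (mean walk
time; normalized jerk = mean L5 jerk amplitude / mean speed with speed =
10 m / walk time, averaged over walks 1–2; stride-duration mean and SD
and stride count averaged over walks 3–4, the count rounded half-up).
Alternate tremor computations (mean in-band power, mean total power, both
estimators) are produced as auxiliary outputs outside the inventory, as
are per-task completion times. The CoP ellipse uses the χ²(2) 95% quantile
(5.991): axis length 2·√(5.991·eigenvalue), area π·5.991·√det(cov).
Analyses use the subject's most affected side (session metadata).

Missingness is data, not failure: a vector always carries 62 named
entries plus a per-metric missing mask (a session without a force plate
flags exactly the 12 CoP metrics, for instance).

## Dimensionality

Variables are standardized to mean 0, SD 1 (n−1 denominator); constant
columns are dropped with a log entry; missing metric values are imputed by
the cohort median before standardization. PCA is an SVD of the centered
standardized table; the variance-explained curve is the quantity of
interest. The UPDRS variables entering PCA are the 14 aggregate item
scores (per-limb sub-items are supported but off by default).

## Prediction

The elastic net minimizes
(1/2n)·Σ(y − β₀ − Xβ)² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²); the solver is
scikit-learn's coordinate descent (duality-gap tolerance 1e-7 for reported
fits; 1e-5 with Gram precomputation along the warm-started hyperparameter
paths, with the selected model refit at the tight tolerance). Degrees of
freedom = number of nonzero coefficients, computed on the full-data fit;
any (α, λ) whose DF exceeds ⌊0.5·n⌋ is discarded. Grids: α from 0.1 to
1.0 in steps of 0.1; per α, 50 log-spaced λ values from λ_max =
max|Xᵀy|/(n·α) down to 10⁻³·λ_max. The surviving pair with the highest
leave-one-out R² wins; ties break to smaller DF, then larger λ. LOOCV
refits every fold from scratch and re-standardizes features and centers
the outcome inside the training fold, so the held-out subject never leaks
into the scaling. The same LOOCV used for selection is reported — a
single-level search, not nested CV — so the reported R² carries the usual
optimistic-selection bias; with 500 grid points on n = 50 this bias is
real but modest, and it is stated rather than hidden.

Day-2 transfer applies the frozen day-1 model (coefficients and
standardization) without refitting. Cluster augmentation appends one-hot
cluster indicators, penalized like any feature; within each LOOCV fold the
held-out subject's indicator comes from its nearest neighbour in
standardized metric space among training subjects — the best-matching-unit
analogue that works for any label source, so no label leaks.

## Phenotyping

* t-SNE (perplexity 30, learning rate 200, 1000 iterations, PCA init)
  followed by K-means (10 restarts). Cohorts with n ≤ 3·perplexity warn
  rather than fail; desk-scale cohorts of 50 are the intended regime.
* SOM: rectangular grid (default 6×6), online training, Gaussian
  neighbourhood with radius decaying linearly from its initial value to 1
  and learning rate from 0.5 to 0.01, seeded random N(0,1) weight
  initialization in standardized space. The configuration search (grid
  sizes × epochs × initial neighbourhoods × 10 restarts) keeps the model
  with the lowest quantization error (mean distance of samples to their
  best-matching unit).
* Ward linkage on the neuron weights, cut at k = 2, 3, 4; subjects inherit
  their BMU's cluster. Cuts of one dendrogram are nested by construction.
* Random-forest importance: a bagged forest of CART trees (500 trees,
  √p features per split) with explicit seeded bootstrap indices, so
  Breiman-style out-of-bag permutation importance is exact: per tree, the
  OOB accuracy drop when one feature is permuted, averaged over trees,
  then over 10 forest seeds; the top 10 features are reported. The bagging
  is implemented in-package because the stock forest class does not expose
  OOB permutation importance.
* Dominance: per feature, one-way ANOVA across clusters; if p < 0.05,
  pairwise two-sample t-tests Bonferroni-corrected by the number of
  cluster pairs; each significant pair awards one win to the cluster with
  the higher feature median. The pairwise t-test is the package's choice
  of post-hoc test; the table equals an independent brute-force loop on
  every test fixture.
* Clinical subtyping: ratio of mean tremor items (Q20, Q21) to mean
  akinetic-rigid items (Q22–Q26, Q31); tremor-dominant at ≥ 1.5,
  akinetic-rigid at ≤ 1/1.5, mixed between; a zero denominator gives
  tremor-dominant when the numerator is positive and mixed when both are
  zero. Item sets and thresholds are config-exposed defaults of the
  ratio-based subtyping family.

## Synthetic data generator

The generator encodes the exam protocol (10 repetitions, 30 s rest hold,
15 s postural hold, 15 s balance holds, four 10 m walks) and links five
latent severities in [0,1] — bradykinesia, rest tremor, postural tremor,
postural instability, gait impairment — to the signals:

* reaches: alternating minimum-jerk strokes of 0.45 m with duration
  T = 0.4·(1 + 1.5·s_brady) s (hand-to-nose 1.4× slower at its natural
  pace) and task-specific pauses (0.15 s continuous, 2 s discrete);
* opening–closing: sinusoidal x_rot bursts with period
  0.5·(1 + 1.5·s_brady) s, spanning ≈ 0.5 s (healthy) to ≈ 1.25 s
  (severe) movement times;
* complex sequence: completion time 20·(1 + 1.15·s_brady) s;
* tremor: sinusoid on the finger accelerometer (rest 3.5–5.5 Hz, postural
  5.5–7.5 Hz, per-subject random frequency and phase) with amplitude
  0.02 + 0.25·s m/s², sized against the 0.05 m/s² white + 0.03 m/s² 1/f
  sensor noise so the band-power ratio sweeps ~0.15–0.93 over the severity
  range instead of saturating;
* balance: CoP as a mean-reverting (rate 0.3 s⁻¹) random walk with
  diffusion 0.1·(1 + 4·s_postural) cm/√s, ×1.5 with eyes closed; trunk
  sway acceleration as 2 Hz-lowpassed noise scaling with s_postural;
* gait: walk time 10/(1.4·(1 − 0.5·s_gait)) s, stride period
  1.0·(1 + 0.4·s_gait) s with Gaussian z_rot bursts at stride times, and
  step-locked L5 accelerations growing with s_gait.

UPDRS items are clip(round(4·(w_item·s) + ε), 0, 4) with rater noise
ε ~ N(0, 0.3) by default; the fixed weight matrix maps Q20/Q21 to the
tremor severities, Q23–Q26/Q31 to bradykinesia, Q27–Q30 to postural/gait,
Q22 half to bradykinesia, and the two non-limb items (Q18, Q19) to the
mean severity so a fully severe profile saturates every item. Cohorts draw
domain severities as clip(g + N(0, 0.15)) around a global g ~ Beta(2,2),
or, in planted-phenotype mode, as a base level 0.15 with one signature
domain elevated by 0.6 per archetype (tremor-, bradykinesia-, or
instability-dominant). A day-2 replicate adds N(0, 0.05) severity drift.
One seed fixes all randomness through spawned generator streams.

What the generator does **not** emulate: multi-joint coupling and
compensatory movement, camera occlusion and tracking failures, asymmetric
or intermittent (re-emergent) tremor, medication-state fluctuation,
freezing of gait, turns, and nonstationarity within a task. Passing
parameter-recovery tests therefore demonstrates that the pipeline's
machinery is correct and sensitive in the designed directions — not that
its accuracy transfers to clinical recordings.

## Problem sizes and verification

The test suite and the acceptance script run everything at the study's
desk scale: cohorts of n = 50, ten simulation seeds for the recovery
suites (score prediction R² > 0.3 in ≥ 9/10 cohorts; SOM+Ward ARI ≥ 0.8
against planted phenotypes in ≥ 8/10; severity–metric Spearman |ρ| > 0.7
with the designed signs). Closed-form oracles pin down the signal layer
(minimum-jerk smoothness, analytic filter responses, flat-spectrum
band-power expectation 3/31.5 ≈ 0.095, polyline CoP path lengths), and
brute-force reimplementations pin down LOOCV, dominance counting, and the
λ→0 OLS limit. Published cohort-specific values (e.g. prediction accuracy
on real patients) are not reproducible without the clinical recordings
and are not asserted anywhere.

## Known limitations

* The 62-metric inventory is a reconstruction; other decompositions
  reaching the same total are conceivable.
* Segmentation thresholds (θ = 0.2, refractory times, activity and edge
  floors) are config-exposed choices validated on synthetic fixtures, not
  fitted to clinical data.
* The grid-search R² is optimistically biased (selection and evaluation
  share the LOOCV); a nested CV would be the conservative alternative.
* The SOM is an online implementation with linear decay schedules; batch
  SOM variants would converge differently.
* t-SNE at n = 50 with perplexity 30 violates the usual heuristic and is
  kept only because the analysis it mirrors used those settings; treat the
  embedding as illustrative.
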