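# Methods

## Problem and pipeline

`spastimu` implements an automated grading of elbow spasticity on the
modified Ashworth scale (MAS) from a wearable inertial measurement unit
(IMU) worn on the forearm during a passive stretch test: a therapist
holds the relaxed limb still, then moves the elbow through five
flexion–extension cycles at one cycle per second while triaxial
acceleration (g) and angular velocity (deg/s) are sampled at 256 Hz.
The six MAS grades {0, 1, 1+, 2, 3, 4} are encoded as integer class
labels 0–5 and treated as nominal classes (the 1+ grade makes the scale
ordinally ambiguous, so grading is posed as multiclass classification,
not ordinal regression).

The pipeline stages, in order:

1. **Simulation** — labeled synthetic recordings (below).
2. **Preprocessing** — the quasi-static baselines are located by
   thresholding the gyroscope vector magnitude and discarded; the active
   interval is split into five equal-length blocks and the middle three
   kept, isolating the three most stable movement cycles.
3. **Segmentation** — each portion is windowed two ways: three disjoint
   windows of `floor(L/3)` samples (dataset DS1) or five windows of the
   same length hopping by half a window, i.e. 50% overlap (dataset DS2).
4. **Features** — per window, seven statistics (RMS, mean, SD, energy,
   spectral energy, mean absolute successive difference, variance) on
   each of the six raw channels give the 42-feature set FS1; adding the
   same statistics on the per-sample accelerometer roll
   `(180/π)·atan2(ay, az)` and pitch `(180/π)·atan2(ax, az)` series plus
   the signal magnitude area `SMA = Σ(|xᵢ|+|yᵢ|)/n` and signal vector
   magnitude `SV = Σ√(xᵢ²+yᵢ²)/n` of the accelerometer x/y axes gives
   the 58-feature set FS2.
5. **Evaluation** — DT, RF, SVM, LDA and MLP classifiers under
   leave-one-out cross-validation for every dataset × feature-set cell;
   accuracy = matching-label fraction; conditions summarized by median
   accuracy and compared with two-sided Wilcoxon signed-rank tests at
   α = 0.05 (raw p-values, no multiple-testing correction).

## Synthetic-data generator

No public corpus of MAS-labeled passive-stretch recordings exists, so
the package ships a generator whose defaults define the study
conditions: a 48-subject cohort with 17/13/7/6/4/1 subjects at grades
0–4 (1+ counted between 1 and 2), 1 s quasi-static holds around five
1-second cycles, 256 Hz sampling.

The elbow is a single-axis hinge starting at full flexion (angle 0).
Each half-cycle follows a raised-cosine angle profile (half-sine
velocity). Grade enters through two monotone parameter maps:

| label (MAS)    | 0 (0) | 1 (1) | 2 (1+) | 3 (2) | 4 (3) | 5 (4) |
|----------------|------|------|------|------|------|------|
| ROM (deg)      | 150  | 135  | 120  | 100  | 65   | 15   |
| catch depth    | 0    | 0.30 | 0.45 | 0.60 | 0.75 | 0.90 |
| catch position | –    | 0.80 | 0.65 | 0.50 | 0.45 | 0.40 |

The *catch* — the velocity-dependent resistance that defines low-grade
spasticity — is a multiplicative Gaussian notch (SD 0.08 of the
extension half-cycle) in the extension velocity profile, centered where
the angle passes the grade's catch position (late in range for MAS 1,
progressively earlier and deeper for higher grades); the cumulative sum
is renormalized so each cycle still attains its excursion. MAS 0 has no
notch by definition; MAS 4 is near-rigid (15° of excursion under the
therapist's force). ROM must be non-increasing and depth non-decreasing
in the label; the configuration validates both.

Two stochastic layers make the classification task non-trivial:

* **Inter-subject variability** — each subject draws a ROM (relative SD
  3%), catch position (absolute SD 0.03) and catch depth (absolute SD
  0.03) around the grade's nominal values. Without it, all subjects of
  a grade would be identical up to sensor noise and any classifier
  would succeed trivially.
* **Cycle-to-cycle variability** — each of the five cycles perturbs the
  subject's excursion and depth by a relative SD of 5%, reflecting that
  hand-moved cycles are never identical. This is also what gives
  overlapping windows genuinely new information (window boundaries fall
  differently), the mechanism behind the overlap-advantage analysis.
* **Sensor noise** — i.i.d. Gaussian noise per axis, default 0.02 g and
  2 deg/s. Noise is generated as SD × unit normal draws from a stream
  whose length does not depend on the SD, so configurations differing
  only in noise scale share their underlying randomness (common random
  numbers), which stabilizes noise-sweep comparisons.

The cycle period is *not* jittered: the protocol paces the therapist at
one cycle per second, and a fixed period keeps the default recording at
exactly 7 s (1792 samples).

Forward sensor model: the designated gyroscope axis (x) carries the
first difference of the angle times the sample rate; the accelerometer
reads the gravity unit vector rotated through the elbow angle
(ay = sin θ, az = cos θ), so noiseless roll recovers the trajectory
exactly. The remaining axes carry noise only. The magnetometer present
on real devices is not simulated (no feature uses it), and no
musculoskeletal dynamics are modeled.

What passing tests on this generator do **not** show: robustness to
sensor misplacement or off-axis rotation, voluntary-movement artifacts,
therapist speed drift, EMG-correlated tone changes, or the label noise
of real MAS ratings (inter-rater reliability of the 1/1+ boundary is a
known clinical weakness). Results on synthetic cohorts bound the
method's plumbing, not its clinical accuracy.

## Preprocessing choices

"Determined by the angular velocity" needs a quantitative rule: the
default threshold is 10 deg/s on the gyro vector magnitude with a
0.25 s contiguous-duration debounce — an order of magnitude below the
1 Hz stretch peak velocity for all but the rigid grade, and an order of
magnitude above the default noise floor. The five subsets are
equal-length index blocks, not detected cycles (deterministic, and
faithful to an equal-division reading); remainder samples attach to the
last block and are truncated with it. All indices are 0-based,
half-open.

## Numerical definitions

* Variance/SD are population moments (ddof = 0); `variance = std²`.
* Energy is the mean square; *spectral energy* is `Σ|X_k|²/n²` over all
  DFT bins, which equals the energy by Parseval's theorem. The
  redundancy is deliberate — the pair mirrors the conventional 7-stat
  list and doubles as a numerical cross-check (tested at 1e-9 relative
  tolerance).
* *Absolute difference* is the mean absolute successive difference
  (signal roughness); the alternative reading (mean absolute deviation
  from the mean) was rejected as it duplicates the dispersion features.
* Roll/pitch use quadrant-aware `atan2` on raw accelerometer values (no
  gravity-separation filter: during a slow passive stretch gravity
  dominates the specific force). The degenerate (0, 0) input returns 0
  with a warning.
* Windows are never padded; trailing remainders are discarded (padding
  would distort the spectral features).
* Feature ordering is fixed (channel-major, stats in canonical order,
  then sma, sv) and written as the CSV header, so matrices reproduce
  bit-for-bit.
* Recordings round-trip CSV exactly (17-significant-digit output,
  round-trip float parsing).

## Cross-validation design

The LOOCV unit defaults to the **subject**: all segments of one subject
are held out per fold, so overlapping windows of one subject can never
leak between train and test. Segment-granularity LOOCV is available
behind a flag; it reflects the common setup in the activity-recognition
literature but inflates accuracy for overlapping windows, which is why
both are exposed and the granularity is recorded in every result. The
overlap-advantage replication uses segment granularity deliberately:
under subject granularity the held-out subject contributes no training
windows either way, which removes most of the mechanism being measured.

Classifier hyperparameters are fixed and seeded rather than tuned
(RF: 100 trees; SVM: RBF kernel via scikit-learn's SVC with an
one-vs-rest decision function; MLP: one hidden layer of 64, 500
iterations, no early stopping; DT: unlimited depth; LDA: SVD solver).
Features are z-scored with statistics fit on the training fold only.
The singleton class (MAS 4, one subject) necessarily trains absent from
its own fold under subject-level LOOCV; this is logged, its recall is
reported as missing where undefined, and per-class aggregates exclude
undefined entries rather than imputing 0.

The Wilcoxon signed-rank test drops zero differences, uses the exact
null distribution when the effective n ≤ 25 with tie-free absolute
differences, and otherwise a tie-corrected normal approximation
(reporting Z). Tests are cross-checked against a full 2⁵
sign-enumeration oracle in the suite.

## Problem sizes used in the checked analyses

The structural checks run the full 48-subject cohort once. The
parameter-recovery analysis scores RF on DS2/FS2 under subject-level
LOOCV over the five classes with at least two subjects, averaged over
10 cohort replicates, in two designs: (a) an *easy-regime* cohort —
catch depths (0, 0.30, 0.50, 0.70, 0.85, 0.95), kinematic jitters at
1% (cycle 2%), sensor noise 0.01 g / 1 deg/s — where the grades are
cleanly separated and near-perfect recovery is expected; and (b) the
default study cohort swept across sensor noise levels
(accel SD ∈ {0.01, 0.05, 0.2} g paired with gyro SD ∈ {1, 5, 20}
deg/s), where accuracy sits off its ceiling (≈0.89 at the lowest
level) and its monotone degradation with noise is measurable. The
overlap-advantage analysis uses 10 replicate cohorts at 0.25 g /
25 deg/s — a regime chosen a priori where gyro noise obscures the
catch signature — comparing DS1 vs DS2 with RF/FS2 under segment-level
LOOCV and a paired Wilcoxon test.

## Known limitations

* The trajectory model is kinematic, not biomechanical; catch geometry
  and grade parameter values are plausible but invented, and live in
  the configuration rather than the code so they can be re-estimated if
  labeled recordings become available.
* The published device placement is ambiguous (elbow dorsum vs wrist);
  the simulator models a forearm-mounted sensor rotating with the elbow
  angle, and the downstream pipeline is placement-agnostic.
* Only 0% and 50% overlap ship as schemes; window/hop are internal
  parameters, but other overlaps are untested.
* The per-class "accuracy" column is the mean of precision and recall,
  a convention chosen to match the shape of per-class reports in this
  literature; it is not the overall accuracy restricted to that class.
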