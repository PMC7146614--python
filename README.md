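# spastimu

Automated grading of **elbow spasticity** on the modified Ashworth
scale (MAS) from a wearable inertial measurement unit (IMU), for
rehabilitation-engineering researchers and developers of remote
assessment tools.

During a passive stretch test a therapist moves the relaxed elbow
through five flexion–extension cycles at one cycle per second while a
forearm-mounted sensor records triaxial acceleration **a** (g) and
angular velocity **ω** (deg/s) at 256 Hz. Spasticity — a
velocity-dependent increase in muscle tone — shows up in these signals
as a grade-dependent range of motion and a *catch*, a transient
velocity drop during extension. `spastimu` turns such recordings (or
simulated ones; no public labeled corpus exists) into a six-class MAS
grade via:

1. **Preprocessing** — discard quasi-static baselines by thresholding
   ‖ω‖, keep the middle three of five equal subsets of the active
   interval;
2. **Segmentation** — window each portion without overlap (3 windows,
   dataset DS1) or with 50% overlap (5 windows, dataset DS2);
3. **Features** — per window, 7 statistics (rms, mean, std, energy,
   spectral energy, mean |Δ|, variance) × 6 channels = 42 features
   (FS1); plus the same statistics on roll = (180/π)·atan2(a_y, a_z)
   and pitch = (180/π)·atan2(a_x, a_z), and
   SMA = Σ(|x_i|+|y_i|)/n, SV = Σ√(x_i²+y_i²)/n over the accelerometer
   x/y axes → 58 features (FS2);
4. **Classification** — DT, RF, SVM, LDA and MLP under leave-one-out
   cross-validation, Accuracy = (1/N)·Σ I(g(x) = ĝ(x)), median
   accuracies per condition, and two-sided Wilcoxon signed-rank
   comparisons (α = 0.05) of feature sets and segmentation schemes.

See `docs/methods.md` for the generative model, parameter tables and
design rationale.

## Worked example

```python
from spastimu import (STUDY_COHORT, SimulationConfig, simulate_cohort,
                      preprocess_recording, build_segment_table,
                      feature_table, loocv)

recordings = simulate_cohort(STUDY_COHORT, SimulationConfig(), seed=1)
portions = [preprocess_recording(r) for r in recordings]
segments = build_segment_table(portions, "overlap50")      # dataset DS2
table = feature_table(segments, "FS2")                     # 58 features
result = loocv(table, "RF", granularity="subject", seed=1)
print(len(recordings), len(segments), table.shape)
print(f"RF accuracy: {100 * result.accuracy:.1f}%")
```

prints

```
48 240 (240, 61)
RF accuracy: 87.9%
```

48 subjects (17/13/7/6/4/1 across MAS 0, 1, 1+, 2, 3, 4) yield 240
50%-overlap segments; the feature matrix has 58 feature columns plus 3
metadata columns; a 100-tree random forest, evaluated by
leave-one-*subject*-out cross-validation so overlapping windows never
leak between train and test, grades 87.9% of held-out segments
correctly. The residual errors concentrate on the clinically ambiguous
MAS 1 / 1+ boundary and on MAS 4, which has a single subject and
therefore can never appear in its own training fold.

The same run from the shell:

```bash
spastimu run-all --out out/ --seed 1          # full 2x2x5 grid + report.json
spastimu simulate --out raw/ --seed 1         # or stage by stage
spastimu preprocess --in raw/manifest.csv --out portions/
spastimu segment --in portions/portions.csv --scheme overlap50 --out segs/
spastimu featurize --in segs/segments.csv --set FS2 --out features.csv
spastimu evaluate --features features.csv --classifier RF --seed 1 --out eval.json
```

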