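# armsmooth

Movement-smoothness analysis for wrist-worn inertial sensors: from raw free
accelerations and orientations to segmented arm-elevation trials,
phase-resolved jerk metrics, jerk ratios, and reliability/comparison
statistics.

## The problem

Clinicians examining the shoulder judge the *quality* of arm movement —
its smoothness — by eye. Wrist IMUs make that quantitative: a sensor on
each wrist records free linear acceleration (gravity removed) and
orientation at 100 Hz while the subject performs repeated maximal arm
elevations in different planes (sagittal, scapular, frontal) plus
functional tasks (hair combing, low back washing). Smoothness is captured
by the **jerk**, the amount of acceleration variation: for a sensor *s*
over a window [t₀, t₁],

```
J_s(t0, t1) = Σ_{t=t0}^{t1} ‖a_s(t+1) − a_s(t)‖²
```

the summed squared first differences of the (10 Hz low-pass filtered) free
acceleration — lower is smoother. Scaling by the sample rate turns this
into a sampled estimate of the continuous squared-jerk integral
∫‖r⃛(t)‖² dt, whose minimum over point-to-point movements is attained by
the minimum-jerk quintic (720·D²/T⁵ for displacement D in time T). Two
jerk quantities are compared via the normalized **jerk ratio**

```
r_{1/2} = J1 / (J1 + J2)
```

(0.5 = equally smooth; 0.1 = motion 1 far smoother), and the two arms
fuse into a total-motion jerk `J_total = sqrt(J_left² + J_right²)`.

The pipeline around the metric:

1. **Kinematics** — build the subject frame (x forward, z vertical) from
   the forehead and lower-back sensors at rest; derive acceleration norms,
   the elevation angle θ_E (0° arm down … 180° arm up) and the
   horizontal-plane angle θ_H (valid for 30° ≤ θ_E ≤ 150°); zero-phase
   4th-order Butterworth filtering at 10 Hz.
2. **Segmentation** — a random-forest classifier (40 trees, trained on a
   hand-labelled 20% bootstrap) yields a motion probability p(t); an exact
   dynamic program cuts it into 7 alternating rest/motion segments (each
   1–20 s); each motion segment splits into ascending/lowering phases at
   the mid-elevation timestep minimizing a local mirror-symmetry loss of
   θ_E (window w = 100 samples).
3. **Statistics** — ICC(3,1)/ICC(2,1) with SEM and MDC95 for
   repeatability/reliability, per-subject medians (3 sessions × 3 trials),
   and paired two-sided Wilcoxon signed-rank tests with Bonferroni
   correction for laterality, contraction-phase and elevation-plane
   comparisons.

Because no public recordings exist, the package ships a synthetic-recording
generator with full ground truth (segment boundaries, mid-elevation
timesteps, injected smoothness asymmetries), so every stage is testable.

## Worked example

```python
import armsmooth as am
from armsmooth.kinematics import lowpass

session = am.simulate_session([am.MOVEMENT_CATALOGUE[0]], rng_seed=7)
mov = session.movements[0]
frame = am.build_subject_frame(mov.sensors["head"].orient[:100],
                               mov.sensors["back"].orient[:100])
kin_l = am.compute_kinematics(mov.sensors["left"], frame)
kin_r = am.compute_kinematics(mov.sensors["right"], frame)
feats = am.extract_features(kin_l, kin_r)
clf, _ = am.train_motion_classifier([feats], [mov.ground_truth.binary_labels()])
p = am.predict_motion_probability(clf, feats, session.fs)
result = am.segment_movement(p, kin_l, kin_r)
print("boundaries (s):", [round(b / session.fs, 2) for b in result.boundaries])
print("mid-elevation (s):", [round(m / session.fs, 2) for m in result.midpoints])

accels = {a: lowpass(mov.sensors[a].accel, session.fs) for a in ("left", "right")}
table = am.phase_jerks(accels, result, session.fs)
full = table[table.phase == "full"].groupby("arm")["jerk"].sum()
print(f"J_right = {full['right']:.3f}  J_left = {full['left']:.3f}")
print(f"r_left/right = {am.jerk_ratio(full['left'], full['right']).r:.3f}")
tot = table[table.arm == "total"].groupby("phase")["jerk"].sum()
print(f"r_asc/low = {am.jerk_ratio(tot['ascending'], tot['lowering']).r:.3f}")
```

prints

```
boundaries (s): [3.01, 13.8, 16.82, 27.37, 30.39, 39.84]
mid-elevation (s): [8.4, 22.09, 35.11]
J_right = 0.810  J_left = 0.837
r_left/right = 0.508
r_asc/low = 0.449
```

The segmenter recovers the three ~10 s trials separated by 3 s rests and
their elevation peaks; the left/right ratio slightly above 0.5 reflects
the generator's default dominant-arm asymmetry (the left arm receives more
corrective sub-movements), and the ascending/lowering ratio below 0.5
reflects the smoother concentric phase.

A command-line interface wraps the same stages:

```sh
armsmooth simulate --config demo.yaml --seed 7 --out data/
armsmooth run --in data/ --seed 7 --out reports/
```

producing per-sensor CSV recordings with ground-truth sidecars and, from
them, tidy jerk tables, reliability reports and comparison tables.

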