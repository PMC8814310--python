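# Methods

## Signal model and conventions

A recording session carries four sensors (right wrist, left wrist,
forehead, lower back), each providing a synchronized time series of 3-D
free linear acceleration (m·s⁻², gravity removed, expressed in the sensor
frame) and orientation (3×3 rotation matrices, sensor frame → a shared
common frame) at a nominal 100 Hz.

The **subject frame** has x pointing forward (orthogonal to the frontal
plane), y to the subject's left, z vertical. Its y axis is the renormalised
average of the head and back sensors' facing-related (y) axes after
removing their vertical component, taken over the first second of the
recording (assumed resting); x = y × z. If either facing axis is within
numerical tolerance of the vertical the pose is degenerate and an error is
raised rather than guessing.

The **elevation angle** θ_E is the angle between the downward vertical and
the wrist sensor's long (x) axis: 0° arm hanging, 90° horizontal, 180°
overhead. The **horizontal-plane angle** θ_H is the signed angle (positive
counterclockwise about the upward vertical, seen from above) between the
subject x axis and the horizontal projection of the sensor x axis. Near
the poles the projection degenerates, so θ_H carries a validity mask that
is true exactly where 30° ≤ θ_E ≤ 150°.

**Filtering.** A 4th-order Butterworth low-pass at 10 Hz, applied forward
and backward (zero phase, effective 8th order, −6 dB at the cutoff). Phase
lag would bias the mid-elevation estimate, which is why the zero-phase
variant is used. Acceleration channels are filtered before taking norms;
angles are computed from unfiltered orientations and θ_E is then filtered
with the same filter. Note that a second filtering pass is only a strict
no-op for content well below the cutoff (passband droop scales as
(f/10 Hz)⁸ per pass); arm-elevation content lives near 0.1–1 Hz where the
double-pass difference is below 10⁻⁶ relative RMS.

## Jerk metrics

The discrete jerk of a window [t₀, t₁] is the literal sum of squared first
differences of the filtered free acceleration,
J = Σ ‖a(t+1) − a(t)‖², with the sum consuming samples up to a(t₁+1).
Lower is smoother; the value is sample-rate dependent (units m²·s⁻⁴). The
`physical=True` variant multiplies by fs, giving a consistent estimator of
the continuous squared-jerk integral ∫‖r⃛‖² dt (m²·s⁻⁵): since
‖Δa‖² ≈ ‖jerk‖²·Δt², the scaled sum is a midpoint-rule quadrature with
O(fs⁻²) error. On the minimum-jerk quintic (D = 1, T = 1, analytic
integral 720) the scaled sum is accurate to 0.05% at 100 Hz and 5·10⁻⁶
at 1 kHz.

Left/right fusion uses the root-sum-of-squares rule
J_total = √(J_left² + J_right²) (a plain-sum alternative sits behind a
config switch). The same RSS pattern combines the per-side symmetry
losses. The jerk ratio r = J₁/(J₁+J₂) is the normalized comparison used
throughout; it is strictly increasing in J₁, complements to 1 under
exchange, and is undefined only when both jerks vanish.

Jerk is computed in the sensor frame: the norm of an acceleration
difference is invariant under any fixed rigid rotation, so transforming to
the subject frame would not change the metric.

## Segmentation

Each movement recording holds three trials of the same movement separated
by rests. Segmentation is semi-supervised:

1. **Motion probability.** A random forest (40 trees, fixed seed) maps the
   per-timestep features (‖a_left‖, ‖a_right‖, θ_E left, θ_E right) to
   P(motion). It is trained on a deterministic 20% bootstrap subset of the
   cohort; for synthetic data the generator's ground-truth labels stand in
   for manual annotation.
2. **Constrained change points.** The probability (smoothed with a 0.2 s
   moving average to suppress single-step flicker) is cut into exactly 7
   segments by dynamic programming minimizing the within-segment squared
   deviation from the segment mean, subject to every segment duration
   lying strictly inside (1 s, 20 s). Labels alternate
   rest/motion/rest/…, starting and ending at rest. The DP is exact: it
   returns the global optimum over all feasible boundary placements or
   raises if no placement is feasible.
3. **Mid-elevation.** Within each motion segment the
   ascending/lowering split point minimizes the combined local symmetry
   loss L(t) = √(L_left(t)² + L_right(t)²) with
   L_s(t) = (1/w)·Σᵢ₌₁..w (θ_E(t−i) − θ_E(t+i))², w = 100 samples.
   Candidates keep a margin of w from the segment ends; exact ties break
   toward the segment centre, then toward the earlier candidate. A
   constant (resting) contralateral arm contributes zero loss, so
   unilateral movements are handled by the same rule.

Functional movements (hair combing, low back washing) have no
mirror-symmetric midpoint; they are segmented but only full-window jerks
are computed for them.

## Statistics

Reliability uses the single-measurement intraclass correlations from the
two-way ANOVA decomposition: ICC(3,1) = (MSR−MSE)/(MSR+(k−1)MSE)
(consistency; trial-to-trial repeatability) and
ICC(2,1) = (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n) (absolute agreement;
between sessions/observers). Negative estimates are reported as computed.
Precision: SEM = SD·√(1−ICC) with SD the across-subject standard
deviation of the occasions entering the ICC, and MDC95 = 1.96·√2·SEM.
Classification bins: <0.40 poor, 0.40–0.59 fair, 0.60–0.74 good,
>0.74 excellent.

Comparisons use one value per subject (the median of the 9 session×trial
values), a two-sided Wilcoxon signed-rank test on the paired jerks (zero
differences dropped; exact null for ≤25 untied pairs, continuity-corrected
normal approximation otherwise), Bonferroni correction within each
comparison family (7 laterality, 7 phase, 5 plane comparisons), and the
across-subject mean jerk ratio as the descriptive effect size. The mean
ratio is reported descriptively alongside the test rather than being the
test statistic itself.

## The synthetic-data generator

The generator emulates the recording protocol: per movement, three trials
of ~10 s (uniform ±10% duration jitter) separated by 3 s rests, a 3 s lead
rest and a 10 s trailing (inter-movement) rest, giving the 4-rest/3-motion
segment structure with every segment inside the (1 s, 20 s) constraint.
The arm is a single rigid segment (elbow extended) of 0.6 m; a trial's
elevation is a minimum-jerk quintic rise to the peak followed by a
minimum-jerk descent, optionally skewed so the peak leads or lags the
temporal midpoint. The elevation plane is fixed per analytic movement
(convention: 90° sagittal, 40° scapular, 0° frontal); functional
movements sweep the plane during the trial and have no symmetric midpoint.
Orientations are built analytically from the commanded angles (the common
frame is a random yaw of the subject frame, since orientation software
provides the vertical); free acceleration is the numerical second
derivative of the wrist position. Noise-free signals round-trip through
the kinematics module to the commanded angles within 10⁻⁶ degrees.

Smoothness structure is injected on top of the smooth profile:

* **saccades** — Gaussian-windowed acceleration pulses (default peak
  0.4 m·s⁻², σ = 0.05 s, Poisson counts per arm×phase) confined to the
  motion support; they model corrective sub-movements, stay differentiable
  after filtering, and strictly increase the discrete jerk. Default rates
  make the dominant (right) arm and the ascending phase smoother
  (1/2 right asc/low, 1.5/3 left asc/low per trial);
* **physiologic tremor** — an 8–12 Hz sinusoid (default 10 Hz,
  0.05 m·s⁻²) in a random direction during motion only (action tremor);
* **sensor noise** — white Gaussian noise, SD 0.02 m·s⁻² on every channel,
  the RMS noise floor of an MTw-class accelerometer (~0.003 m·s⁻²·Hz^-½
  over a ~50 Hz band).

A separate cohort-level generator draws per-subject/session/trial jerk
pairs directly for statistical studies: a latent left/right ratio per
subject (Normal(0.53, 0.02) — a dominant-arm asymmetry typical of healthy
right-handed adults, sized so a cohort of 29 detects it decisively, raw
Wilcoxon z ≈ 4.2), a log-normal subject baseline (median 2.5, log-SD 0.4),
a session factor (log-SD 0.10) *common to both arms* — the physiologic
session state cancels in laterality ratios while still degrading
between-session reliability of raw jerks — and independent per-trial noise
(log-SD 0.10, consistent with good-to-excellent intra-session
repeatability, ICC(3,1) ≈ 0.85–0.95, on the raw jerks).

What the generator does **not** emulate: scapulohumeral rhythm and
multi-joint coordination, gravity-inclusive raw accelerometry, orientation
estimation error (orientations are exact up to the commanded profile),
magnetometer disturbance, and realistic inter-subject kinematic
variability. Passing tests therefore show the pipeline recovers structure
it is designed for under controlled, physiologically plausible
distortions; they do not certify performance on human recordings.

## Numerical choices and degenerate inputs

* The continuous-jerk oracle interpolates each coordinate with a quintic
  spline and integrates the squared third derivative with Simpson's rule;
  repeated `np.gradient` edge stencils amplify to O(1/h) errors at the
  boundaries and are avoided.
* The segmentation DP's duration bounds are strict: a segment of exactly
  1 s or 20 s at fs is infeasible (`floor(min·fs)+1` … `ceil(max·fs)−1`
  samples).
* Jerk windows: motion segments are half-open [start, end); the
  full-window sum runs t = start … end−2 (consuming the segment's last
  sample), the ascending window ends at the midpoint and the lowering
  window starts there, so phase jerks add exactly to the full-window jerk.
* Ties in the midpoint search are broken deterministically (centre-most,
  then earliest); ICC with zero total variance, ratios of two zero jerks,
  all-zero paired differences, and single-class training labels raise
  specific exceptions instead of returning NaN.
* ICC parameter-recovery checks average over replicate simulated studies:
  the rater variance component is estimated from k−1 degrees of freedom,
  so a single study's ICC(2,1) carries irreducible sampling error from the
  rater draw itself (sd ≈ 0.08 at k = 3) regardless of the number of
  subjects.

## Problem sizes used in the shipped studies

Segmentation recovery runs 20 single-movement sessions (~49 s each at
100 Hz); the classifier is trained on the 20% bootstrap subset. ICC
recovery uses 10 replicate studies of 2000 subjects × 50 raters per
variance regime. The Wilcoxon calibration uses 1000 null replicates and 50
effect replicates at n = 29 subjects. Pipeline integration tests use small
cohorts (6–7 subjects, 1–3 movements) — large enough for the exact
signed-rank test to reach significance, small enough to keep the suite
fast.

## Known limitations

* The discrete jerk's absolute scale is sample-rate dependent unless the
  physical scaling is enabled; comparisons within a study at fixed fs are
  unaffected, which is why the literal sum is the default.
* The change-point cost is level-based (piecewise-constant fit to the
  motion probability); a classifier that is systematically uncertain
  (p ≈ 0.5 everywhere) yields arbitrary, though still
  constraint-respecting, boundaries.
* The mid-elevation rule assumes a single dominant peak per trial; motions
  with plateaus or double peaks produce broad symmetry-loss minima where
  the tie-break, not the data, decides.
* Reliability estimates on fully synthetic signal-level cohorts are not
  meaningful unless the generator is given explicit between-subject
  variance; the cohort-level generator exists for that purpose.
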