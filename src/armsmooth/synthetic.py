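"""Synthetic wrist-IMU recordings with known ground truth.

The recording protocol this generator emulates: a seated/standing participant
performs a catalogue of arm movements — bilateral and unilateral maximal
elevations in the sagittal, scapular and frontal planes plus two functional
tasks (hair combing, low back washing).  Each movement is repeated 3 times
(~10 s per trial) separated by 3 s rests, with 10 s rests between movements;
four sensors (both wrists, forehead, lower back) record 3-D free linear
acceleration and orientation at 100 Hz.

The arm is modelled as a single rigid segment (elbow extended) of fixed
length; a trial's elevation angle follows a minimum-jerk rise to the peak
followed by a minimum-jerk descent, optionally skewed so the peak is offset
from the temporal midpoint.  On top of the smooth profile the generator
injects Gaussian-windowed acceleration pulses ("saccades", controlling
graded smoothness asymmetries between arms and phases), physiologic tremor
(8–12 Hz sinusoid during motion), and white sensor noise.  Every recording
ships with its ground truth: segment boundaries, mid-elevation timesteps and
injected saccade counts per arm and phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .kinematics import SensorRecording

DEFAULT_FS = 100.0
#: wrist-sensor distance from the shoulder, metres (rigid extended arm)
ARM_LENGTH_M = 0.6
#: default rest durations, seconds: between trials and between movements
DEFAULT_REST_S = {"trial": 3.0, "movement": 10.0}

#: default expected saccade counts per trial for (arm, phase); the dominant
#: (right) arm and the ascending (concentric) phase are smoother
DEFAULT_SACCADE_RATES = {
    ("right", "ascending"): 1.0,
    ("right", "lowering"): 2.0,
    ("left", "ascending"): 1.5,
    ("left", "lowering"): 3.0,
}


@dataclass
class MotionSpec:
    """Parameters of one movement block (3 trials + surrounding rests)."""

    movement_id: str
    laterality: str = "bilateral"  # bilateral | unilateral_right | unilateral_left
    duration_s: float = 10.0
    amplitude_deg: float = 150.0
    plane_deg: float = 90.0  # 90 sagittal, 40 scapular, 0 frontal
    saccade_rate_per_phase: dict = field(
        default_factory=lambda: dict(DEFAULT_SACCADE_RATES)
    )
    saccade_magnitude: float = 0.4  # m/s^2
    saccade_width_s: float = 0.05
    tremor_amplitude: float = 0.05  # m/s^2
    tremor_freq_hz: float = 10.0
    noise_sd: float = 0.02  # m/s^2, MTw-class accelerometer noise floor
    asymmetry_phase_shift_s: float = 0.0
    functional: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidArgumentError("duration_s must be positive")
        if not 0 < self.amplitude_deg <= 180:
            raise InvalidArgumentError("amplitude_deg must lie in (0, 180]")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")
        if not 8.0 <= self.tremor_freq_hz <= 12.0:
            raise InvalidArgumentError("tremor_freq_hz must lie in [8, 12]")
        if any(v < 0 for v in self.saccade_rate_per_phase.values()):
            raise InvalidArgumentError("saccade rates must be non-negative")
        if self.laterality not in ("bilateral", "unilateral_right", "unilateral_left"):
            raise InvalidArgumentError(f"unknown laterality {self.laterality!r}")

    @property
    def active_arms(self) -> tuple[str, ...]:
        if self.laterality == "bilateral":
            return ("right", "left")
        return ("right",) if self.laterality == "unilateral_right" else ("left",)


#: the per-session movement catalogue (execution order of the protocol)
MOVEMENT_CATALOGUE: tuple[MotionSpec, ...] = tuple(
    MotionSpec(movement_id=mid, laterality=lat, plane_deg=plane, functional=fun)
    for mid, lat, plane, fun in [
        ("sagittal_bilateral", "bilateral", 90.0, False),
        ("scapular_bilateral", "bilateral", 40.0, False),
        ("frontal_bilateral", "bilateral", 0.0, False),
        ("hair_combing_right", "unilateral_right", 40.0, True),
        ("hair_combing_left", "unilateral_left", 40.0, True),
        ("low_back_washing_right", "unilateral_right", 90.0, True),
        ("low_back_washing_left", "unilateral_left", 90.0, True),
        ("sagittal_unilateral_right", "unilateral_right", 90.0, False),
        ("sagittal_unilateral_left", "unilateral_left", 90.0, False),
        ("scapular_unilateral_right", "unilateral_right", 40.0, False),
        ("scapular_unilateral_left", "unilateral_left", 40.0, False),
    ]
)


@dataclass
class GroundTruth:
    """Construction-time truth for one movement recording."""

    n_samples: int
    fs: float
    boundaries: list  # 6 interior change-points (sample indices)
    midpoints: list  # one index per motion segment, or None (functional)
    injected_saccades: dict = field(default_factory=dict)  # (arm, phase) -> count

    def __post_init__(self) -> None:
        b = list(self.boundaries)
        if len(b) != 6 or any(b[i] >= b[i + 1] for i in range(5)):
            raise InvalidArgumentError("need 6 strictly increasing interior boundaries")
        if b[0] <= 0 or b[-1] >= self.n_samples:
            raise InvalidArgumentError("boundaries must be interior")
        for (s, e), m in zip(self.motion_segments(), self.midpoints):
            if m is not None and not s < m < e - 1:
                raise InvalidArgumentError("midpoint must lie strictly inside segment")

    @property
    def labels(self) -> list:
        return ["rest", "motion", "rest", "motion", "rest", "motion", "rest"]

    def segments(self) -> list:
        edges = [0, *self.boundaries, self.n_samples]
        return [(edges[i], edges[i + 1]) for i in range(7)]

    def motion_segments(self) -> list:
        return [seg for seg, lab in zip(self.segments(), self.labels) if lab == "motion"]

    def binary_labels(self) -> np.ndarray:
        out = np.zeros(self.n_samples, dtype=int)
        for s, e in self.motion_segments():
            out[s:e] = 1
        return out


@dataclass
class MovementRecording:
    """One movement block: 4 sensor recordings + ground truth."""

    movement_id: str
    spec: MotionSpec
    sensors: dict  # sensor_id -> SensorRecording
    ground_truth: GroundTruth


@dataclass
class Session:
    """A full recorded session: one MovementRecording per movement."""

    movements: list
    fs: float
    vertical: np.ndarray  # common-frame vertical unit vector
    seed: int | None = None


def min_jerk_profile(D: float, T: float, fs: float):
    """Minimum-jerk point-to-point profile (quintic 10τ³ − 15τ⁴ + 6τ⁵).

    Returns ``(t, position, velocity, acceleration)`` sampled at ``fs`` over
    [0, T].  Position moves from 0 to D with zero velocity and acceleration
    at both endpoints; among all five-times differentiable trajectories with
    these boundary conditions it minimises ∫‖x⃛‖²dt = 720·D²/T⁵.
    """
    if T <= 0 or fs <= 0:
        raise InvalidArgumentError("T and fs must be positive")
    if not math.isfinite(D):
        raise InvalidArgumentError("D must be finite")
    n = int(round(T * fs))
    t = np.arange(n + 1) / fs
    tau = np.clip(t / T, 0.0, 1.0)
    pos = D * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = D / T * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    acc = D / T**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)
    return t, pos, vel, acc


def skewed_bell_profile(
    amplitude: float, duration_s: float, fs: float, phase_shift_s: float = 0.0
):
    """Rise-then-fall elevation profile; returns ``(angles_deg, peak_index)``.

    Minimum-jerk ascent to ``amplitude`` over half the duration plus
    ``phase_shift_s``, then minimum-jerk descent back to 0.  The peak index
    is the true mid-elevation timestep.
    """
    t_up = duration_s / 2.0 + phase_shift_s
    t_down = duration_s - t_up
    if t_up <= 0 or t_down <= 0:
        raise InvalidArgumentError("phase shift exceeds half the trial duration")
    _, up, _, _ = min_jerk_profile(amplitude, t_up, fs)
    _, down, _, _ = min_jerk_profile(amplitude, t_down, fs)
    profile = np.concatenate([up, amplitude - down[1:]])
    return profile, len(up) - 1


def functional_profile(amplitude: float, duration_s: float, fs: float):
    """Irregular multi-plane profile emulating a functional task.

    Rise, a wavering hold (no mirror-symmetric midpoint), then descent, with
    the elevation plane sweeping during the trial.  Returns
    ``(angles_deg, plane_deg_series)``.
    """
    t_seg = duration_s / 3.0
    _, up, _, _ = min_jerk_profile(0.8 * amplitude, t_seg, fs)
    _, down, _, _ = min_jerk_profile(0.8 * amplitude, duration_s - 2 * t_seg, fs)
    n_hold = int(round(t_seg * fs))
    th = np.arange(1, n_hold + 1) / fs
    hold = 0.8 * amplitude + 0.1 * amplitude * np.sin(2 * np.pi * 0.7 * th)
    descent = hold[-1] - down[1:] * (hold[-1] / (0.8 * amplitude))
    profile = np.concatenate([up, hold, descent])
    plane = np.linspace(90.0, 20.0, len(profile))
    return np.clip(profile, 0.0, 180.0), plane


def elevation_to_sensor_signals(
    profile_deg: np.ndarray,
    plane_deg,
    fs: float,
    arm_length: float = ARM_LENGTH_M,
    common_rotation: np.ndarray | None = None,
):
    """Forward kinematics: elevation profile → wrist free accel + orientation.

    The wrist sensor sits at ``arm_length`` from the shoulder with its x axis
    along the arm.  Returns ``(accel_sensor, orient)`` where ``accel_sensor``
    is the (T, 3) free acceleration in the sensor frame (second derivative of
    the wrist position, gravity excluded) and ``orient`` the (T, 3, 3)
    sensor→common rotation series.  ``plane_deg`` may be a scalar or a (T,)
    series (functional movements sweep the plane).
    """
    theta = np.asarray(profile_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta > 180):
        raise InvalidArgumentError("elevation angles must lie in [0, 180] degrees")
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    th = np.radians(theta)
    ph = np.radians(np.broadcast_to(np.asarray(plane_deg, dtype=float), theta.shape))

    # arm direction (sensor x axis) in the subject frame, z up
    u = np.stack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), -np.cos(th)], axis=1
    )
    n = np.stack([-np.sin(ph), np.cos(ph), np.zeros_like(ph)], axis=1)
    w = np.cross(u, n)
    r_sf = np.stack([u, n, w], axis=2)  # columns: sensor axes in subject frame

    dt = 1.0 / fs
    pos = arm_length * u
    acc_subject = np.gradient(np.gradient(pos, dt, axis=0), dt, axis=0)
    acc_sensor = np.einsum("tji,tj->ti", r_sf, acc_subject)  # R^T @ a

    orient = r_sf
    if common_rotation is not None:
        orient = np.einsum("ij,tjk->tik", np.asarray(common_rotation, float), r_sf)
    return acc_sensor, orient


def inject_saccades(
    accel: np.ndarray,
    count: int,
    magnitude: float,
    width_s: float,
    rng,
    fs: float = DEFAULT_FS,
    support: tuple[int, int] | None = None,
) -> np.ndarray:
    """Add ``count`` Gaussian-windowed acceleration pulses to a (T, 3) series.

    Pulses have peak amplitude ``magnitude`` (random direction) and temporal
    width ``width_s`` (Gaussian σ), with centres drawn uniformly inside
    ``support`` (a half-open index window; the whole series by default).
    Smooth localized bumps mimic corrective sub-movements rather than sensor
    glitches, so filtered signals stay differentiable.
    """
    if count < 0:
        raise InvalidArgumentError("count must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = np.array(accel, dtype=float, copy=True)
    if count == 0 or magnitude == 0:
        return out
    T = len(out)
    lo, hi = (0, T) if support is None else support
    sigma = max(width_s * fs, 1.0)
    margin = int(math.ceil(3 * sigma))
    c_lo, c_hi = lo + margin, hi - margin
    if c_hi <= c_lo:  # support too narrow: centre the pulses
        c_lo, c_hi = (lo + hi) // 2, (lo + hi) // 2 + 1
    for _ in range(count):
        c = rng.integers(c_lo, c_hi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t0, t1 = max(lo, c - 4 * margin), min(hi, c + 4 * margin)
        idx = np.arange(t0, t1)
        bump = magnitude * np.exp(-0.5 * ((idx - c) / sigma) ** 2)
        out[idx] += bump[:, None] * direction
    return out


def _yaw(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _simulate_movement(
    spec: MotionSpec, rest_s: dict, rng: np.random.Generator, fs: float, q: np.ndarray
) -> MovementRecording:
    n_trials = 3
    durations = [
        spec.duration_s * (1 + rng.uniform(-0.1, 0.1)) for _ in range(n_trials)
    ]
    lead = int(round(rest_s["trial"] * fs))
    gap = int(round(rest_s["trial"] * fs))
    tail = int(round(rest_s["movement"] * fs))

    # assemble the elevation timeline and ground-truth structure
    pieces, boundaries, midpoints, planes = [], [], [], []
    pieces.append(np.zeros(lead))
    cursor = lead
    for i, dur in enumerate(durations):
        if spec.functional:
            prof, plane = functional_profile(spec.amplitude_deg, dur, fs)
            mid = None
        else:
            prof, peak = skewed_bell_profile(
                spec.amplitude_deg, dur, fs, spec.asymmetry_phase_shift_s
            )
            plane = np.full(len(prof), spec.plane_deg)
            mid = cursor + peak
        boundaries.append(cursor)
        pieces.append(prof)
        planes.append((cursor, plane))
        cursor += len(prof)
        boundaries.append(cursor)
        midpoints.append(mid)
        rest_len = gap if i < n_trials - 1 else tail
        pieces.append(np.zeros(rest_len))
        cursor += rest_len
    theta_active = np.concatenate(pieces)
    T = len(theta_active)
    plane_series = np.full(T, spec.plane_deg)
    for start, plane in planes:
        plane_series[start : start + len(plane)] = plane

    gt = GroundTruth(
        n_samples=T, fs=fs, boundaries=boundaries, midpoints=midpoints
    )

    sensors: dict[str, SensorRecording] = {}
    injected: dict[tuple[str, str], int] = {}
    for arm in ("right", "left"):
        active = arm in spec.active_arms
        theta = theta_active if active else np.zeros(T)
        accel, orient = elevation_to_sensor_signals(
            theta, plane_series, fs, common_rotation=q
        )
        if active:
            # physiologic tremor during motion only (action tremor)
            tremor_dir = rng.normal(size=3)
            tremor_dir /= np.linalg.norm(tremor_dir)
            tt = np.arange(T) / fs
            carrier = spec.tremor_amplitude * np.sin(
                2 * np.pi * spec.tremor_freq_hz * tt + rng.uniform(0, 2 * np.pi)
            )
            mask = gt.binary_labels().astype(float)
            accel = accel + (carrier * mask)[:, None] * tremor_dir
            for (seg_start, seg_end), mid in zip(gt.motion_segments(), gt.midpoints):
                phase_windows = (
                    {"full": (seg_start, seg_end)}
                    if mid is None
                    else {"ascending": (seg_start, mid), "lowering": (mid, seg_end)}
                )
                for phase, window in phase_windows.items():
                    rate = spec.saccade_rate_per_phase.get((arm, phase), 0.0)
                    if phase == "full":
                        rate = sum(
                            spec.saccade_rate_per_phase.get((arm, p), 0.0)
                            for p in ("ascending", "lowering")
                        )
                    count = int(rng.poisson(rate))
                    injected[(arm, phase)] = injected.get((arm, phase), 0) + count
                    accel = inject_saccades(
                        accel,
                        count,
                        spec.saccade_magnitude,
                        spec.saccade_width_s,
                        rng,
                        fs=fs,
                        support=window,
                    )
        accel = accel + rng.normal(scale=spec.noise_sd, size=accel.shape)
        sensors[arm] = SensorRecording(arm, fs, accel, orient)

    for sensor_id in ("head", "back"):
        accel = rng.normal(scale=spec.noise_sd, size=(T, 3))
        orient = np.broadcast_to(q, (T, 3, 3)).copy()
        sensors[sensor_id] = SensorRecording(sensor_id, fs, accel, orient)

    gt.injected_saccades = injected
    return MovementRecording(spec.movement_id, spec, sensors, gt)


def simulate_session(
    specs,
    rest_s: dict | None = None,
    rng_seed: int | np.random.Generator = 0,
    fs: float = DEFAULT_FS,
) -> Session:
    """Simulate one recording session (one MovementRecording per spec).

    The common frame is a random yaw rotation of the subject frame (the
    orientation software provides the vertical, so the shared frame is
    arbitrary only in heading).  Fixed seed ⇒ bit-identical output.
    """
    specs = list(specs)
    if not specs:
        raise InvalidArgumentError("need at least one MotionSpec")
    rest_s = dict(DEFAULT_REST_S if rest_s is None else rest_s)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    q = _yaw(rng.uniform(0, 2 * np.pi))
    movements = [_simulate_movement(spec, rest_s, rng, fs, q) for spec in specs]
    seed = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    return Session(
        movements=movements, fs=fs, vertical=np.array([0.0, 0.0, 1.0]), seed=seed
    )


def simulate_rating_study(
    n_subjects: int,
    n_raters: int,
    var_subject: float,
    var_rater: float,
    var_error: float,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Two-way crossed rating data y_ij = μ + s_i + r_j + e_ij.

    Subject, rater and error effects are independent zero-mean Gaussians with
    the given variances; the analytic single-measurement ICCs are
    var_s/(var_s+var_r+var_e) for absolute agreement (ICC(2,1)) and
    var_s/(var_s+var_e) for consistency (ICC(3,1)).
    """
    if n_subjects < 2 or n_raters < 2:
        raise InvalidArgumentError("need at least 2 subjects and 2 raters")
    if min(var_subject, var_rater, var_error) < 0:
        raise InvalidArgumentError("variances must be non-negative")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    s = rng.normal(scale=math.sqrt(var_subject), size=(n_subjects, 1))
    r = rng.normal(scale=math.sqrt(var_rater), size=(1, n_raters))
    e = rng.normal(scale=math.sqrt(var_error), size=(n_subjects, n_raters))
    return s + r + e


def simulate_jerk_cohort(
    n_subjects: int = 29,
    mean_ratio: float = 0.53,
    ratio_sd: float = 0.02,
    n_sessions: int = 3,
    n_trials: int = 3,
    trial_cv: float = 0.10,
    session_cv: float = 0.10,
    base_jerk: float = 2.5,
    base_sigma: float = 0.4,
    rng_seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Cohort-level left/right jerk draws in a fixed laterality regime.

    Each subject carries a latent jerk ratio r_i ~ N(mean_ratio, ratio_sd)
    (truncated to (0.05, 0.95)) relating the left to the right arm,
    J_left = J_right · r/(1−r), a log-normal subject baseline, and
    multiplicative log-normal session and trial noise.  Defaults place the
    cohort in the dominant-arm regime reported for bilateral elevations
    (average left/right ratio ≈ 0.53, strongly significant at n = 29).

    Returns a tidy frame: subject, session, observer, trial, J_right, J_left.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    rows = []
    for subj in range(1, n_subjects + 1):
        ratio = float(
            np.clip(rng.normal(mean_ratio, ratio_sd), 0.05, 0.95)
        )
        j_right = base_jerk * rng.lognormal(0.0, base_sigma)
        j_left = j_right * ratio / (1 - ratio)
        for sess in range(1, n_sessions + 1):
            # the session state (fatigue, physiologic tremor level) is common
            # to both arms, so it cancels in left/right ratios while still
            # degrading between-session reliability of the raw jerks
            sess_fac = rng.lognormal(0.0, session_cv)
            observer = "A" if sess < n_sessions else "B"
            for trial in range(1, n_trials + 1):
                noise = rng.lognormal(0.0, trial_cv, size=2)
                rows.append(
                    {
                        "subject": subj,
                        "session": sess,
                        "observer": observer,
                        "trial": trial,
                        "J_right": j_right * sess_fac * noise[0],
                        "J_left": j_left * sess_fac * noise[1],
                    }
                )
    return pd.DataFrame(rows)
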