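"""Discrete jerk metrics and the jerk ratio.

The smoothness metric is the discrete jerk of a sensor's free acceleration
over a window [t_init, t_end]:

    J(t_init, t_end) = sum_{t=t_init}^{t_end} ||a(t+1) - a(t)||^2

i.e. the summed squared first differences of the (pre-filtered) free
acceleration — lower is smoother.  The literal sum carries units m²·s⁻⁴ and
depends on the sample rate; multiplying by fs recovers the sampled
approximation of the continuous squared-jerk integral ∫‖r⃛‖²dt (m²·s⁻⁵),
since ‖Δa‖² ≈ ‖jerk‖²·Δt².  Two jerk quantities are compared through the
normalized jerk ratio r_{1/2} = J₁/(J₁+J₂): 0.5 means equal smoothness,
values below 0.5 mean motion 1 is smoother.

Left and right arm jerks are fused into a total-motion jerk with a
root-sum-of-squares rule by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedRatioError

ARMS = ("right", "left")
PHASES = ("full", "ascending", "lowering")


@dataclass(frozen=True)
class JerkValue:
    """One discrete-jerk measurement over a sample window."""

    value: float
    sensor_id: str = ""
    t_init: int = 0
    t_end: int = 0
    phase: str = "full"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InvalidArgumentError("jerk value must be non-negative")
        if self.t_end < self.t_init:
            raise InvalidArgumentError("t_end must not precede t_init")


@dataclass(frozen=True)
class JerkRatio:
    """Normalized comparison r = J1 / (J1 + J2) of two jerk quantities."""

    r: float
    numerator_id: str = "1"
    denominator_context: str = "2"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise InvalidArgumentError("jerk ratio must lie in [0, 1]")


def discrete_jerk(
    accel: np.ndarray,
    t_init: int,
    t_end: int,
    physical: bool = False,
    fs: float | None = None,
) -> float:
    """Discrete jerk of a (T, d) acceleration series over [t_init, t_end].

    The sum runs over t = t_init … t_end inclusive and therefore consumes
    samples up to a(t_end + 1).  With ``physical=True`` the sum is scaled by
    ``fs`` so it approximates the continuous squared-jerk integral.
    """
    accel = np.atleast_2d(np.asarray(accel, dtype=float).T).T
    if t_init < 0 or t_end + 1 >= len(accel):
        raise InvalidArgumentError("jerk window must keep t_end + 1 inside the series")
    if t_end < t_init:
        raise InvalidArgumentError("jerk window must span at least 2 samples")
    diffs = np.diff(accel[t_init : t_end + 2], axis=0)
    value = float(np.einsum("ij,ij->", diffs, diffs))
    if physical:
        if fs is None or fs <= 0:
            raise InvalidArgumentError("physical scaling requires a positive fs")
        value *= fs
    return value


def continuous_jerk(
    position: np.ndarray, fs: float, t_init: int = 0, t_end: int | None = None
) -> float:
    """Squared-jerk integral ∫‖r⃛‖²dt of a finely sampled (T, d) trajectory.

    Each coordinate is interpolated with a quintic spline (exact for
    polynomial trajectories up to degree 5, e.g. the minimum-jerk quintic),
    differentiated three times, and the squared norm integrated with
    Simpson's rule; this is the convergence oracle for :func:`discrete_jerk`.
    """
    from scipy.integrate import simpson
    from scipy.interpolate import make_interp_spline

    position = np.atleast_2d(np.asarray(position, dtype=float).T).T
    if t_end is None:
        t_end = len(position) - 1
    if t_init < 0 or t_end >= len(position) or t_end - t_init < 6:
        raise InvalidArgumentError("window outside trajectory support or too short")
    seg = position[t_init : t_end + 1]
    t = np.arange(len(seg)) / fs
    jerk = np.column_stack(
        [make_interp_spline(t, seg[:, d], k=5).derivative(3)(t) for d in range(seg.shape[1])]
    )
    return float(simpson(np.sum(jerk**2, axis=1), x=t))


def total_jerk(j_left: JerkValue, j_right: JerkValue, rule: str = "rss") -> JerkValue:
    """Fuse the two arms' jerks into a total-motion jerk.

    ``rule='rss'`` (default) is sqrt(J_left² + J_right²); ``rule='sum'`` is
    the plain sum.  Windows and phases must match.
    """
    if (j_left.t_init, j_left.t_end, j_left.phase) != (
        j_right.t_init,
        j_right.t_end,
        j_right.phase,
    ):
        raise InvalidArgumentError("total jerk requires matching windows and phases")
    if rule == "rss":
        value = float(np.hypot(j_left.value, j_right.value))
    elif rule == "sum":
        value = j_left.value + j_right.value
    else:
        raise InvalidArgumentError(f"unknown fusion rule {rule!r}")
    return JerkValue(
        value=value,
        sensor_id="total",
        t_init=j_left.t_init,
        t_end=j_left.t_end,
        phase=j_left.phase,
    )


def jerk_ratio(
    j1: "JerkValue | float",
    j2: "JerkValue | float",
    numerator_id: str = "1",
    denominator_context: str = "2",
) -> JerkRatio:
    """Jerk ratio r_{1/2} = J1 / (J1 + J2) of two non-negative jerk values."""
    v1 = j1.value if isinstance(j1, JerkValue) else float(j1)
    v2 = j2.value if isinstance(j2, JerkValue) else float(j2)
    if v1 < 0 or v2 < 0:
        raise InvalidArgumentError("jerk values must be non-negative")
    if v1 + v2 == 0:
        raise UndefinedRatioError("jerk ratio undefined for two zero jerks")
    return JerkRatio(
        r=v1 / (v1 + v2),
        numerator_id=numerator_id,
        denominator_context=denominator_context,
    )


def phase_jerks(
    accels: dict[str, np.ndarray],
    segmentation,
    fs: float,
    functional: bool = False,
    fusion_rule: str = "rss",
    physical: bool = False,
) -> pd.DataFrame:
    """Per-trial, per-arm, per-phase jerk rows for one movement recording.

    ``accels`` maps 'right'/'left' to pre-filtered (T, 3) free acceleration.
    Motion segments are half-open [start, end); the full-window jerk sums
    differences t = start … end−2 so the last sample consumed is the
    segment's own final sample.  The ascending window runs up to the
    mid-elevation timestep and the lowering window from it to the segment
    end, so the two phase jerks add exactly to the full-window jerk.
    Functional movements (no well-defined midpoint) only get full-phase rows.
    """
    rows = []
    motion_segments = segmentation.motion_segments()
    midpoints = segmentation.midpoints if not functional else [None] * len(
        motion_segments
    )
    if not functional and (
        midpoints is None or any(m is None for m in midpoints)
    ):
        raise InvalidArgumentError("analytic movement requires midpoints per segment")
    for trial, ((start, end), mid) in enumerate(zip(motion_segments, midpoints), 1):
        windows = {"full": (start, end - 2)}
        if not functional:
            windows["ascending"] = (start, mid - 1)
            windows["lowering"] = (mid, end - 2)
        for phase, (t0, t1) in windows.items():
            per_arm = {}
            for arm in ARMS:
                per_arm[arm] = JerkValue(
                    value=discrete_jerk(
                        accels[arm], t0, t1, physical=physical, fs=fs
                    ),
                    sensor_id=arm,
                    t_init=t0,
                    t_end=t1,
                    phase=phase,
                )
            per_arm["total"] = total_jerk(
                per_arm["left"], per_arm["right"], rule=fusion_rule
            )
            for arm, jv in per_arm.items():
                rows.append(
                    {
                        "trial": trial,
                        "arm": arm,
                        "phase": phase,
                        "t_init": jv.t_init,
                        "t_end": jv.t_end,
                        "jerk": jv.value,
                    }
                )
    return pd.DataFrame(rows)
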