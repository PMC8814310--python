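"""From raw wrist-IMU streams to the derived kinematic signals.

A recording session provides, per sensor, the free linear acceleration
(gravity removed, expressed in the sensor frame) and the sensor orientation
as a rotation-matrix time series in an arbitrary common frame.  This module
builds the subject frame from the head and lower-back sensors, and derives
the three scalar signals everything downstream consumes:

* the acceleration norm ``‖a(t)‖``,
* the elevation angle ``theta_E`` (0° arm down … 180° arm up), taken between
  the downward vertical and the sensor's long (x) axis,
* the signed horizontal-plane angle ``theta_H`` of the arm's horizontal
  projection, valid only while 30° ≤ theta_E ≤ 150° (near the poles the
  projection degenerates).

All angles are in degrees; accelerations in m·s⁻².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    DegeneratePoseError,
    InvalidArgumentError,
    NumericDegeneracyError,
)

#: elevation band (degrees) inside which the horizontal-plane angle is defined
THETA_H_VALID_BAND = (30.0, 150.0)

_ORTHO_TOL = 1e-6


def _check_rotations(orient: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    rtr = np.einsum("tij,tik->tjk", orient, orient)
    if np.max(np.abs(rtr - np.eye(3))) > tol:
        raise InvalidArgumentError("orientation matrices are not orthonormal")
    if np.any(np.linalg.det(orient) < 0):
        raise InvalidArgumentError("orientation matrices must have determinant +1")


@dataclass
class SensorRecording:
    """Synchronised free acceleration + orientation for one sensor.

    ``orient[t]`` maps sensor-frame vectors into the common frame:
    ``v_common = orient[t] @ v_sensor``.
    """

    sensor_id: str
    fs: float
    accel: np.ndarray  # (T, 3) free linear acceleration, sensor frame
    orient: np.ndarray  # (T, 3, 3) sensor -> common frame

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.orient = np.asarray(self.orient, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise InvalidArgumentError("accel must have shape (T, 3)")
        if self.orient.shape != (len(self.accel), 3, 3):
            raise InvalidArgumentError("orient must have shape (T, 3, 3) matching accel")
        if len(self.accel) < 2:
            raise InvalidArgumentError("recording needs at least 2 samples")
        _check_rotations(self.orient)

    def __len__(self) -> int:
        return len(self.accel)


@dataclass
class SubjectFrame:
    """Rotation mapping the common frame into the subject frame.

    Rows of ``rotation`` are the subject axes expressed in common-frame
    coordinates: x forward (orthogonal to the frontal plane), y to the
    subject's left, z the vertical.
    """

    rotation: np.ndarray  # (3, 3), v_subject = rotation @ v_common

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        r = self.rotation
        if np.max(np.abs(r @ r.T - np.eye(3))) > _ORTHO_TOL:
            raise InvalidArgumentError("subject frame must be orthonormal")
        if np.linalg.det(r) < 0:
            raise InvalidArgumentError("subject frame must be right-handed")


@dataclass
class KinematicSeries:
    """Per-wrist derived scalars on a shared timeline."""

    fs: float
    accel_norm: np.ndarray  # (T,) m/s^2, >= 0
    theta_E: np.ndarray  # (T,) degrees in [0, 180]
    theta_H: np.ndarray  # (T,) degrees in (-180, 180]; meaningful where valid
    valid: np.ndarray = field(default=None)  # (T,) bool mask for theta_H

    def __post_init__(self) -> None:
        if self.valid is None:
            lo, hi = THETA_H_VALID_BAND
            self.valid = (self.theta_E >= lo) & (self.theta_E <= hi)

    def __len__(self) -> int:
        return len(self.accel_norm)


def build_subject_frame(
    head_orient: np.ndarray,
    back_orient: np.ndarray,
    vertical: np.ndarray = (0.0, 0.0, 1.0),
) -> SubjectFrame:
    """Construct the subject frame from head and lower-back orientations.

    The subject y axis is the renormalised average of the two sensors'
    facing-related (y) axes after removal of their vertical component,
    averaged over the supplied (resting) interval; z is the vertical;
    x = y × z completes a right-handed frame, pointing forward.

    Raises
    ------
    DegeneratePoseError
        If either sensor's facing axis is parallel to the vertical, or the
        two horizontalised axes cancel.
    """
    vertical = np.asarray(vertical, dtype=float)
    vertical = vertical / np.linalg.norm(vertical)

    def mean_facing(orient: np.ndarray) -> np.ndarray:
        orient = np.asarray(orient, dtype=float)
        if orient.ndim == 2:
            orient = orient[None]
        axis = orient[:, :, 1].mean(axis=0)  # sensor y axis in common frame
        horiz = axis - np.dot(axis, vertical) * vertical
        n = np.linalg.norm(horiz)
        if n < 1e-8:
            raise DegeneratePoseError(
                "sensor facing axis is (nearly) parallel to the vertical"
            )
        return horiz / n

    y = mean_facing(head_orient) + mean_facing(back_orient)
    n = np.linalg.norm(y)
    if n < 1e-8:
        raise DegeneratePoseError("head and back facing axes cancel")
    y = y / n
    x = np.cross(y, vertical)
    x = x / np.linalg.norm(x)
    return SubjectFrame(rotation=np.stack([x, y, vertical]))


def lowpass(
    series: np.ndarray, fs: float, order: int = 4, cutoff_hz: float = 10.0
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward–backward, effective 2×order).

    DC gain is exactly 1 and the output has no phase lag, at the cost of the
    squared magnitude response (−6 dB at the cutoff).
    """
    series = np.asarray(series, dtype=float)
    if cutoff_hz >= fs / 2:
        raise InvalidArgumentError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0 or order < 1:
        raise InvalidArgumentError("cutoff and order must be positive")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if series.shape[0] <= padlen:
        raise InvalidArgumentError(
            f"series too short for zero-phase filtering (need > {padlen} samples)"
        )
    return signal.sosfiltfilt(sos, series, axis=0)


def accel_norm(accel: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean norm of a (T, 3) acceleration series."""
    return np.linalg.norm(np.asarray(accel, dtype=float), axis=-1)


def _sensor_x_in_subject(orient: np.ndarray, subject: SubjectFrame) -> np.ndarray:
    # sensor x axis in common frame is the first column of each rotation
    x_common = np.asarray(orient, dtype=float)[:, :, 0]
    return x_common @ subject.rotation.T


def elevation_angle(orient: np.ndarray, subject: SubjectFrame) -> np.ndarray:
    """Elevation angle theta_E (degrees) of the sensor long axis.

    Angle between the downward vertical of the subject frame and the sensor
    x axis: 0° with the arm hanging down, 90° horizontal, 180° overhead.
    """
    x_subj = _sensor_x_in_subject(orient, subject)
    cos_e = np.clip(-x_subj[:, 2], -1.0, 1.0)  # dot with (0, 0, -1)
    return np.degrees(np.arccos(cos_e))


def horizontal_plane_angle(
    orient: np.ndarray,
    subject: SubjectFrame,
    theta_E: np.ndarray,
    band: tuple[float, float] = THETA_H_VALID_BAND,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed horizontal-plane angle theta_H (degrees) and its validity mask.

    The sensor x axis is projected onto the subject horizontal plane and the
    signed angle from the subject x axis is measured positive counterclockwise
    about the upward vertical (viewed from above), so +90° is the subject's
    left.  The mask is true exactly where theta_E lies inside ``band``.
    """
    x_subj = _sensor_x_in_subject(orient, subject)
    lo, hi = band
    theta_E = np.asarray(theta_E, dtype=float)
    valid = (theta_E >= lo) & (theta_E <= hi)
    proj_norm = np.hypot(x_subj[:, 0], x_subj[:, 1])
    if np.any(valid & (proj_norm < 1e-12)):
        raise NumericDegeneracyError(
            "zero-length horizontal projection inside the validity band"
        )
    theta_H = np.degrees(np.arctan2(x_subj[:, 1], x_subj[:, 0]))
    theta_H[~valid & (proj_norm < 1e-12)] = np.nan
    return theta_H, valid


def compute_kinematics(
    recording: SensorRecording,
    subject: SubjectFrame,
    filter_order: int = 4,
    cutoff_hz: float = 10.0,
) -> KinematicSeries:
    """Derive the per-wrist kinematic series used by segmentation and jerk.

    Acceleration channels are low-pass filtered before the norm is taken;
    angles are computed from the unfiltered orientations and the elevation
    angle is then filtered with the same zero-phase Butterworth so the
    change-point and midpoint stages see band-limited signals.
    """
    acc = lowpass(recording.accel, recording.fs, filter_order, cutoff_hz)
    theta_e = elevation_angle(recording.orient, subject)
    theta_e_f = np.clip(
        lowpass(theta_e, recording.fs, filter_order, cutoff_hz), 0.0, 180.0
    )
    theta_h, valid = horizontal_plane_angle(recording.orient, subject, theta_e_f)
    return KinematicSeries(
        fs=recording.fs,
        accel_norm=accel_norm(acc),
        theta_E=theta_e_f,
        theta_H=theta_h,
        valid=valid,
    )
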