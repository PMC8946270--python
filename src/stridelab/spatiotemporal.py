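"""Spatial-temporal gait parameters from per-foot events and stride lengths.

The 24 parameters computed here are the conventional clinical quantities:
stance/swing times and percents per foot, the three double/single-support
splits of stance, ZUPT-EKF stride length, left-right symmetry indices and
cadence.  Temporal quantities are computed per stride from the event times
and then averaged across strides; the symmetry indices are taken on the
per-foot averages.

Stride length comes from foot-mounted strap-down inertial navigation: the
foot is (almost) stationary during mid stance, so zero-velocity intervals are
detected and used as pseudo-measurements in an error-state extended Kalman
filter that bounds the drift of the double-integrated accelerations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import G0, GaitError, GaitEvents, ImuRecording

__all__ = [
    "SpatioTemporalParams",
    "StrideLengthEstimate",
    "PARAM_NAMES",
    "symmetry_index",
    "compute_spatiotemporal",
    "detect_zero_velocity",
    "estimate_stride_length",
]

#: Canonical parameter order (rows 1..24 of the clinical parameter table).
PARAM_NAMES = (
    "stance_phase_time_right_s",
    "stance_phase_time_left_s",
    "swing_phase_time_right_s",
    "swing_phase_time_left_s",
    "stance_phase_percent_right",
    "stance_phase_percent_left",
    "double_support_first_phase_time_right_s",
    "double_support_first_phase_time_left_s",
    "double_support_second_phase_time_right_s",
    "double_support_second_phase_time_left_s",
    "single_support_phase_time_right_s",
    "single_support_phase_time_left_s",
    "double_support_first_phase_percent_right",
    "double_support_first_phase_percent_left",
    "double_support_second_phase_percent_right",
    "double_support_second_phase_percent_left",
    "single_support_phase_percent_right",
    "single_support_phase_percent_left",
    "stride_length_right_m",
    "stride_length_left_m",
    "stance_phase_time_si",
    "swing_phase_time_si",
    "stance_phase_percent_si",
    "cadence_steps_per_min",
)


@dataclass
class SpatioTemporalParams:
    stance_phase_time_right_s: float
    stance_phase_time_left_s: float
    swing_phase_time_right_s: float
    swing_phase_time_left_s: float
    stance_phase_percent_right: float
    stance_phase_percent_left: float
    double_support_first_phase_time_right_s: float
    double_support_first_phase_time_left_s: float
    double_support_second_phase_time_right_s: float
    double_support_second_phase_time_left_s: float
    single_support_phase_time_right_s: float
    single_support_phase_time_left_s: float
    double_support_first_phase_percent_right: float
    double_support_first_phase_percent_left: float
    double_support_second_phase_percent_right: float
    double_support_second_phase_percent_left: float
    single_support_phase_percent_right: float
    single_support_phase_percent_left: float
    stride_length_right_m: float
    stride_length_left_m: float
    stance_phase_time_si: float
    swing_phase_time_si: float
    stance_phase_percent_si: float
    cadence_steps_per_min: float

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


def symmetry_index(right: float, left: float) -> float:
    """Left-right symmetry index |R - L| / (0.5 * (R + L)).

    Dimensionless, 0 for perfect symmetry, bounded above by 2.
    """
    denom = 0.5 * (right + left)
    if denom <= 0:
        raise GaitError("symmetry index needs a positive right + left sum")
    return abs(right - left) / denom


def _per_stride_temporal(own: GaitEvents, opp: GaitEvents) -> pd.DataFrame:
    """Per-stride stance/swing/support times for one foot.

    For the stride [HS, next HS): DS1 = opposite TO - HS (both feet down just
    after own HS), single support = opposite HS - opposite TO, DS2 = own TO -
    opposite HS.  Strides whose opposite events do not interleave as
    HS < oppTO < oppHS < TO < next HS are skipped.
    """
    rows = []
    opp_to = np.sort(opp.to)
    opp_hs = np.sort(opp.hs)
    for i in range(own.n_strides):
        hs, to, nxt = own.hs[i], own.to[i], own.hs[i + 1]
        stride_t = nxt - hs
        if not (0 < to - hs < stride_t):
            continue
        j = np.searchsorted(opp_to, hs, side="right")
        k = np.searchsorted(opp_hs, hs, side="right")
        if j >= opp_to.size or k >= opp_hs.size:
            continue
        oto, ohs = opp_to[j], opp_hs[k]
        if not (hs < oto < ohs < to < nxt):
            continue
        rows.append({
            "stride_time": stride_t,
            "stance_time": to - hs,
            "swing_time": nxt - to,
            "ds1_time": oto - hs,
            "ss_time": ohs - oto,
            "ds2_time": to - ohs,
        })
    return pd.DataFrame(rows)


def compute_spatiotemporal(
    events_right: GaitEvents,
    events_left: GaitEvents,
    stride_lengths_right: np.ndarray | None = None,
    stride_lengths_left: np.ndarray | None = None,
) -> SpatioTemporalParams:
    """Compute the 24 spatial-temporal parameters for one walking bout.

    Parameters
    ----------
    events_right, events_left
        Per-foot gait events covering the same bout.
    stride_lengths_right, stride_lengths_left
        Optional per-stride displacements in meters (e.g. from
        :func:`estimate_stride_length`); their mean is reported.  NaN is
        reported when absent.
    """
    per = {}
    for foot, own, opp in (("right", events_right, events_left),
                           ("left", events_left, events_right)):
        df = _per_stride_temporal(own, opp)
        if len(df) < 2:
            raise GaitError(f"need >= 2 complete strides on the {foot} foot, "
                            f"got {len(df)}")
        per[foot] = df.mean()

    out: dict[str, float] = {}
    for foot in ("right", "left"):
        m = per[foot]
        out[f"stance_phase_time_{foot}_s"] = m["stance_time"]
        out[f"swing_phase_time_{foot}_s"] = m["swing_time"]
        out[f"stance_phase_percent_{foot}"] = 100.0 * m["stance_time"] / m["stride_time"]
        out[f"double_support_first_phase_time_{foot}_s"] = m["ds1_time"]
        out[f"double_support_second_phase_time_{foot}_s"] = m["ds2_time"]
        out[f"single_support_phase_time_{foot}_s"] = m["ss_time"]
        out[f"double_support_first_phase_percent_{foot}"] = 100.0 * m["ds1_time"] / m["stride_time"]
        out[f"double_support_second_phase_percent_{foot}"] = 100.0 * m["ds2_time"] / m["stride_time"]
        out[f"single_support_phase_percent_{foot}"] = 100.0 * m["ss_time"] / m["stride_time"]

    for side, sl in (("right", stride_lengths_right), ("left", stride_lengths_left)):
        out[f"stride_length_{side}_m"] = (
            float(np.mean(sl)) if sl is not None and len(sl) else np.nan)

    out["stance_phase_time_si"] = symmetry_index(
        per["right"]["stance_time"], per["left"]["stance_time"])
    out["swing_phase_time_si"] = symmetry_index(
        per["right"]["swing_time"], per["left"]["swing_time"])
    out["stance_phase_percent_si"] = symmetry_index(
        out["stance_phase_percent_right"], out["stance_phase_percent_left"])
    # Cadence from the mean stride time (two steps per stride); robust to a
    # dropped event compared with counting steps.
    mean_stride = 0.5 * (per["right"]["stride_time"] + per["left"]["stride_time"])
    out["cadence_steps_per_min"] = 120.0 / mean_stride
    return SpatioTemporalParams(**out)


# ---------------------------------------------------------------------------
# Zero-velocity detection and ZUPT-EKF stride length
# ---------------------------------------------------------------------------

def detect_zero_velocity(
    rec: ImuRecording,
    gyro_thresh_dps: float = 15.0,
    acc_thresh_g: float = 0.08,
    window: int = 5,
) -> np.ndarray:
    """Boolean per-sample mask of zero-velocity (foot-flat) samples.

    A sample is flagged when, over a centered ``window``-sample moving
    average, the gyroscope magnitude stays below ``gyro_thresh_dps`` and the
    accelerometer norm deviates from 1 g by less than ``acc_thresh_g``.
    """
    gyro_mag = np.linalg.norm(rec.gyro, axis=1)
    acc_dev = np.abs(np.linalg.norm(rec.acc, axis=1) - 1.0)
    kernel = np.ones(window) / window
    gyro_s = np.convolve(gyro_mag, kernel, mode="same")
    acc_s = np.convolve(acc_dev, kernel, mode="same")
    return (gyro_s < gyro_thresh_dps) & (acc_s < acc_thresh_g)


def _mask_intervals(mask: np.ndarray, min_len: int = 3) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as half-open index intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = list(zip(idx[0::2], idx[1::2]))
    return [(a, b) for a, b in runs if b - a >= min_len]


@dataclass
class StrideLengthEstimate:
    """Per-stride horizontal displacement plus the ZUPT intervals used."""

    stride_lengths_m: np.ndarray
    zupt_intervals_s: list
    position_m: np.ndarray

    def __len__(self) -> int:
        return self.stride_lengths_m.size


def estimate_stride_length(
    rec: ImuRecording,
    mask: np.ndarray | None = None,
    sigma_acc: float = 0.02,
    sigma_gyro: float = 0.2,
    sigma_vel: float = 0.01,
) -> StrideLengthEstimate:
    """Stride length by strap-down integration with a ZUPT error-state EKF.

    The 9-state filter carries position, velocity and attitude errors.
    Attitude is initialised by gravity alignment on the first zero-velocity
    interval (heading is unobservable, so only the horizontal displacement
    magnitude between consecutive zero-velocity midpoints is reported).

    Parameters
    ----------
    rec
        Calibrated recording (acc in g, gyro in deg/s).
    mask
        Zero-velocity mask; computed with default thresholds when omitted.
    sigma_acc
        Accelerometer white-noise density used for process noise, in g.
    sigma_gyro
        Gyroscope white noise, in deg/s.
    sigma_vel
        Standard deviation of the zero-velocity pseudo-measurement, in m/s.
    """
    if mask is None:
        mask = detect_zero_velocity(rec)
    intervals = _mask_intervals(mask)
    if len(intervals) < 2:
        raise GaitError("need >= 2 zero-velocity intervals to measure a stride")

    n = rec.n_samples
    dt = 1.0 / rec.fs
    acc_si = rec.acc * G0
    gyro_rad = np.deg2rad(rec.gyro)
    g_vec = np.array([0.0, 0.0, -G0])

    # Gravity-aligned initial attitude from the first foot-flat interval.
    a0, b0 = intervals[0]
    f0 = acc_si[a0:b0].mean(axis=0)
    R = _gravity_alignment(f0)

    p = np.zeros(3)
    v = np.zeros(3)
    P = np.zeros((9, 9))
    P[6:, 6:] = np.eye(3) * 1e-4
    Q_acc = (sigma_acc * G0) ** 2
    Q_gyro = np.deg2rad(sigma_gyro) ** 2
    H = np.zeros((3, 9))
    H[:, 3:6] = np.eye(3)
    R_meas = np.eye(3) * sigma_vel**2

    positions = np.zeros((n, 3))
    I9 = np.eye(9)
    for k in range(1, n):
        w = 0.5 * (gyro_rad[k - 1] + gyro_rad[k])
        R = R @ Rotation.from_rotvec(w * dt).as_matrix()
        f_nav = R @ acc_si[k]
        a_nav = f_nav + g_vec
        p = p + v * dt + 0.5 * a_nav * dt**2
        v = v + a_nav * dt

        F = I9.copy()
        F[0:3, 3:6] = np.eye(3) * dt
        F[3:6, 6:9] = -_skew(f_nav) * dt
        Qd = np.zeros((9, 9))
        Qd[3:6, 3:6] = np.eye(3) * Q_acc * dt
        Qd[6:9, 6:9] = np.eye(3) * Q_gyro * dt
        P = F @ P @ F.T + Qd

        if mask[k]:
            S = H @ P @ H.T + R_meas
            K = P @ H.T @ np.linalg.solve(S, np.eye(3))
            dx = K @ v  # innovation: measured 0 - predicted v
            p = p - dx[0:3]
            v = v - dx[3:6]
            R = Rotation.from_rotvec(-dx[6:9]).as_matrix() @ R
            P = (I9 - K @ H) @ P
        positions[k] = p

    mids = [int((a + b) // 2) for a, b in intervals]
    disp = np.diff(positions[mids, :2], axis=0)
    lengths = np.linalg.norm(disp, axis=1)
    zupt_s = [(a / rec.fs, b / rec.fs) for a, b in intervals]
    return StrideLengthEstimate(lengths, zupt_s, positions)


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def _gravity_alignment(f_mean: np.ndarray) -> np.ndarray:
    """Rotation matrix aligning the mean stationary specific force with +z."""
    z_body = f_mean / np.linalg.norm(f_mean)
    target = np.array([0.0, 0.0, 1.0])
    axis = np.cross(z_body, target)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return np.eye(3) if z_body[2] > 0 else Rotation.from_euler("x", np.pi).as_matrix()
    angle = np.arctan2(s, z_body @ target)
    return Rotation.from_rotvec(axis / s * angle).as_matrix()
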