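"""Synthetic two-foot insole-IMU recordings with known ground truth.

Real insole recordings from the clinical cohorts this package targets are not
redistributable, so the simulator stands in for them: it produces periodic
per-stride 6-axis waveforms with a controllable event schedule (cadence,
stance/swing split, double-support durations, left/right asymmetry), stride
length, and additive noise, and exports the exact event times and
spatial-temporal parameters that generated the signal.

The waveform model is deliberately simple but *kinematically consistent*:

* the foot rotates about one fixed body axis (mostly sagittal pitch); the
  angular rate is a sum of raised-cosine pulses -- a plantar-flexion dip at
  toe off, the dominant positive swing peak at feet-adjacent, and a dip at
  heel strike -- whose areas cancel over a stride so the foot returns flat;
* forward velocity is a sum of raised-cosine pulses (push-off after heel
  rise, the main swing pulse) plus a short zero-mean jolt at heel strike;
  the per-stride displacement integrates exactly to the profile's stride
  length;
* the accelerometer output is the body-frame specific force implied by that
  trajectory (so gravity appears on +z for a flat foot and the strap-down
  ZUPT-EKF can recover the stride length);
* mid stance is quiet on every channel, which is what makes zero-velocity
  detection possible on real foot-worn sensors.

All pulses are anchored on the sample grid, so with ``noise_sd = 0`` and a
grid-aligned schedule the signal is exactly periodic from the second stride
onward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (ACC_RANGE_G, G0, GYRO_RANGE_DPS, GaitError, GaitEvents,
                   ImuRecording)
from .spatiotemporal import SpatioTemporalParams, compute_spatiotemporal

__all__ = ["GaitProfile", "SyntheticRecording", "simulate_recording",
           "simulate_cohort"]


@dataclass(frozen=True)
class GaitProfile:
    """Subject-level gait description driving the simulator.

    Parameters
    ----------
    cadence : float
        Steps per minute (> 0); the stride period is ``120 / cadence``.
    stance_percent : float
        Stance share of the gait cycle, percent.
    ds1_percent : float
        First double support (own HS to opposite TO) share, percent.
    hr_frac : float
        Heel-rise position as a fraction of stance, in (0, 1).
    fa_frac, tv_frac : float
        Feet-adjacent / tibia-vertical positions as fractions of swing,
        ``0 < fa_frac < tv_frac < 1``.
    stride_length : float
        Meters of forward travel per stride (> 0).
    asymmetry : float
        Left/right multiplicative split of stance percent, first double
        support and stride length: right is scaled by ``1 + asymmetry / 2``
        and left by ``1 - asymmetry / 2``, so the resulting symmetry indices
        equal ``asymmetry`` up to rounding.
    noise_sd : float
        Additive white Gaussian noise per channel, expressed as a fraction
        of that channel's noise-free peak amplitude.
    seed : int
        RNG seed for the noise.
    """

    cadence: float = 115.0
    stance_percent: float = 60.0
    ds1_percent: float = 10.0
    hr_frac: float = 0.5
    fa_frac: float = 0.45
    tv_frac: float = 0.75
    stride_length: float = 1.0
    asymmetry: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.cadence <= 0:
            raise GaitError("cadence must be positive")
        if not 0 < self.stance_percent < 100:
            raise GaitError("stance_percent must be in (0, 100)")
        if not 0 < self.ds1_percent < self.stance_percent:
            raise GaitError("ds1_percent must be in (0, stance_percent)")
        if not 0 < self.fa_frac < self.tv_frac < 1:
            raise GaitError("need 0 < fa_frac < tv_frac < 1")
        if not 0 < self.hr_frac < 1:
            raise GaitError("hr_frac must be in (0, 1)")
        if self.stride_length <= 0:
            raise GaitError("stride_length must be positive")
        if self.asymmetry < 0 or self.noise_sd < 0:
            raise GaitError("asymmetry and noise_sd must be >= 0")
        s_r = self.stance_percent / 100.0 * (1 + self.asymmetry / 2)
        s_l = self.stance_percent / 100.0 * (1 - self.asymmetry / 2)
        d1 = self.ds1_percent / 100.0
        phi = 1.0 + d1 - s_l  # left-foot phase offset within the cycle
        if not 0 < phi < 1:
            raise GaitError("ds1/stance combination leaves no valid left-foot offset")
        for s in (s_r, s_l):
            if not d1 < self.hr_frac * s < phi:
                raise GaitError("heel rise must fall between opposite TO and "
                                "opposite HS (adjust hr_frac/ds1_percent)")
        if s_r >= 1 or s_l <= 0:
            raise GaitError("asymmetry pushes a stance fraction out of (0, 1)")
        # second double support = 2*stance - 100 - ds1 (percent); it must be
        # wide enough to hold a phase window at ordinary sampling rates
        if 2 * self.stance_percent - 100 - self.ds1_percent <= 2.0:
            raise GaitError("stance/ds1 combination leaves a degenerate "
                            "second double support (< 2% of the cycle)")


@dataclass
class SyntheticRecording:
    """A simulated two-foot bout with its exported ground truth."""

    right: ImuRecording
    left: ImuRecording
    truth_right: GaitEvents
    truth_left: GaitEvents
    truth_params: SpatioTemporalParams
    profile: GaitProfile


# -- waveform amplitude constants (per stride period T) ----------------------

_PLANTAR_DEG = 15.0    # toe-off plantar-flexion dip area, degrees
_HSDIP_DEG = 10.0      # heel-strike dip area, degrees
_HEELRISE_DEG = 6.0    # slow plantar flexion between heel rise and toe off
_W_TO = 0.12           # toe-off dip width, fraction of T
_W_SWING = 0.20        # swing-peak width, fraction of T
_W_HS = 0.10           # heel-strike dip width, fraction of T
_PUSHOFF_FRAC = 0.12   # share of stride length delivered before toe off
_JOLT_AMP = 3.0        # heel-strike jolt, m/s^2
_JOLT_W = 0.06         # jolt width, seconds
_CLEARANCE_M = 0.05    # vertical foot clearance during swing, m
_SWAY_M = 0.02         # lateral sway during swing, m
_LEAD_IN = 0.8         # standing still before the first heel strike, s
_TAIL = 0.3            # standing still after the last heel strike, s
#: Fixed body rotation axis (x, y, z weights); y (pitch) dominates.
_GYRO_AXIS = np.array([0.25, 1.0, -0.15])


def _grid(t0: float, w: float, fs: float) -> tuple[int, np.ndarray, float]:
    """Snap a pulse [t0, t0+w) to the sample grid; return (i0, u, w_eff)."""
    i0 = int(round(t0 * fs))
    nw = max(int(round(w * fs)), 2)
    u = np.arange(nw) / nw
    return i0, u, nw / fs


class _PulseTrack:
    """Accumulates pulses into consistent position/velocity/acceleration."""

    def __init__(self, n: int, fs: float):
        self.n, self.fs = n, fs
        self.pos = np.zeros(n)
        self.vel = np.zeros(n)
        self.acc = np.zeros(n)
        self._step = np.zeros(n)

    def _clip(self, i0: int, m: int) -> tuple[int, int, int]:
        a = max(i0, 0)
        b = min(i0 + m, self.n)
        return a, b, a - i0

    def add_rc(self, t0: float, w: float, area: float) -> None:
        """Raised-cosine velocity pulse integrating to ``area``."""
        i0, u, w = _grid(t0, w, self.fs)
        a, b, off = self._clip(i0, u.size)
        if a >= b:
            return
        u = u[off:off + (b - a)]
        c = 2.0 * area / w
        self.vel[a:b] += 0.5 * c * (1 - np.cos(2 * np.pi * u))
        self.acc[a:b] += c * np.pi / w * np.sin(2 * np.pi * u)
        self.pos[a:b] += 0.5 * c * w * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
        end = i0 + int(round(w * self.fs))
        if end < self.n:
            self._step[end] += area

    def add_jolt(self, center: float, w: float, amp: float) -> float:
        """Zero-net-velocity sine acceleration pulse; returns its small net
        displacement so the caller can rebalance the stride total."""
        i0, u, w = _grid(center - w / 2, w, self.fs)
        a, b, off = self._clip(i0, u.size)
        net = amp * w**2 / (2 * np.pi)
        if a >= b:
            return net
        u = u[off:off + (b - a)]
        self.acc[a:b] += amp * np.sin(2 * np.pi * u)
        self.vel[a:b] += amp * w / (2 * np.pi) * (1 - np.cos(2 * np.pi * u))
        self.pos[a:b] += amp * w / (2 * np.pi) * (
            u * w - w * np.sin(2 * np.pi * u) / (2 * np.pi))
        end = i0 + int(round(w * self.fs))
        if end < self.n:
            self._step[end] += net
        return net

    def add_bump(self, t0: float, w: float, height: float) -> None:
        """Raised-cosine *position* bump returning to zero (clearance/sway)."""
        i0, u, w = _grid(t0, w, self.fs)
        a, b, off = self._clip(i0, u.size)
        if a >= b:
            return
        u = u[off:off + (b - a)]
        self.pos[a:b] += 0.5 * height * (1 - np.cos(2 * np.pi * u))
        self.vel[a:b] += height * np.pi / w * np.sin(2 * np.pi * u)
        self.acc[a:b] += 2 * height * np.pi**2 / w**2 * np.cos(2 * np.pi * u)

    def finish(self) -> None:
        self.pos += np.cumsum(self._step)


def _foot_schedule(profile: GaitProfile, foot: str, n_strides: int,
                   t_start: float) -> GaitEvents:
    """Exact event times for one foot over ``n_strides`` strides."""
    T = 120.0 / profile.cadence
    a = profile.asymmetry
    s = profile.stance_percent / 100.0 * (1 + a / 2 if foot == "right" else 1 - a / 2)
    s_l = profile.stance_percent / 100.0 * (1 - a / 2)
    phi = 1.0 + profile.ds1_percent / 100.0 - s_l
    offset = 0.0 if foot == "right" else phi
    k = np.arange(n_strides + 1)
    hs = t_start + (k + offset) * T
    to = hs[:-1] + s * T
    hr = hs[:-1] + profile.hr_frac * s * T
    fa = to + profile.fa_frac * (1 - s) * T
    tv = to + profile.tv_frac * (1 - s) * T
    return GaitEvents(foot, hs, to, hr, fa, tv)


def _render_foot(profile: GaitProfile, events: GaitEvents, n: int, fs: float,
                 rng: np.random.Generator) -> ImuRecording:
    """Render the 6-axis signal for one foot from its event schedule."""
    T = 120.0 / profile.cadence
    a = profile.asymmetry
    side = +1.0 if events.foot == "right" else -1.0
    length = profile.stride_length * (1 + side * a / 2)

    ang = _PulseTrack(n, fs)     # pos=angle [deg], vel=rate [deg/s]
    fwd = _PulseTrack(n, fs)     # forward (x) kinematics [m, m/s, m/s^2]
    vert = _PulseTrack(n, fs)
    lat = _PulseTrack(n, fs)

    K = events.n_strides
    for i in range(K):
        hs, to, hr, nxt = events.hs[i], events.to[i], events.hr[i], events.hs[i + 1]
        fa = events.fa[i]
        swing = nxt - to
        # angular-rate pulses; areas cancel over the stride.  The slow
        # heel-rise pulse keeps the gyro active throughout push-off so the
        # foot is only ever gyro-quiet during genuine foot-flat.
        ang.add_rc(hr, to - hr, -_HEELRISE_DEG)
        ang.add_rc(to - _W_TO * T / 2, _W_TO * T, -_PLANTAR_DEG)
        ang.add_rc(fa - _W_SWING * T / 2, _W_SWING * T,
                   _PLANTAR_DEG + _HSDIP_DEG + _HEELRISE_DEG)
        ang.add_rc(nxt - _W_HS * T / 2, _W_HS * T, -_HSDIP_DEG)
        # forward velocity: push-off + swing + heel-strike jolt
        jolt_net = _JOLT_AMP * _JOLT_W**2 / (2 * np.pi)
        fwd.add_rc(hr, to - hr, _PUSHOFF_FRAC * length)
        fwd.add_rc(to, swing, (1 - _PUSHOFF_FRAC) * length - jolt_net)
        fwd.add_jolt(nxt, _JOLT_W, _JOLT_AMP)
        # clearance and sway during swing
        vert.add_bump(to, swing, _CLEARANCE_M)
        lat.add_bump(to, swing, side * _SWAY_M)
        lat.add_jolt(nxt, _JOLT_W, side * _JOLT_AMP / 2)
    for tr in (ang, fwd, vert, lat):
        tr.finish()

    axis = _GYRO_AXIS * np.array([side, 1.0, side])
    gyro = np.outer(ang.vel, axis)                       # deg/s
    rotvec = np.outer(np.deg2rad(ang.pos), axis)
    rot = Rotation.from_rotvec(rotvec)
    f_world = np.column_stack([fwd.acc, lat.acc, vert.acc + G0])
    acc = rot.inv().apply(f_world) / G0                  # specific force, g

    if profile.noise_sd > 0:
        for arr in (acc, gyro):
            peaks = np.abs(arr).max(axis=0)
            arr += rng.normal(size=arr.shape) * (profile.noise_sd * peaks)
    np.clip(acc, -ACC_RANGE_G, ACC_RANGE_G, out=acc)
    np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS, out=gyro)
    t = np.arange(n) / fs
    return ImuRecording(fs=fs, t=t, acc=acc, gyro=gyro, foot=events.foot)


def simulate_recording(profile: GaitProfile, duration: float = 30.0,
                       fs: float = 100.0) -> SyntheticRecording:
    """Simulate one two-foot walking bout.

    Parameters
    ----------
    profile
        Gait description; see :class:`GaitProfile`.
    duration
        Recording length in seconds.  Must accommodate at least 3 full gait
        cycles plus short standing lead-in/out periods.
    fs
        Sampling frequency in Hz.

    Returns
    -------
    SyntheticRecording
        Per-foot recordings, exact ground-truth events for both feet, and
        the spatial-temporal parameters recomputed from those events.
    """
    profile.validate()
    if fs <= 0:
        raise GaitError("fs must be positive")
    T = 120.0 / profile.cadence
    s_l = profile.stance_percent / 100.0 * (1 - profile.asymmetry / 2)
    phi = 1.0 + profile.ds1_percent / 100.0 - s_l
    n_strides = int(np.floor((duration - _LEAD_IN - _TAIL) / T - phi))
    if n_strides < 3:
        raise GaitError(
            f"duration {duration} s allows only {max(n_strides, 0)} gait "
            "cycles; at least 3 are required")
    n = int(round(duration * fs))
    rng = np.random.default_rng(profile.seed)
    ev_r = _foot_schedule(profile, "right", n_strides, _LEAD_IN)
    ev_l = _foot_schedule(profile, "left", n_strides, _LEAD_IN)
    rec_r = _render_foot(profile, ev_r, n, fs, rng)
    rec_l = _render_foot(profile, ev_l, n, fs, rng)
    a = profile.asymmetry
    sl_r = np.full(n_strides, profile.stride_length * (1 + a / 2))
    sl_l = np.full(n_strides, profile.stride_length * (1 - a / 2))
    params = compute_spatiotemporal(ev_r, ev_l, sl_r, sl_l)
    return SyntheticRecording(rec_r, rec_l, ev_r, ev_l, params, profile)


#: Profile fields jittered multiplicatively (log-normally) across subjects,
#: with a per-field scale on the log-sd.  The schedule percentages get half
#: the nominal jitter: double-support durations are small differences of
#: stance and ds1, so noise on those fields is amplified ~15x and full
#: jitter would routinely produce degenerate pre-swing windows.
_JITTER_FIELDS = {"cadence": 1.0, "stance_percent": 0.5, "ds1_percent": 0.5,
                  "stride_length": 1.0, "asymmetry": 1.0}
#: Floor applied to asymmetry before jittering so control subjects still vary.
_ASYM_FLOOR = 0.005


def simulate_cohort(profile_a: GaitProfile, profile_b: GaitProfile,
                    n_per_group: int, duration: float = 30.0, fs: float = 100.0,
                    seed: int = 0, jitter_sd: float = 0.02) -> list:
    """Simulate a labelled two-group cohort.

    Each subject's profile is the group profile with independent log-normal
    multiplicative jitter (``sd = jitter_sd`` on the log scale) on cadence,
    stance percent, first double support, stride length and asymmetry
    (asymmetry is floored at a small positive value first so that nominally
    symmetric subjects still vary).  Group A carries label 1 (patients),
    group B label 0.

    Returns
    -------
    list of (subject_id, label, SyntheticRecording)
    """
    if n_per_group < 2:
        raise GaitError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    out = []
    for label, base in ((1, profile_a), (0, profile_b)):
        for i in range(n_per_group):
            sub_seed = int(rng.integers(2**31))
            z = rng.normal(0.0, 1.0, len(_JITTER_FIELDS))
            updates = {}
            for (name, scale), zi in zip(_JITTER_FIELDS.items(), z):
                value = getattr(base, name)
                if name == "asymmetry":
                    value = max(value, _ASYM_FLOOR)
                updates[name] = value * np.exp(scale * jitter_sd * zi)
            prof = replace(base, seed=sub_seed, **updates)
            prof.validate()
            sid = f"{'pat' if label else 'ctl'}{i + 1:03d}"
            out.append((sid, label, simulate_recording(prof, duration, fs)))
    return out
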