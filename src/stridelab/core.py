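"""Core data containers shared across the gait-analysis pipeline.

Conventions used throughout the package:

* time is in seconds, sample index 0-based, intervals half-open ``[start, end)``;
* accelerometer channels are in g (so a foot flat at rest reads ``acc_z = +1``);
* gyroscope channels are in deg/s;
* within one foot a *stride* runs from one heel strike (HS) to the next HS of
  the same foot, so a recording with ``m`` heel strikes contains ``m - 1``
  strides; the intermediate events (HR, TO, FA, TV) are stored once per stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

G0 = 9.80665
"""Standard gravity in m/s^2, used to convert between g and SI units."""

ACC_RANGE_G = 8.0
"""Accelerometer full-scale range (+-8 g)."""

GYRO_RANGE_DPS = 1000.0
"""Gyroscope full-scale range (+-1000 deg/s)."""

#: Canonical ordering of the seven gait phases within one stride.
PHASE_NAMES = (
    "loading_response",
    "mid_stance",
    "terminal_stance",
    "pre_swing",
    "initial_swing",
    "mid_swing",
    "terminal_swing",
)

#: Canonical ordering of the six inertial channels.
CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

#: The five gait events detected per foot.
EVENT_NAMES = ("HS", "TO", "HR", "FA", "TV")


class GaitError(ValueError):
    """Base error for gait-analysis failures."""


class NoGaitError(GaitError):
    """Raised when no periodic walking pattern can be found in a recording."""


@dataclass
class ImuRecording:
    """One foot's 6-axis inertial time series.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz.
    t : ndarray, shape (n,)
        Sample times in seconds, uniformly spaced at ``1/fs``.
    acc : ndarray, shape (n, 3)
        Accelerometer x/y/z in g. x is the walking direction, z is vertical
        (gravity reads +1 g on a flat, stationary foot).
    gyro : ndarray, shape (n, 3)
        Gyroscope x/y/z in deg/s; y is the sagittal (pitch) axis.
    foot : {"right", "left"}
    """

    fs: float
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    foot: str = "right"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.foot not in ("right", "left"):
            raise ValueError(f"foot must be 'right' or 'left', got {self.foot!r}")
        if self.acc.shape != (self.t.size, 3) or self.gyro.shape != (self.t.size, 3):
            raise ValueError("acc and gyro must have shape (n_samples, 3)")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-6:
                raise ValueError("sample times are not uniform at 1/fs")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return self.t.size / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one named channel (see :data:`CHANNEL_NAMES`)."""
        i = CHANNEL_NAMES.index(name)
        return self.acc[:, i] if i < 3 else self.gyro[:, i - 3]

    def channels(self) -> np.ndarray:
        """All six channels as an (n, 6) array in canonical order."""
        return np.hstack([self.acc, self.gyro])


@dataclass
class GaitEvents:
    """Per-foot gait-event time stamps in seconds.

    ``hs`` has one entry per heel strike (``n_strides + 1``); ``to``, ``hr``,
    ``fa`` and ``tv`` have one entry per stride, i.e. the event belonging to
    the stride that starts at ``hs[i]``.
    """

    foot: str
    hs: np.ndarray
    to: np.ndarray
    hr: np.ndarray = field(default=None)  # type: ignore[assignment]
    fa: np.ndarray = field(default=None)  # type: ignore[assignment]
    tv: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.hs = np.asarray(self.hs, dtype=float)
        self.to = np.asarray(self.to, dtype=float)
        n = self.n_strides
        for name in ("hr", "fa", "tv"):
            v = getattr(self, name)
            v = np.full(n, np.nan) if v is None else np.asarray(v, dtype=float)
            setattr(self, name, v)
            if v.size != n:
                raise ValueError(f"{name} must have one entry per stride ({n})")
        if self.to.size != n:
            raise ValueError("to must have one entry per stride")

    @property
    def n_strides(self) -> int:
        return max(self.hs.size - 1, 0)

    def stride_ok(self, i: int) -> bool:
        """True when stride ``i`` satisfies HS < HR < TO < FA < TV < next HS."""
        seq = (self.hs[i], self.hr[i], self.to[i], self.fa[i], self.tv[i], self.hs[i + 1])
        return bool(np.all(np.isfinite(seq)) and np.all(np.diff(seq) > 0))

    def validate(self) -> None:
        """Raise :class:`GaitError` unless every stride is well ordered."""
        for i in range(self.n_strides):
            if not self.stride_ok(i):
                raise GaitError(f"event ordering violated in stride {i} ({self.foot})")

    def shifted(self, dt: float) -> "GaitEvents":
        return GaitEvents(self.foot, self.hs + dt, self.to + dt,
                          self.hr + dt, self.fa + dt, self.tv + dt)


@dataclass
class PhaseWindows:
    """Seven half-open phase intervals per stride.

    ``windows[i]`` maps phase name -> ``(start, end)`` in seconds for the
    ``i``-th accepted stride; the seven intervals are contiguous and tile
    ``[HS, next HS)``. ``stride_index`` records which strides of the source
    events were accepted.
    """

    foot: str
    windows: list
    stride_index: list

    def __len__(self) -> int:
        return len(self.windows)

    def durations(self, i: int) -> np.ndarray:
        return np.array([self.windows[i][p][1] - self.windows[i][p][0]
                         for p in PHASE_NAMES])
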