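"""Descriptive statistical gait features with canonical numbering.

Ten descriptive statistics are computed for each of the six inertial
channels inside each of the seven gait phases, for both feet:
``2 x 7 x 6 x 10 = 840`` features.  Every feature has a canonical integer
index in 1..840: the right foot occupies 1..420 and the left foot 421..840;
within a foot, phases are blocks of 60 in stride order, channels blocks of
10 in (AccX, AccY, AccZ, GyroX, GyroY, GyroZ) order, and the statistics run
(Max, Min, SD, AbSum, RMS, Kurtosis, Skewness, MMgr, DMM, Mdif)::

    index = 420 * [foot == left] + 60 * phase + 10 * channel + stat + 1

Statistics are computed per stride on the raw (un-resampled) samples inside
the phase window and averaged across strides.  Conventions: SD is the
sample standard deviation (ddof=1); kurtosis is the Pearson moment kurtosis
(normal = 3, not excess); skewness is the Fisher-Pearson moment coefficient
g1 (biased); MMgr is the signed slope (max - min) / (t_min - t_max) in
units/s, 0 for a constant segment; DMM = max - min; Mdif is the maximum
absolute difference of successive samples.  Ties for the max/min location
are broken by the earliest occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CHANNEL_NAMES, GaitError, ImuRecording, PHASE_NAMES, PhaseWindows

__all__ = ["FeatureIndexKey", "STAT_NAMES", "feature_index", "feature_key",
           "feature_dictionary", "compute_stat", "compute_features"]

FOOT_ORDER = ("right", "left")
#: Canonical statistic order within a channel block.
STAT_NAMES = ("Max", "Min", "SD", "AbSum", "RMS", "Kurtosis", "Skewness",
              "MMgr", "DMM", "Mdif")

N_FEATURES = len(FOOT_ORDER) * len(PHASE_NAMES) * len(CHANNEL_NAMES) * len(STAT_NAMES)


@dataclass(frozen=True)
class FeatureIndexKey:
    """(foot, phase, signal, statistic) address of one feature."""

    foot: str
    phase: str
    signal: str
    stat: str

    def __post_init__(self) -> None:
        if self.foot not in FOOT_ORDER:
            raise KeyError(f"unknown foot {self.foot!r}")
        if self.phase not in PHASE_NAMES:
            raise KeyError(f"unknown phase {self.phase!r}")
        if self.signal not in CHANNEL_NAMES:
            raise KeyError(f"unknown signal {self.signal!r}")
        if self.stat not in STAT_NAMES:
            raise KeyError(f"unknown statistic {self.stat!r}")


def feature_index(key: FeatureIndexKey) -> int:
    """Canonical 1-based index of a feature key (bijective, 1..840)."""
    return (420 * FOOT_ORDER.index(key.foot)
            + 60 * PHASE_NAMES.index(key.phase)
            + 10 * CHANNEL_NAMES.index(key.signal)
            + STAT_NAMES.index(key.stat) + 1)


def feature_key(index: int) -> FeatureIndexKey:
    """Inverse of :func:`feature_index`."""
    if not 1 <= index <= N_FEATURES:
        raise KeyError(f"feature index must be in 1..{N_FEATURES}, got {index}")
    i = index - 1
    return FeatureIndexKey(
        foot=FOOT_ORDER[i // 420],
        phase=PHASE_NAMES[(i % 420) // 60],
        signal=CHANNEL_NAMES[(i % 60) // 10],
        stat=STAT_NAMES[i % 10],
    )


def feature_dictionary() -> pd.DataFrame:
    """The full index -> (foot, phase, signal, stat) dictionary as a table."""
    rows = []
    for i in range(1, N_FEATURES + 1):
        k = feature_key(i)
        rows.append({"index": i, "foot": k.foot, "phase": k.phase,
                     "signal": k.signal, "stat": k.stat})
    return pd.DataFrame(rows).set_index("index")


def compute_stat(stat: str, x: np.ndarray, fs: float = 100.0) -> float:
    """One descriptive statistic of a sample vector (see module docstring).

    ``fs`` is needed only for MMgr, whose slope is per second.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise GaitError("need at least 2 samples")
    if stat == "Max":
        return float(np.max(x))
    if stat == "Min":
        return float(np.min(x))
    if stat == "SD":
        return float(np.std(x, ddof=1))
    if stat == "AbSum":
        return float(np.sum(np.abs(x)))
    if stat == "RMS":
        return float(np.sqrt(np.mean(x**2)))
    if stat == "Kurtosis":
        if np.ptp(x) == 0:
            return 0.0
        return float(sps.kurtosis(x, fisher=False, bias=True))
    if stat == "Skewness":
        if np.ptp(x) == 0:
            return 0.0
        return float(sps.skew(x, bias=True))
    if stat == "MMgr":
        imax = int(np.argmax(x))
        imin = int(np.argmin(x))
        if imax == imin:
            return 0.0
        return float((x[imax] - x[imin]) / ((imin - imax) / fs))
    if stat == "DMM":
        return float(np.ptp(x))
    if stat == "Mdif":
        return float(np.max(np.abs(np.diff(x))))
    raise KeyError(f"unknown statistic {stat!r}")


def compute_features(rec_right: ImuRecording, rec_left: ImuRecording,
                     phases_right: PhaseWindows,
                     phases_left: PhaseWindows) -> pd.Series:
    """The 840-entry descriptive feature vector for one subject.

    For every (foot, phase, signal) triple, each statistic is computed per
    stride on the raw samples inside the phase window and then averaged over
    strides.  Phase windows holding fewer than 2 samples are skipped for that
    stride; a feature with no valid stride at all is NaN (the vector is then
    incomplete and callers should treat extraction as failed).

    Returns
    -------
    pandas.Series
        Indexed ``p0001``..``p0840`` in canonical order.
    """
    values = np.full(N_FEATURES, np.nan)
    for foot, rec, phases in (("right", rec_right, phases_right),
                              ("left", rec_left, phases_left)):
        if len(phases) < 2:
            raise GaitError(f"need >= 2 complete strides on the {foot} foot")
        base_foot = 420 * FOOT_ORDER.index(foot)
        for ip, phase in enumerate(PHASE_NAMES):
            segments = []
            for w in phases.windows:
                a, b = w[phase]
                i0 = int(np.ceil(a * rec.fs - 1e-9))
                i1 = int(np.ceil(b * rec.fs - 1e-9))
                i0, i1 = max(i0, 0), min(i1, rec.n_samples)
                if i1 - i0 >= 2:
                    segments.append(slice(i0, i1))
            if not segments:
                continue
            for ic, channel in enumerate(CHANNEL_NAMES):
                sig = rec.channel(channel)
                per_stride = np.array(
                    [[compute_stat(s, sig[seg], rec.fs) for s in STAT_NAMES]
                     for seg in segments])
            # mean over strides, per statistic
                base = base_foot + 60 * ip + 10 * ic
                values[base:base + 10] = per_stride.mean(axis=0)
    return pd.Series(values, index=[f"p{i:04d}" for i in range(1, N_FEATURES + 1)])
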