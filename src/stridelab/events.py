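"""Gait-event detection and seven-phase stride segmentation.

Detection works on the sagittal-plane gyroscope of a foot-worn sensor, the
standard signal for this task: each swing produces one dominant positive
pitch peak (feet adjacent), flanked by a plantar-flexion minimum at toe off
before it and a smaller minimum at heel strike after it.  Heel rise is taken
from the onset of the push-off transient on the forward accelerometer, and
tibia vertical from the downward zero crossing of the sagittal gyro after
the swing peak.

The first and last cycles of a bout are always discarded: accelerations at
gait initiation and termination are not representative of steady walking.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

from .core import (GaitError, GaitEvents, ImuRecording, NoGaitError,
                   PhaseWindows, PHASE_NAMES)

__all__ = ["detect_events", "assign_phases", "normalize_stride",
           "detected_cadence"]

log = logging.getLogger(__name__)

#: Valid cadence range, steps/min; outside it the bout is rejected.
CADENCE_RANGE = (40.0, 160.0)


def _refine_extremum(y: np.ndarray, i: int, sign: float, fs: float) -> float:
    """Sub-sample extremum time via parabolic interpolation around sample i."""
    if 0 < i < y.size - 1:
        a, b, c = sign * y[i - 1], sign * y[i], sign * y[i + 1]
        denom = a - 2 * b + c
        if denom < 0:
            return (i + 0.5 * (a - c) / denom) / fs
    return i / fs


def _dominant_stride_period(gyro_sag: np.ndarray, fs: float) -> float:
    """Stride period from the autocorrelation of the band-passed sagittal gyro.

    Raises :class:`NoGaitError` when no periodicity in the walking cadence
    band (40-160 steps/min) is found.
    """
    sos = butter(2, [0.3, 3.0], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, gyro_sag)
    if np.std(x) < 1e-6:
        raise NoGaitError("signal has no periodic component")
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    # stride frequency = cadence / 120 (two steps per stride)
    lo = int(fs * 120.0 / CADENCE_RANGE[1])
    hi = min(int(fs * 120.0 / CADENCE_RANGE[0]), ac.size - 1)
    if hi <= lo:
        raise NoGaitError("recording too short for cadence estimation")
    lag = lo + int(np.argmax(ac[lo:hi]))
    if ac[lag] <= 0.1 * ac[0]:
        raise NoGaitError("no dominant cadence in the 40-160 steps/min band")
    return lag / fs


def detected_cadence(rec: ImuRecording) -> float:
    """Cadence in steps/min from the dominant stride period."""
    return 120.0 / _dominant_stride_period(rec.channel("gyro_y"), rec.fs)


def detect_events(rec: ImuRecording) -> GaitEvents:
    """Detect HS, TO, HR, FA and TV for one foot.

    Returns a :class:`~stridelab.core.GaitEvents` covering the interior
    strides only (first and last cycles discarded).  Raises
    :class:`~stridelab.core.NoGaitError` when no periodic gait in the
    40-160 steps/min cadence band is present.
    """
    fs = rec.fs
    gyro = rec.channel("gyro_y")
    T = _dominant_stride_period(gyro, fs)

    # mid-swing (feet adjacent): dominant positive sagittal-gyro peaks
    height = 0.4 * np.percentile(gyro, 99.5)
    peaks, _ = find_peaks(gyro, height=height, distance=int(0.6 * T * fs))
    if peaks.size < 4:
        raise NoGaitError("fewer than 4 swing peaks found")

    hs_list, to_list, fa_list, tv_list = [], [], [], []
    for j, p in enumerate(peaks):
        # TO: gyro minimum in the window before the swing peak
        a = max(p - int(0.45 * T * fs), 0)
        if a >= p:
            continue
        i_to = a + int(np.argmin(gyro[a:p]))
        # HS: gyro minimum after the swing peak
        b = min(p + int(0.45 * T * fs), gyro.size)
        if p + 1 >= b:
            continue
        i_hs = p + 1 + int(np.argmin(gyro[p + 1:b]))
        to_list.append(_refine_extremum(gyro, i_to, -1.0, fs))
        hs_list.append(_refine_extremum(gyro, i_hs, -1.0, fs))
        fa_list.append(_refine_extremum(gyro, p, +1.0, fs))
        # TV: first downward zero crossing after the swing peak
        seg = gyro[p:i_hs]
        neg = np.flatnonzero(seg <= 0)
        if neg.size and neg[0] > 0:
            i = p + neg[0]
            y0, y1 = gyro[i - 1], gyro[i]
            frac = y0 / (y0 - y1) if y0 != y1 else 0.5
            tv_list.append((i - 1 + frac) / fs)
        else:
            tv_list.append((fa_list[-1] + hs_list[-1]) / 2)

    # assemble strides: stride i runs from HS after peak i to HS after peak
    # i+1; TO/FA/TV of the stride come from peak i+1's swing.
    hs = np.array(hs_list)
    if hs.size < 3 or np.any(np.diff(hs) <= 0):
        raise NoGaitError("could not assemble a consistent stride sequence")
    n_strides = hs.size - 1
    to = np.array(to_list[1:])
    fa = np.array(fa_list[1:])
    tv = np.array(tv_list[1:])

    hr = np.full(n_strides, np.nan)
    acc_x = rec.channel("acc_x")
    sos_hp = butter(2, 1.5, btype="highpass", fs=fs, output="sos")
    hp = sosfiltfilt(sos_hp, acc_x)
    for i in range(n_strides):
        t_hs, t_to = hs[i], to[i]
        stance = t_to - t_hs
        if stance <= 0:
            continue
        # quiet mid-stance reference level for the onset test
        q0, q1 = int((t_hs + 0.25 * stance) * fs), int((t_hs + 0.40 * stance) * fs)
        quiet = np.abs(hp[q0:q1])
        mad = np.median(np.abs(quiet - np.median(quiet))) if quiet.size else 0.0
        thresh = max(6 * mad, 0.02)
        w0 = int((t_hs + 0.40 * stance) * fs)
        w1 = int(t_to * fs)
        idx = np.flatnonzero(np.abs(hp[w0:w1]) > thresh)
        hr[i] = (w0 + idx[0]) / fs if idx.size else t_hs + 0.5 * stance

    # discard boundary strides
    events = GaitEvents(rec.foot, hs[1:-1], to[1:-1], hr[1:-1], fa[1:-1],
                        tv[1:-1])
    cad = 120.0 / np.mean(np.diff(events.hs)) if events.n_strides else 0.0
    if not CADENCE_RANGE[0] <= cad <= CADENCE_RANGE[1]:
        raise NoGaitError(f"detected cadence {cad:.1f} steps/min outside "
                          f"{CADENCE_RANGE}")
    return events


def assign_phases(self_events: GaitEvents,
                  opposite_events: GaitEvents) -> PhaseWindows:
    """Partition each stride into the seven gait phases.

    Phase boundaries (half-open intervals): loading response = [HS, opposite
    TO), mid stance = [opposite TO, HR), terminal stance = [HR, opposite HS),
    pre swing = [opposite HS, TO), initial swing = [TO, FA), mid swing =
    [FA, TV), terminal swing = [TV, next HS).  Strides whose events violate
    this ordering are rejected with a warning and omitted from the result.
    """
    windows, kept = [], []
    opp_to = np.sort(opposite_events.to)
    opp_hs = np.sort(opposite_events.hs)
    for i in range(self_events.n_strides):
        hs, nxt = self_events.hs[i], self_events.hs[i + 1]
        to, hr = self_events.to[i], self_events.hr[i]
        fa, tv = self_events.fa[i], self_events.tv[i]
        j = np.searchsorted(opp_to, hs, side="right")
        k = np.searchsorted(opp_hs, hs, side="right")
        if j >= opp_to.size or k >= opp_hs.size:
            log.warning("stride %d: no opposite-foot events; rejected", i)
            continue
        oto, ohs = opp_to[j], opp_hs[k]
        bounds = (hs, oto, hr, ohs, to, fa, tv, nxt)
        if not (np.all(np.isfinite(bounds)) and np.all(np.diff(bounds) > 0)):
            log.warning("stride %d: event ordering violated; rejected", i)
            continue
        windows.append(dict(zip(PHASE_NAMES, zip(bounds[:-1], bounds[1:]))))
        kept.append(i)
    return PhaseWindows(self_events.foot, windows, kept)


def normalize_stride(segment: np.ndarray, n_out: int = 100) -> np.ndarray:
    """Resample one stride's samples onto ``n_out`` points by cubic spline.

    The output grid spans the segment exactly, so the endpoints are
    preserved; a cubic spline is exact on polynomials of degree <= 3.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 4:
        raise GaitError("stride segment must have at least 4 samples")
    x = np.arange(segment.size, dtype=float)
    spline = CubicSpline(x, segment)
    return spline(np.linspace(0.0, segment.size - 1, n_out))
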