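"""Canonical feature numbering and descriptive statistics."""

import math

import numpy as np
import pytest

import stridelab as sl
from stridelab.core import GaitError
from stridelab.features import (N_FEATURES, STAT_NAMES, FeatureIndexKey,
                                feature_dictionary, feature_index, feature_key)

# ---------------------------------------------------------------------------
# independent brute-force oracle for the ten statistics (pure python loops)
# ---------------------------------------------------------------------------

def brute_force_stats(x, fs):
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    imax = max(range(n), key=lambda i: (x[i], -i))
    imin = min(range(n), key=lambda i: (x[i], i))
    # earliest occurrence on ties
    imax = next(i for i in range(n) if x[i] == x[imax])
    imin = next(i for i in range(n) if x[i] == x[imin])
    out = {
        "Max": max(x),
        "Min": min(x),
        "SD": math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1)),
        "AbSum": sum(abs(v) for v in x),
        "RMS": math.sqrt(sum(v * v for v in x) / n),
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "MMgr": ((x[imax] - x[imin]) / ((imin - imax) / fs)
                 if imax != imin else 0.0),
        "DMM": max(x) - min(x),
        "Mdif": max(abs(x[i + 1] - x[i]) for i in range(n - 1)),
    }
    return out


class TestCanonicalIndex:
    @pytest.mark.parametrize("key,expected", [
        (FeatureIndexKey("right", "loading_response", "acc_x", "Max"), 1),
        (FeatureIndexKey("right", "initial_swing", "acc_x", "Skewness"), 247),
        (FeatureIndexKey("right", "mid_stance", "gyro_z", "AbSum"), 114),
        (FeatureIndexKey("left", "mid_stance", "gyro_y", "AbSum"), 524),
        (FeatureIndexKey("left", "loading_response", "acc_x", "Mdif"), 430),
        (FeatureIndexKey("left", "terminal_swing", "gyro_z", "Mdif"), 840),
    ])
    def test_named_parameters(self, key, expected):
        assert feature_index(key) == expected

    def test_bijection_round_trip(self):
        seen = set()
        for i in range(1, N_FEATURES + 1):
            k = feature_key(i)
            assert feature_index(k) == i
            seen.add(k)
        assert len(seen) == N_FEATURES

    def test_invalid_members_rejected(self):
        with pytest.raises(KeyError):
            FeatureIndexKey("center", "mid_stance", "acc_x", "Max")
        with pytest.raises(KeyError):
            feature_key(841)
        with pytest.raises(KeyError):
            feature_key(0)

    def test_dictionary_table(self):
        d = feature_dictionary()
        assert len(d) == 840
        assert tuple(d.loc[524]) == ("left", "mid_stance", "gyro_y", "AbSum")


class TestComputeStat:
    @pytest.mark.parametrize("stat,x,expected", [
        ("Mdif", [1, 4, 2], 3.0),
        ("DMM", [1, 5, 3], 4.0),
        ("AbSum", [-1, 2, -3], 6.0),
        ("RMS", [3, 4], 3.5355339059),
        ("Max", [1, 5, 3], 5.0),
        ("Min", [1, 5, 3], 1.0),
        ("Skewness", [1, 2, 3, 4, 5], 0.0),
    ])
    def test_examples(self, stat, x, expected):
        assert sl.compute_stat(stat, np.array(x, float)) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.normal(size=rng.integers(5, 60))
            ref = brute_force_stats(list(x), 100.0)
            for stat in STAT_NAMES:
                got = sl.compute_stat(stat, x, fs=100.0)
                assert got == pytest.approx(ref[stat], abs=1e-10), stat

    def test_mmgr_signed_slope_and_constant(self):
        # max at t=0, min at t=0.02 -> slope (5-1)/(0.02-0) = +200 units/s
        assert sl.compute_stat("MMgr", np.array([5.0, 3.0, 1.0]), fs=100.0) \
            == pytest.approx(200.0)
        assert sl.compute_stat("MMgr", np.ones(5)) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(GaitError):
            sl.compute_stat("Max", np.array([1.0]))


class TestComputeFeatures:
    def test_vector_complete_with_840_entries(self, analyzed, clean_sim):
        f = analyzed["features"]
        assert f.size == 840
        assert not f.isna().any()
        assert list(f.index[:2]) == ["p0001", "p0002"]

    def test_feet_swap_swaps_blocks(self, analyzed, clean_sim):
        ph = analyzed["phases"]
        swapped = sl.compute_features(clean_sim.left, clean_sim.right,
                                      ph["left"], ph["right"])
        f = analyzed["features"].to_numpy()
        s = swapped.to_numpy()
        assert np.allclose(s[:420], f[420:])
        assert np.allclose(s[420:], f[:420])

    def test_scaling_a_channel(self, analyzed, clean_sim):
        """Scaling gyro_y by c scales its linear stats by c and leaves
        kurtosis/skewness unchanged."""
        c = 2.5
        rec = clean_sim.right
        gyro = rec.gyro.copy()
        gyro[:, 1] *= c
        scaled_rec = sl.ImuRecording(rec.fs, rec.t, rec.acc, gyro, rec.foot)
        ph = analyzed["phases"]
        base = analyzed["features"]
        scaled = sl.compute_features(scaled_rec, clean_sim.left,
                                     ph["right"], ph["left"])
        for phase in ("mid_swing", "initial_swing"):
            for stat in STAT_NAMES:
                i = feature_index(FeatureIndexKey("right", phase, "gyro_y", stat))
                b, s = base.iloc[i - 1], scaled.iloc[i - 1]
                if stat in ("Kurtosis", "Skewness"):
                    assert s == pytest.approx(b, abs=1e-9)
                else:
                    assert s == pytest.approx(c * b, rel=1e-9)

    def test_swing_gyro_features_grow_with_amplitude(self, analyzed, clean_sim):
        rec = clean_sim.right
        ph = analyzed["phases"]
        prev = None
        for c in (1.0, 1.3, 1.6):
            gyro = rec.gyro.copy() * c
            rec_c = sl.ImuRecording(rec.fs, rec.t, rec.acc, gyro, rec.foot)
            f = sl.compute_features(rec_c, clean_sim.left, ph["right"],
                                    ph["left"])
            i_max = feature_index(FeatureIndexKey("right", "mid_swing",
                                                  "gyro_y", "Max"))
            i_rms = feature_index(FeatureIndexKey("right", "mid_swing",
                                                  "gyro_y", "RMS"))
            cur = (f.iloc[i_max - 1], f.iloc[i_rms - 1])
            if prev is not None:
                assert cur[0] > prev[0] and cur[1] > prev[1]
            prev = cur

    def test_single_stride_rejected(self, analyzed, clean_sim):
        ph = analyzed["phases"]["right"]
        one = sl.PhaseWindows("right", ph.windows[:1], ph.stride_index[:1])
        with pytest.raises(GaitError):
            sl.compute_features(clean_sim.right, clean_sim.left, one,
                                analyzed["phases"]["left"])
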