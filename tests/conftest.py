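import numpy as np
import pytest

import stridelab as sl


@pytest.fixture(scope="session")
def clean_profile():
    """Grid-aligned, noise-free, symmetric gait profile (stride time 1 s)."""
    return sl.GaitProfile(cadence=120, stance_percent=60, ds1_percent=10,
                          stride_length=1.0, asymmetry=0.0, noise_sd=0.0,
                          seed=11)


@pytest.fixture(scope="session")
def clean_sim(clean_profile):
    return sl.simulate_recording(clean_profile, duration=20.0, fs=100.0)


@pytest.fixture(scope="session")
def analyzed(clean_sim):
    """Detected events, phases and features for the clean simulation."""
    ev_r = sl.detect_events(clean_sim.right)
    ev_l = sl.detect_events(clean_sim.left)
    ph_r = sl.assign_phases(ev_r, ev_l)
    ph_l = sl.assign_phases(ev_l, ev_r)
    feats = sl.compute_features(clean_sim.right, clean_sim.left, ph_r, ph_l)
    return {"events": {"right": ev_r, "left": ev_l},
            "phases": {"right": ph_r, "left": ph_l}, "features": feats}


def separated_profiles():
    """Two group profiles with a strong (several-jitter-sd) separation in
    stance percent, double support and asymmetry."""
    a = sl.GaitProfile(cadence=114.0, stance_percent=58.2, ds1_percent=9.0,
                       stride_length=0.96, asymmetry=0.07)
    b = sl.GaitProfile(cadence=114.0, stance_percent=61.8, ds1_percent=11.2,
                       stride_length=0.90, asymmetry=0.01)
    return a, b


@pytest.fixture(scope="session")
def separated_cohort_features():
    """Feature matrix + labels for a well-separated simulated cohort,
    run through the full detection/segmentation/extraction chain."""
    a, b = separated_profiles()
    cohort = sl.simulate_cohort(a, b, n_per_group=10, duration=15.0, fs=100.0,
                                seed=5, jitter_sd=0.02)
    X_rows, y = [], []
    for _sid, label, sim in cohort:
        res = sl.analyze_subject(sim.right, sim.left)
        X_rows.append(res["features"].to_numpy())
        y.append(label)
    X = np.vstack(X_rows)
    assert not np.isnan(X).any()
    return X, np.asarray(y)
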