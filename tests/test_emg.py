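"""EMG preprocessing, landmark rules, CancelTime and profile analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stopcascade import emg, synth

FS = 2000.0


def test_preprocess_zero_in_zero_out():
    out = emg.preprocess(np.zeros(4000), FS)
    assert out.shape == (4000,)
    assert np.all(out == 0.0)


def test_preprocess_rejects_nan():
    x = np.zeros(4000)
    x[5] = np.nan
    with pytest.raises(ValueError, match="trial 7"):
        emg.preprocess(x, FS, trial=7)


def test_notch_removes_mains():
    """A pure 1 mV 60 Hz sinusoid is attenuated to < 0.05 mV RMS away from
    the filter edges."""
    t = np.arange(4000) / FS
    x = 1.0 * np.sin(2 * np.pi * 60.0 * t)
    out = emg.preprocess(x, FS)
    interior = out[400:-400]
    assert interior.max() < 0.05


def test_rms_of_constant_is_constant():
    x = np.full(4000, 0.3)
    out = emg.preprocess(x, FS)
    assert out[200:-200] == pytest.approx(0.3, rel=1e-6)


def _triangle(peak_idx=1200, width=200, n=4000):
    """Symmetric triangular envelope peaking at peak_idx with given rise."""
    x = np.zeros(n)
    up = np.linspace(0, 1, width, endpoint=True)
    x[peak_idx - width:peak_idx] = up
    x[peak_idx:peak_idx + width] = up[::-1]
    return x


def test_detect_burst_on_injection(rng):
    """A burst 20x the baseline SD is found with its peak within 5 ms."""
    noise = 0.01 * rng.standard_normal(4000)
    x = noise.copy()
    inj_peak = int((500 + 300) * FS / 1000)   # 300 ms after Go at 500 ms
    x += 0.2 * np.exp(-0.5 * ((np.arange(4000) - inj_peak) / 80) ** 2)
    rms = emg.preprocess(np.abs(x), FS)
    go_idx = int(500 * FS / 1000)
    exc, chosen, flag = emg.detect_burst(rms, FS, go_idx)
    assert chosen is not None and not flag
    assert abs(chosen[2] - inj_peak) * 1000 / FS <= 5.0


def test_detect_burst_noise_only(rng):
    """Stationary baseline-distributed noise almost never crosses mean+8SD."""
    rms = emg.preprocess(0.01 * rng.standard_normal(4000), FS)
    _, chosen, _ = emg.detect_burst(rms, FS, int(500 * FS / 1000))
    assert chosen is None


def test_detect_burst_zero_variance_baseline():
    x = np.zeros(4000)
    x[2400:2600] = 1.0
    _, chosen, flag = emg.detect_burst(x, FS, 1000)
    assert flag and chosen is not None


def test_onset_triangle_geometry():
    """On a linear 0->1 rise over 100 ms the onset lands at the 20% crossing,
    i.e. 20 ms after the true foot of the ramp."""
    n = 4000
    x = np.zeros(n)
    start, width = 2000, 200      # rise over 100 ms
    x[start:start + width] = np.linspace(0, 1, width)
    x[start + width:] = 1.0
    peak = start + width
    onset, flag = emg.find_onset(x, FS, peak)
    assert not flag
    assert (onset - start) * 1000 / FS == pytest.approx(20.0, abs=1.0)


def test_onset_step_function():
    x = np.zeros(4000)
    x[2500:] = 1.0
    onset, flag = emg.find_onset(x, FS, 2600)
    assert not flag
    assert abs(onset - 2500) <= 1


def test_onset_criterion_never_met():
    x = np.full(4000, 0.5)
    x[3000] = 0.6
    onset, flag = emg.find_onset(x, FS, 3000)
    assert flag and onset == 0


def test_decline_symmetric_triangle():
    x = _triangle(peak_idx=1200)
    dec = emg.find_decline(x, FS, 1200)
    assert abs(dec - 1200) <= 1


def test_decline_requires_strict_decrease_after_plateau():
    x = np.zeros(4000)
    x[1000:1200] = np.linspace(0, 1, 200)
    x[1200:1400] = 1.0                       # 100 ms plateau
    x[1400:] = np.exp(-(np.arange(2600)) / 100.0)
    dec = emg.find_decline(x, FS, 1200)
    assert dec >= 1399                       # decay start, not plateau start
    assert emg.find_decline(np.linspace(0, 1, 4000), FS, 3990) is None


@settings(max_examples=25, deadline=None, derandomize=True)
@given(gain=st.floats(min_value=0.01, max_value=100.0),
       seed=st.integers(min_value=0, max_value=10))
def test_landmarks_gain_invariant(gain, seed):
    """Scaling a trace by any positive gain leaves all landmark times fixed."""
    r = np.random.default_rng(seed)
    x = 0.01 * r.standard_normal(4000)
    c = int(2600)
    x += 0.3 * np.exp(-0.5 * ((np.arange(4000) - c) / 60) ** 2) * r.standard_normal(4000)
    a1 = emg.annotate_trace(x, FS, go_ms=500.0)
    a2 = emg.annotate_trace(gain * x, FS, go_ms=500.0)
    assert (a1 is None) == (a2 is None)
    if a1 is not None:
        assert a1.onset_ms == a2.onset_ms
        assert a1.peak_ms == a2.peak_ms
        assert a1.decline_ms == a2.decline_ms


def test_landmark_ordering(stop_emg, session_data, default_config):
    trials, _ = session_data
    ann = emg.annotate_trials(stop_emg, trials, go_ms=default_config.fix_ms)
    assert len(ann) > 50
    assert (ann["onset_ms"] <= ann["peak_ms"]).all()
    ok = ann["decline_ms"].notna()
    assert (ann.loc[ok, "peak_ms"] <= ann.loc[ok, "decline_ms"]).all()
    ok2 = ok & ann["offset_ms"].notna()
    assert (ann.loc[ok2, "decline_ms"] <= ann.loc[ok2, "offset_ms"] + 1e-9).all()


def test_canceltime_floor_and_iqr():
    trials = pd.DataFrame({
        "trial": range(6), "type": "stop", "direction": "left",
        "ssd_ms": 200.0, "rt_ms": np.nan, "outcome": "SuccStop_PartialEMG"})
    ann = pd.DataFrame({
        "trial": range(6), "muscle": "FDI",
        "onset_ms": 700.0, "peak_ms": 800.0, "peak_amp_mv": 0.2,
        "decline_ms": [740.0, 840.0, 850.0, 860.0, 870.0, 1400.0],
        "offset_ms": np.nan, "onset_flag": False, "baseline_flag": False,
        "canceltime_ms": None, "outlier": False})
    ct = emg.compute_canceltimes(ann, trials, go_ms=500.0)
    ct = ct.set_index("trial")
    assert ct.loc[0, "canceltime_ms"] == 40.0 and ct.loc[0, "outlier"]      # < 50 ms floor
    assert ct.loc[5, "outlier"]                                             # Q3+1.5 IQR
    assert not ct.loc[2, "outlier"]


def test_canceltime_iqr_skipped_when_few_trials():
    trials = pd.DataFrame({
        "trial": [0, 1], "type": "stop", "direction": "left",
        "ssd_ms": 200.0, "rt_ms": np.nan, "outcome": "SuccStop_PartialEMG"})
    ann = pd.DataFrame({
        "trial": [0, 1], "muscle": "FDI", "onset_ms": 700.0, "peak_ms": 800.0,
        "peak_amp_mv": 0.2, "decline_ms": [860.0, 880.0], "offset_ms": np.nan,
        "onset_flag": False, "baseline_flag": False, "canceltime_ms": None,
        "outlier": False})
    ct = emg.compute_canceltimes(ann, trials, go_ms=500.0)
    assert ct["iqr_skipped"].all()
    assert not ct["outlier"].any()


def test_canceltime_injection_recovery(default_config, session_data, stop_emg):
    """Recovered CancelTimes track the injected muscle cancellation times."""
    trials, truth = session_data
    ann = emg.annotate_trials(stop_emg, trials, go_ms=default_config.fix_ms)
    ct = emg.compute_canceltimes(ann, trials, go_ms=default_config.fix_ms)
    m = ct[~ct["outlier"]].merge(truth, on="trial")
    err = (m["canceltime_ms"] - m["muscle_cancel_ms"]).dropna()
    assert len(err) > 80
    assert np.median(np.abs(err)) <= 10.0
    assert abs(err.mean()) <= 6.0


def test_normalize_profiles_scale_invariance():
    shape = np.sin(np.linspace(0, np.pi, 100)) ** 2
    profiles = [1.0 * shape, 0.1 * shape]
    out, peaks = emg.normalize_profiles(profiles, ["FDI", "ADM"], ["go", "go"])
    assert np.allclose(out["go"], shape / shape.max())
    assert np.allclose(peaks, 1.0)


def test_profile_divergence_constructed():
    fs = 2000.0
    a = np.full(400, 0.5)
    b = a.copy()
    b[100:] += 0.2                     # separate from 50 ms on
    assert emg.profile_divergence(a, b, fs, criterion=0.1) == pytest.approx(50.0, abs=1.0)
    assert emg.profile_divergence(a, a, fs, criterion=0.1) is None


def test_amplitude_by_ssd_increases(default_config, session_data, stop_emg):
    trials, _ = session_data
    ann = emg.annotate_trials(stop_emg, trials, go_ms=default_config.fix_ms)
    ct = emg.compute_canceltimes(ann, trials, go_ms=default_config.fix_ms)
    tab = emg.amplitude_by_ssd(ct, n_bins=4)
    means = tab["mean_amp"].dropna().to_numpy()
    assert len(means) >= 3
    # monotone trend allowing sampling noise: top bin clearly above bottom
    assert means[-1] > means[0]


def test_amplitude_by_ssd_single_level():
    ct = pd.DataFrame({"ssd_ms": [200.0] * 5, "peak_amp_mv": [0.1] * 5,
                       "outlier": [False] * 5})
    tab = emg.amplitude_by_ssd(ct, n_bins=5)
    assert (tab["n"] > 0).sum() == 1
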