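"""Tests of the synthetic stop-signal generator against its ground truth."""

import numpy as np
import pandas as pd
import pytest

from stopcascade import synth
from stopcascade.synth.config import RaceParams


def test_invalid_race_params_rejected():
    cfg = synth.SimConfig(race=RaceParams(mu_go=np.nan))
    with pytest.raises(ValueError, match="mu_go"):
        synth.simulate_task(cfg)
    with pytest.raises(ValueError, match="prop_stop"):
        synth.SimConfig(prop_stop=1.5).validate()
    with pytest.raises(ValueError, match="press_threshold"):
        synth.SimConfig(press_threshold_mv=0.9, emg_peak_mv=0.5).validate()


def test_reproducible_from_seed(default_config):
    t1, g1 = synth.simulate_task(default_config)
    t2, g2 = synth.simulate_task(default_config)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(g1, g2)


def test_outcome_conservation(session_data):
    trials, _ = session_data
    go = trials[trials["type"] == "go"]
    stop = trials[trials["type"] == "stop"]
    assert (go["outcome"].isin(["CorrectGo", "GoOmission"])).all()
    assert (stop["outcome"].isin(
        ["FailedStop", "SuccStop_PartialEMG", "SuccStop_NoEMG"])).all()
    assert len(go) + len(stop) == len(trials)


def test_truth_invariants(session_data):
    trials, truth = session_data
    m = trials.merge(truth, on="trial")
    nt = m[~m["triggered"] & (m["type"] == "stop")]
    assert nt["muscle_cancel_ms"].isna().all()
    part = m[m["partial"]]
    assert part["rt_ms"].isna().all()
    assert np.isfinite(part["emg_onset_ms"]).all()


def test_stop_always_wins_when_instantaneous():
    """Degenerate stop process at 0 with SSD 0 stops every triggered trial
    before any EMG."""
    rp = RaceParams(mu_stop=0.0, sigma_stop=1e-6, tau_stop=0.0, p_tf=0.0)
    cfg = synth.SimConfig(n_trials=400, race=rp, ssd_start=0.0, ssd_step=1e-9,
                          conduction_ms=0.0, seed=5)
    trials, truth = synth.simulate_task(cfg)
    stop = trials[trials["type"] == "stop"]
    assert (stop["outcome"] == "SuccStop_NoEMG").all()


def test_trigger_failure_one_means_no_stopping():
    """With p_tf = 1 the stop process never launches: P(respond|stop) equals
    P(keypress beats the deadline), independent of SSD."""
    rp = RaceParams(p_tf=1.0)
    cfg = synth.SimConfig(n_trials=4000, race=rp, seed=6)
    trials, truth = synth.simulate_task(cfg)
    stop = trials[trials["type"] == "stop"]
    p_resp = (stop["outcome"] == "FailedStop").mean()
    m = trials.merge(truth, on="trial")
    p_beats = (m["go_finish_ms"] + cfg.electromech_ms <= cfg.deadline).mean()
    assert p_resp == pytest.approx(p_beats, abs=0.03)


def test_staircase_converges_to_half():
    """The +/-50 ms staircase holds long-run P(respond|stop) at ~0.5."""
    cfg = synth.SimConfig(n_trials=40_000, seed=7)
    trials, _ = synth.simulate_task(cfg)
    stop = trials[trials["type"] == "stop"]
    assert len(stop) > 9000
    assert (stop["outcome"] == "FailedStop").mean() == pytest.approx(0.50, abs=0.02)


def test_fixed_ssd_matches_analytic_race_probability():
    """Empirical P(respond|stop) at a frozen SSD matches the race mixture
    (1-pTF) * P(race lost) + pTF * P(go beats deadline)."""
    cfg = synth.SimConfig(n_trials=40_000, ssd_start=250.0, ssd_step=1e-9, seed=8)
    trials, _ = synth.simulate_task(cfg)
    stop = trials[trials["type"] == "stop"]
    emp = (stop["outcome"] == "FailedStop").mean()
    ana = synth.respond_probability(250.0, cfg)
    assert emp == pytest.approx(ana, abs=0.015)


def test_noiseless_envelope_peak_exact(default_config):
    env = synth.render_envelope(600.0, None, default_config)
    assert env.max() == pytest.approx(default_config.emg_peak_mv, rel=1e-12)
    assert env.min() == 0.0


def test_envelope_declines_at_injected_cancellation(default_config):
    """Injected cancellation at 160 ms post-Stop shows up as the pre-noise
    envelope decline at 160 +/- 2 ms."""
    cfg = default_config
    ssd = 200.0
    onset_abs = cfg.fix_ms + ssd + 80.0      # burst begins 80 ms after Stop,
    # so the drive is still rising (peak would be at +190 ms) when cancelled
    trunc_abs = cfg.fix_ms + ssd + 160.0
    env = synth.render_envelope(onset_abs, trunc_abs, cfg)
    t = np.arange(env.size) * 1000.0 / cfg.fs_emg
    peak_ms = t[np.argmax(env)]
    assert peak_ms - (cfg.fix_ms + ssd) == pytest.approx(160.0, abs=2.0)


def test_partial_amplitude_increases_with_ssd():
    """Partial-burst drive amplitude is non-decreasing in SSD: later Stop
    signals allow the go drive to develop further before truncation."""
    cfg = synth.SimConfig(n_trials=30_000, seed=9)
    trials, truth = synth.simulate_task(cfg)
    m = trials.merge(truth, on="trial")
    part = m[(m["outcome"] == "SuccStop_PartialEMG") & m["triggered"]].copy()
    u = (part["ssd_ms"] + part["muscle_cancel_ms"] - part["emg_onset_ms"]) / cfg.emg_rise_ms
    part["amp"] = synth.envelope_shape(np.clip(u, 0, 1))
    bins = pd.qcut(part["ssd_ms"], 4, duplicates="drop")
    means = part.groupby(bins, observed=True)["amp"].mean().to_numpy()
    assert np.all(np.diff(means) > -0.02)


def test_partial_regime_matches_study_conditions():
    """Defaults land in the reported regime: ~half of successful stops carry
    a partial burst whose amplitude is ~half the keypress-trial amplitude."""
    cfg = synth.SimConfig(n_trials=20_000, seed=2)
    trials, truth = synth.simulate_task(cfg)
    stop = trials[trials["type"] == "stop"]
    succ = stop[stop["outcome"].str.startswith("SuccStop")]
    frac = (succ["outcome"] == "SuccStop_PartialEMG").mean()
    assert 0.40 <= frac <= 0.60
    m = trials.merge(truth, on="trial")
    u = (m["ssd_ms"] + m["muscle_cancel_ms"] - m["emg_onset_ms"]) / cfg.emg_rise_ms
    amp = synth.envelope_shape(np.clip(u.fillna(1.0), 0, 1))
    partial_amp = amp[m["outcome"] == "SuccStop_PartialEMG"].mean()
    keypress_amp = amp[m["outcome"].isin(["CorrectGo", "FailedStop"])].mean()
    assert 0.40 <= partial_amp / keypress_amp <= 0.60


def test_emg_alignment_and_subset(default_config, session_data, stop_emg):
    trials, truth = session_data
    some = next(iter(stop_emg))
    assert set(stop_emg[some]) == {"FDI", "ADM"}
    trace = stop_emg[some]["FDI"]
    assert trace.fs == default_config.fs_emg
    assert trace.samples.size == int(default_config.epoch_ms * trace.fs / 1000)
    with pytest.raises(ValueError, match="aligned"):
        synth.synthesize_emg(trials.iloc[:10], truth, default_config)


def test_emg_rise_resolution_guard():
    with pytest.raises(ValueError, match="fs_emg too low"):
        synth.SimConfig(fs_emg=20.0, emg_rise_ms=100.0).validate()


def test_eeg_burst_at_injected_time(session_data):
    """With zero background noise the envelope maximum sits at the injected
    burst centre: muscle cancellation minus the beta lead."""
    trials, truth = session_data
    cfg = synth.SimConfig(n_trials=2000, seed=42)
    succ = trials[trials["outcome"].str.startswith("SuccStop")]["trial"].to_numpy()[:10]
    eeg = synth.synthesize_eeg_beta(trials, truth, cfg, noise_amp=0.0, subset=succ)
    for tr, ep in eeg.items():
        if ep.injected_burst_ms is None:
            continue
        cancel = truth.set_index("trial").loc[tr, "muscle_cancel_ms"]
        assert ep.injected_burst_ms == pytest.approx(cancel - cfg.beta_lead_ms, abs=1e-9)
        env = np.abs(ep.samples)
        peak_t = ep.times_ms[np.argmax(env)]
        # waveform peak is within a beta half-cycle of the envelope centre
        assert abs(peak_t - ep.injected_burst_ms) < 1000.0 / cfg.beta_freq


def test_eeg_burst_clipped_when_lead_exceeds_cancel(session_data):
    trials, truth = session_data
    cfg = synth.SimConfig(n_trials=2000, seed=42, beta_lead_ms=5000.0)
    succ = trials[trials["outcome"].str.startswith("SuccStop")]["trial"].to_numpy()[:5]
    eeg = synth.synthesize_eeg_beta(trials, truth, cfg, subset=succ)
    flagged = [ep for ep in eeg.values() if ep.injected_burst_ms is not None]
    assert all(ep.clipped and ep.injected_burst_ms == 0.0 for ep in flagged)


def test_mep_generator_suppression_arithmetic(session_data):
    """Suppression factor 0.6 from 140 ms: early time-points sit at baseline,
    late ones at ~60% of it, ITI at 100% by construction."""
    trials, truth = session_data
    cfg = synth.SimConfig(n_trials=2000, seed=42)
    meps = synth.synthesize_mep(trials, truth, cfg)
    iti = meps[meps["tms_time"] == "ITI"]["amplitude_mv"].mean()
    succ = meps[meps["trial_type"] == "SuccStop"]
    lognorm_mean = cfg.mep_base_mv * np.exp(cfg.mep_log_sd**2 / 2)
    for t in ("100", "120"):
        grp = succ[succ["tms_time"] == t]["amplitude_mv"]
        assert grp.mean() == pytest.approx(lognorm_mean, rel=0.12)
    for t in ("140", "160", "180"):
        grp = succ[succ["tms_time"] == t]["amplitude_mv"]
        assert grp.mean() == pytest.approx(0.6 * lognorm_mean, rel=0.12)
    assert iti == pytest.approx(lognorm_mean, rel=0.1)


def test_mep_null_generator(session_data):
    trials, truth = session_data
    cfg = synth.SimConfig(n_trials=2000, seed=42, mep_suppression_factor=1.0)
    meps = synth.synthesize_mep(trials, truth, cfg)
    means = meps.groupby("trial_type")["amplitude_mv"].mean()
    assert means.max() / means.min() < 1.1
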