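"""Synthetic TMS motor-evoked potentials (MEPs).

Amplitudes are lognormal around a resting baseline.  On successfully stopped
trials, stimuli delivered at or after the global-suppression onset
(~140 ms post-Stop) are scaled down by ``mep_suppression_factor``.  Go-trial
stimulus times are yoked to the previous stop trial, as in the task design.
A small fraction of trials carries pre-TMS EMG contamination for exercising
the QC rules, and a separate helper renders MEP waveforms with a known onset
latency for conduction-time estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig

TMS_TIMES = ("ITI", 100, 120, 140, 160, 180)


def synthesize_mep(trials: pd.DataFrame, truth: pd.DataFrame, config: SimConfig,
                   seed: int | None = None) -> pd.DataFrame:
    """One MEP record per stop trial and per (roughly) half of go trials.

    Returns a DataFrame with columns trial, tms_time (``'ITI'`` or ms post-Stop
    as str), trial_type, amplitude_mv, pre_tms_emg_mv.
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 3_000_003)

    type_map = {"CorrectGo": "CorrectGo", "GoOmission": None,
                "FailedStop": "FailedStop",
                "SuccStop_PartialEMG": "SuccStop", "SuccStop_NoEMG": "SuccStop"}

    records = []
    last_stop_time = TMS_TIMES[rng.integers(len(TMS_TIMES))]
    for row in trials.itertuples(index=False):
        ttype = type_map[row.outcome]
        if ttype is None:
            continue
        if row.type == "stop":
            tms_time = TMS_TIMES[rng.integers(len(TMS_TIMES))]
            last_stop_time = tms_time
        else:
            if rng.random() < 0.5:
                continue
            tms_time = last_stop_time  # yoked to the previous stop trial
        amp = rng.lognormal(np.log(config.mep_base_mv), config.mep_log_sd)
        suppressed = (ttype == "SuccStop" and tms_time != "ITI"
                      and tms_time >= config.mep_suppression_onset_ms)
        if suppressed:
            amp *= config.mep_suppression_factor
        if rng.random() < config.mep_contam_frac:
            pre = 0.05 + abs(rng.normal(0.05, 0.02))
        else:
            pre = abs(rng.normal(0.01, 0.005))
        records.append((row.trial, str(tms_time), ttype, amp, pre))

    return pd.DataFrame(records, columns=["trial", "tms_time", "trial_type",
                                          "amplitude_mv", "pre_tms_emg_mv"])


def synthesize_mep_waveforms(n_trials: int = 10, onset_ms: float = 23.0,
                             jitter_ms: float = 1.5, fs: float = 5000.0,
                             epoch_ms: float = 60.0, amp_mv: float = 1.0,
                             noise_sd_mv: float = 0.005,
                             seed: int = 0) -> list[np.ndarray]:
    """MEP waveforms (post-stimulus epochs) with onset latency
    ``onset_ms + U(0, jitter_ms)`` per trial; used to estimate corticospinal
    conduction time as the earliest onset across trials."""
    rng = np.random.default_rng(seed)
    n = int(round(epoch_ms * fs / 1000.0))
    t = np.arange(n) * 1000.0 / fs
    waves = []
    for _ in range(n_trials):
        onset = onset_ms + rng.uniform(0.0, jitter_ms)
        w = noise_sd_mv * rng.standard_normal(n)
        dur = 10.0  # ms, one biphasic period
        m = (t >= onset) & (t < onset + dur)
        w[m] += amp_mv * np.sin(2 * np.pi * (t[m] - onset) / dur)
        waves.append(w)
    return waves
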