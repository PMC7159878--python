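"""Render two-channel surface EMG for simulated trials.

Each trial yields a 2 s epoch per muscle starting at the fixation cue.
The direction-congruent muscle (left arrow -> FDI/index, right arrow ->
ADM/little finger) carries the movement burst; the other muscle carries
baseline noise only.  The raw signal is an amplitude-modulated broadband
carrier plus Gaussian baseline noise and a 60 Hz mains component, so that
rectified-RMS processing recovers the underlying drive envelope.

On successfully stopped trials the drive is truncated at the muscle
cancellation time and decays quickly, producing the partial bursts whose
decline marks the single-trial stopping latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig
from .task import envelope_shape

MUSCLE_FOR_DIRECTION = {"left": "FDI", "right": "ADM"}


@dataclass
class EmgTrace:
    """One sampled EMG epoch."""

    samples: np.ndarray   # mV
    fs: float             # Hz
    t0: float             # ms, epoch start relative to fixation (0 here)
    muscle: str           # FDI / ADM / ECR
    trial: int

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) * 1000.0 / self.fs


def render_envelope(onset_abs_ms, trunc_abs_ms, config: SimConfig, n_samples: int | None = None):
    """Deterministic (pre-noise) drive envelope of one burst, in mV.

    ``onset_abs_ms``/``trunc_abs_ms`` are relative to the epoch start
    (fixation); pass ``trunc_abs_ms=None`` for an uncancelled burst.
    The onset is snapped to the sample grid.
    """
    fs = config.fs_emg
    if n_samples is None:
        n_samples = int(round(config.epoch_ms * fs / 1000.0))
    t = np.arange(n_samples) * 1000.0 / fs
    env = np.zeros(n_samples)
    if onset_abs_ms is None or not np.isfinite(onset_abs_ms):
        return env
    onset = round(onset_abs_ms * fs / 1000.0) * 1000.0 / fs
    peak_t = onset + config.emg_rise_ms
    u = (t - onset) / config.emg_rise_ms
    rise = config.emg_peak_mv * envelope_shape(np.clip(u, 0.0, 1.0))
    decay = config.emg_peak_mv * np.exp(-np.maximum(t - peak_t, 0.0) / config.emg_decay_ms)
    env = np.where(t < peak_t, rise, decay)
    env[t < onset] = 0.0
    if trunc_abs_ms is not None and np.isfinite(trunc_abs_ms):
        trunc = round(trunc_abs_ms * fs / 1000.0) * 1000.0 / fs
        if trunc <= onset:
            return np.zeros(n_samples)
        at = np.interp(trunc, t, env)
        after = t > trunc
        env[after] = at * np.exp(-(t[after] - trunc) / config.emg_trunc_decay_ms)
    return env


def _burst_times_for_trial(row_trial, row_truth, config: SimConfig):
    """(onset_abs, trunc_abs) in epoch time for one trial, or (None, None)."""
    onset = row_truth.emg_onset_ms
    if not np.isfinite(onset):
        return None, None
    onset_abs = config.fix_ms + onset
    trunc_abs = None
    if row_trial.type == "stop" and row_truth.triggered and np.isfinite(row_truth.muscle_cancel_ms):
        trunc_abs = config.fix_ms + row_trial.ssd_ms + row_truth.muscle_cancel_ms
        if trunc_abs <= onset_abs:
            return None, None  # cancelled before any drive reached the muscle
    return onset_abs, trunc_abs


def synthesize_emg(trials, truth, config: SimConfig, seed: int | None = None,
                   subset=None) -> dict[int, dict[str, EmgTrace]]:
    """Render raw EMG for ``subset`` (default: all) trials.

    Returns a mapping trial -> {muscle: EmgTrace} with both recorded muscles.
    """
    config.validate()
    if len(trials) != len(truth):
        raise ValueError("trials and truth must be aligned by index")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1_000_003)
    fs = config.fs_emg
    n_samples = int(round(config.epoch_ms * fs / 1000.0))
    t_s = np.arange(n_samples) / fs
    if subset is None:
        subset = trials["trial"].to_numpy()
    subset = np.asarray(subset)

    trials_ix = trials.set_index("trial")
    truth_ix = truth.set_index("trial")

    out: dict[int, dict[str, EmgTrace]] = {}
    for tr in subset:
        row_t = trials_ix.loc[tr]
        row_g = truth_ix.loc[tr]
        active = MUSCLE_FOR_DIRECTION[row_t.direction]
        onset_abs, trunc_abs = _burst_times_for_trial(row_t, row_g, config)
        out[int(tr)] = {}
        for muscle in ("FDI", "ADM"):
            if muscle == active and onset_abs is not None:
                env = render_envelope(onset_abs, trunc_abs, config, n_samples)
            else:
                env = np.zeros(n_samples)
            carrier = rng.standard_normal(n_samples)
            sig = env * carrier
            if config.noise_sd_mv > 0:
                sig = sig + config.noise_sd_mv * rng.standard_normal(n_samples)
            if config.line_amp_mv > 0:
                phase = rng.uniform(0, 2 * np.pi)
                sig = sig + config.line_amp_mv * np.sin(2 * np.pi * 60.0 * t_s + phase)
            out[int(tr)][muscle] = EmgTrace(samples=sig, fs=fs, t0=0.0, muscle=muscle, trial=int(tr))
    return out
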