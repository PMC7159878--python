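"""Surrogate single-channel EEG with injected beta bursts.

This emulates the *output* of a right-frontal spatial filter, not scalp EEG:
a 1/f background plus, on successfully stopped trials, one beta-band burst
(Gaussian envelope, ~3 cycles) whose peak precedes the muscle cancellation
time by ``beta_lead_ms``.  Epochs are aligned to the Stop signal on stop
trials and to Go + mean SSD on go trials, mirroring how the burst-threshold
windows are defined downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig


@dataclass
class EegEpoch:
    """One surrogate epoch, aligned so that t=0 is the (surrogate) Stop signal."""

    samples: np.ndarray
    fs: float
    t_start_ms: float     # time of first sample relative to alignment point
    trial: int
    injected_burst_ms: float | None = None   # ground-truth burst peak, ms post-align
    clipped: bool = False                    # burst centre fell before the Stop signal

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.samples.size) * 1000.0 / self.fs


def one_over_f_noise(n: int, fs: float, rng: np.random.Generator,
                     f_lo: float = 2.0, f_hi: float = 100.0) -> np.ndarray:
    """Unit-SD band-limited 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    shape[band] = 1.0 / np.sqrt(freqs[band])
    sig = np.fft.irfft(spec * shape, n=n)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def beta_burst_waveform(t_ms: np.ndarray, centre_ms: float, freq: float,
                        amp: float, phase: float = 0.0) -> np.ndarray:
    """Gaussian-windowed beta oscillation; FWHM of the envelope ~= 3 cycles."""
    sigma_ms = 3000.0 / freq / 2.355  # FWHM = 3 periods
    env = amp * np.exp(-0.5 * ((t_ms - centre_ms) / sigma_ms) ** 2)
    return env * np.cos(2 * np.pi * freq * (t_ms - centre_ms) / 1000.0 + phase)


def synthesize_eeg_beta(trials: pd.DataFrame, truth: pd.DataFrame, config: SimConfig,
                        seed: int | None = None, noise_amp: float = 1.0,
                        subset=None) -> dict[int, EegEpoch]:
    """Render one surrogate epoch per trial (see module docstring)."""
    config.validate()
    if len(trials) != len(truth):
        raise ValueError("trials and truth must be aligned by index")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2_000_003)
    fs = config.fs_eeg
    half = config.eeg_epoch_half_ms
    n = int(round(2 * half * fs / 1000.0))
    t_ms = -half + np.arange(n) * 1000.0 / fs

    if subset is None:
        subset = trials["trial"].to_numpy()
    trials_ix = trials.set_index("trial")
    truth_ix = truth.set_index("trial")

    out: dict[int, EegEpoch] = {}
    for tr in np.asarray(subset):
        row_t = trials_ix.loc[tr]
        row_g = truth_ix.loc[tr]
        sig = noise_amp * one_over_f_noise(n, fs, rng) if noise_amp > 0 else np.zeros(n)
        burst_ms = None
        clipped = False
        succ = row_t.type == "stop" and row_t.outcome in ("SuccStop_PartialEMG", "SuccStop_NoEMG")
        if succ and row_g.triggered and np.isfinite(row_g.muscle_cancel_ms):
            centre = row_g.muscle_cancel_ms - config.beta_lead_ms
            if centre < 0:
                centre = 0.0
                clipped = True
            phase = rng.uniform(0, 2 * np.pi)
            sig = sig + beta_burst_waveform(t_ms, centre, config.beta_freq,
                                            config.beta_burst_amp, phase)
            burst_ms = float(centre)
        out[int(tr)] = EegEpoch(samples=sig, fs=fs, t_start_ms=float(t_ms[0]),
                                trial=int(tr), injected_burst_ms=burst_ms, clipped=clipped)
    return out
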