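"""Beta-burst detection from a spatially filtered (single-channel) signal.

The chain mirrors the standard burst analysis for right-frontal stop-signal
EEG: a Morlet time-frequency map (4-30 Hz, 3 cycles at the lowest frequency
increasing by 0.5 per Hz) identifies the participant's peak beta frequency
in the Stop-signal -> SSRT window; the signal is then narrow-band filtered
at that frequency with a frequency-domain Gaussian window (FWHM 5 Hz), the
analytic envelope is taken by Hilbert transform, and bursts are
supra-threshold excursions of the envelope.  The detection threshold is the
median + 1.5 SD of the envelope amplitude pooled over a late post-Stop
window (500-1000 ms; post-mean-SSD on go trials), and the burst-width
threshold is the median + 1 SD.  BurstTime is the time of the envelope peak
within a burst.

ICA decomposition and dipole fitting are upstream concerns: this module
consumes the already spatially filtered series (or the surrogate generator's
output) and implements only the beta-power selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BurstParams:
    beta_band: tuple = (13.0, 30.0)
    tf_freqs: tuple = (4.0, 30.0)
    wavelet_cycles_base: float = 3.0     # cycles at the lowest frequency
    wavelet_cycles_step: float = 0.5     # increase per Hz
    filter_fwhm_hz: float = 5.0
    thresh_k: float = 1.5                # detection: median + 1.5 SD
    width_k: float = 1.0                 # burst width: median + 1 SD
    thresh_window_ms: tuple = (500.0, 1000.0)   # post-Stop / post-mean-SSD

    def validate(self) -> None:
        if not self.width_k < self.thresh_k:
            raise ValueError("width_k must be below thresh_k")
        if self.thresh_window_ms[0] >= self.thresh_window_ms[1]:
            raise ValueError("empty threshold window")


# ------------------------------------------------------------------ TF map

def morlet_tf(epochs: np.ndarray, fs: float, params: BurstParams | None = None):
    """Morlet time-frequency power of shape (n_epochs, n_freqs, n_times).

    ``epochs`` is (n_epochs, n_times).  Epochs shorter than the longest
    wavelet are rejected.
    """
    from mne.time_frequency import tfr_array_morlet
    params = params or BurstParams()
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    f_lo, f_hi = params.tf_freqs
    freqs = np.arange(f_lo, f_hi + 1e-9, 1.0)
    n_cycles = params.wavelet_cycles_base + params.wavelet_cycles_step * (freqs - f_lo)
    longest = np.max(n_cycles / freqs)
    if epochs.shape[1] / fs < longest:
        raise ValueError("epoch shorter than the longest wavelet "
                         f"({longest:.2f} s at {freqs[np.argmax(n_cycles / freqs)]:.0f} Hz)")
    power = tfr_array_morlet(epochs[:, None, :], sfreq=fs, freqs=freqs,
                             n_cycles=n_cycles, output="power", zero_mean=True)
    return freqs, power[:, 0, :, :]


def select_peak_beta(epochs: np.ndarray, fs: float, t_start_ms: float,
                     ssrt_beh_ms: float, params: BurstParams | None = None,
                     baseline_window_ms: tuple = (-1000.0, -500.0),
                     margin: float = 0.05):
    """Peak beta frequency in the Stop-signal -> SSRT window, or None.

    Epochs must be aligned so t=0 is the Stop signal.  Returns the 13-30 Hz
    frequency with maximal mean power in [0, SSRT] if the band-mean power
    there exceeds the pre-Go baseline window by the relative ``margin``
    (which absorbs wavelet edge effects on stationary signals); otherwise
    None (rejection, mirroring participant exclusion when no beta-responsive
    component exists).
    """
    params = params or BurstParams()
    freqs, power = morlet_tf(epochs, fs, params)
    t_ms = t_start_ms + np.arange(power.shape[-1]) * 1000.0 / fs
    beta = (freqs >= params.beta_band[0]) & (freqs <= params.beta_band[1])
    stop_win = (t_ms >= 0) & (t_ms <= ssrt_beh_ms)
    base_win = (t_ms >= baseline_window_ms[0]) & (t_ms <= baseline_window_ms[1])
    if not stop_win.any() or not base_win.any():
        raise ValueError("analysis windows fall outside the epoch")
    stop_power = power[:, beta, :][:, :, stop_win].mean(axis=(0, 2))  # per beta freq
    base_power = power[:, beta, :][:, :, base_win].mean(axis=(0, 2))
    if stop_power.mean() <= (1.0 + margin) * base_power.mean():
        return None
    return float(freqs[beta][np.argmax(stop_power)])


# ------------------------------------------------------------------ envelope

def beta_envelope(signal: np.ndarray, fs: float, centre_freq: float,
                  fwhm_hz: float = 5.0) -> np.ndarray:
    """Analytic envelope after a frequency-domain Gaussian band-pass.

    The spectrum is multiplied by a Gaussian centred on ``centre_freq`` with
    the given FWHM; negative frequencies are zeroed (and positive ones
    doubled), so the inverse FFT is the analytic signal and its modulus the
    envelope.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    spec = np.fft.fft(x)
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    sigma = fwhm_hz / 2.355
    gain = np.exp(-0.5 * ((freqs - centre_freq) / sigma) ** 2)
    gain[freqs < 0] = 0.0
    analytic = np.fft.ifft(spec * gain * 2.0)
    return np.abs(analytic)


# ------------------------------------------------------------------ bursts

@dataclass
class BetaBurstSet:
    bursts: pd.DataFrame           # trial, burst_time_ms, onset_ms, offset_ms, peak_amp
    burst_pct: dict                # trial type -> fraction supra-threshold per sample
    times_ms: np.ndarray
    detect_threshold: float
    width_threshold: float
    peak_beta_freq: float
    masks: dict = field(default_factory=dict)  # trial -> binary width-supra mask


def detect_bursts(epochs: dict, trials: pd.DataFrame, peak_beta_freq: float,
                  params: BurstParams | None = None) -> BetaBurstSet:
    """Detect beta bursts in every epoch.

    ``epochs`` maps trial -> object with ``samples``, ``fs`` and
    ``t_start_ms`` (t=0 at the alignment point: Stop signal, or Go + mean
    SSD on go trials).  Thresholds are computed from the envelope amplitude
    pooled over the 500-1000 ms post-alignment window across all trials.
    """
    params = params or BurstParams()
    params.validate()
    first = next(iter(epochs.values()))
    fs = first.fs
    n = first.samples.size
    t_ms = first.t_start_ms + np.arange(n) * 1000.0 / fs
    w_lo, w_hi = params.thresh_window_ms
    win = (t_ms >= w_lo) & (t_ms <= w_hi)
    if not win.any():
        raise ValueError("threshold window outside the epoch")

    envs = {tr: beta_envelope(ep.samples, fs, peak_beta_freq, params.filter_fwhm_hz)
            for tr, ep in epochs.items()}
    pooled = np.concatenate([env[win] for env in envs.values()])
    med, sd = float(np.median(pooled)), float(pooled.std())
    detect_th = med + params.thresh_k * sd
    width_th = med + params.width_k * sd

    trials_ix = trials.set_index("trial")
    rows, masks = [], {}
    for tr, env in envs.items():
        wide = env > width_th
        masks[tr] = wide
        for s, e in _runs(wide):
            if not (env[s:e] > detect_th).any():
                continue
            p = s + int(np.argmax(env[s:e]))
            rows.append({"trial": tr, "burst_time_ms": float(t_ms[p]),
                         "onset_ms": float(t_ms[s]), "offset_ms": float(t_ms[e - 1]),
                         "peak_amp": float(env[p])})
    bursts = pd.DataFrame(rows, columns=["trial", "burst_time_ms", "onset_ms",
                                         "offset_ms", "peak_amp"])

    burst_pct = {}
    ttypes = {tr: _trial_type(trials_ix.loc[tr, "outcome"]) for tr in epochs}
    for ttype in sorted(set(ttypes.values())):
        sel = [masks[tr] for tr in epochs if ttypes[tr] == ttype]
        if sel:
            burst_pct[ttype] = np.mean(sel, axis=0)
    return BetaBurstSet(bursts=bursts, burst_pct=burst_pct, times_ms=t_ms,
                        detect_threshold=detect_th, width_threshold=width_th,
                        peak_beta_freq=peak_beta_freq, masks=masks)


def _runs(mask: np.ndarray):
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _trial_type(outcome: str) -> str:
    if outcome.startswith("SuccStop"):
        return "SuccStop"
    if outcome == "FailedStop":
        return "FailedStop"
    return "CorrectGo"


def burst_window_stats(burst_set: BetaBurstSet, trials: pd.DataFrame,
                       ssrt_beh_ms: float, mean_ssd_ms: float) -> dict:
    """Mean burst % per trial-type x window, and mean BurstTime in StopWin.

    StopWin is [0, SSRT_Beh] after the alignment point; BaseWin is the Go ->
    Stop-signal interval (Go -> mean SSD on go trials).  A burst counts for
    StopWin if its BurstTime falls inside the window.  With zero StopWin
    bursts on successful stop trials the mean BurstTime is None.
    """
    t_ms = burst_set.times_ms
    trials_ix = trials.set_index("trial")
    stats: dict = {}
    for tr, mask in burst_set.masks.items():
        row = trials_ix.loc[tr]
        ttype = _trial_type(row["outcome"])
        base_len = row["ssd_ms"] if row["type"] == "stop" and np.isfinite(row["ssd_ms"]) \
            else mean_ssd_ms
        stop_win = (t_ms >= 0) & (t_ms <= ssrt_beh_ms)
        base_win = (t_ms >= -base_len) & (t_ms < 0)
        for wname, wmask in (("StopWin", stop_win), ("BaseWin", base_win)):
            key = (ttype, wname)
            stats.setdefault(key, []).append(float(mask[wmask].mean()) if wmask.any() else np.nan)
    out = {"burst_pct": {k: float(np.nanmean(v)) for k, v in stats.items()}}
    succ_trials = set(trials_ix.index[trials_ix["outcome"].str.startswith("SuccStop")])
    b = burst_set.bursts
    in_win = b[(b["burst_time_ms"] >= 0) & (b["burst_time_ms"] <= ssrt_beh_ms)
               & b["trial"].isin(succ_trials)]
    out["mean_burst_time_ms"] = float(in_win["burst_time_ms"].mean()) if len(in_win) else None
    out["n_stopwin_bursts"] = int(len(in_win))
    return out
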