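"""MEP (motor-evoked potential) quality control, normalisation, and
CancelTime-relative binning; corticospinal conduction time.

MEPs are probed at fixed times after the Stop signal (100-180 ms in 20 ms
steps) plus an inter-trial-interval (ITI) baseline.  QC excludes trials with
pre-TMS EMG contamination (>= 0.05 mV in the 90 ms before the pulse) and
amplitudes outside mean +/- 1.5 IQR of their (time-point x trial-type)
group.  Amplitudes are expressed as a percentage of the mean ITI amplitude.
The trial-by-trial analysis re-times each pulse relative to the EMG decline
on that trial and pools 30 ms bins across participants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def qc_filter(meps: pd.DataFrame, pre_emg_max_mv: float = 0.05,
              iqr_k: float = 1.5, min_group: int = 4) -> pd.DataFrame:
    """Apply the two QC rules; adds ``qc_pass``, ``qc_pre_emg``, ``qc_amp``,
    ``qc_iqr_skipped`` columns.

    Rule (ii) (amplitude within group mean +/- 1.5 IQR, computed per
    time-point x trial-type group) is skipped, with a flag, for groups
    smaller than ``min_group``.
    """
    out = meps.copy()
    out["qc_pre_emg"] = out["pre_tms_emg_mv"] < pre_emg_max_mv
    out["qc_amp"] = True
    out["qc_iqr_skipped"] = False
    for _, idx in out.groupby(["tms_time", "trial_type"]).groups.items():
        amps = out.loc[idx, "amplitude_mv"].to_numpy()
        if amps.size < min_group:
            out.loc[idx, "qc_iqr_skipped"] = True
            continue
        q1, q3 = np.percentile(amps, [25, 75])
        iqr = q3 - q1
        mean = amps.mean()
        tol = 1e-9 * max(1.0, abs(mean))   # guard against fp summation error
        ok = (amps >= mean - iqr_k * iqr - tol) & (amps <= mean + iqr_k * iqr + tol)
        out.loc[idx, "qc_amp"] = ok
    out["qc_pass"] = out["qc_pre_emg"] & out["qc_amp"]
    return out


def normalize_to_iti(meps: pd.DataFrame) -> pd.DataFrame:
    """Express amplitudes as % of the mean ITI amplitude (QC-passing trials,
    collapsed across trial types).  The ITI group mean maps to exactly 100."""
    passing = meps[meps.get("qc_pass", pd.Series(True, index=meps.index))]
    iti = passing[passing["tms_time"] == "ITI"]["amplitude_mv"]
    if len(iti) == 0:
        raise ValueError("no QC-passing ITI trials to normalise against")
    baseline = float(iti.mean())
    if baseline <= 0:
        raise ValueError("non-positive ITI baseline amplitude")
    out = meps.copy()
    out["amplitude_pct"] = 100.0 * out["amplitude_mv"] / baseline
    return out


def timepoint_means(meps: pd.DataFrame) -> pd.DataFrame:
    """Mean normalised amplitude per TMS time-point x trial type
    (QC-passing trials only)."""
    df = meps[meps["qc_pass"]] if "qc_pass" in meps else meps
    return (df.groupby(["tms_time", "trial_type"])["amplitude_pct"]
              .agg(["mean", "count"]).reset_index())


def bin_relative_to_canceltime(meps: pd.DataFrame, decline_ms_by_trial: dict,
                               bin_ms: float = 30.0, t_range=(-90.0, 60.0),
                               min_trials: int = 50) -> pd.DataFrame:
    """Pool MEP amplitudes into bins of TMS time relative to the EMG decline.

    ``meps`` needs numeric ``tms_time_ms`` (post-Stop) and normalised
    ``amplitude_pct``; ``decline_ms_by_trial`` maps trial -> EMG decline time
    (post-Stop), so only EMG-burst trials participate.  Bins are half-open
    [lo, hi) labelled by the lower edge; negative times mean the pulse
    preceded the decline.  Bins with fewer than ``min_trials`` pooled trials
    are dropped.
    """
    df = meps.copy()
    df = df[df["trial"].isin(decline_ms_by_trial.keys())]
    if "tms_time_ms" not in df:
        df = df[df["tms_time"] != "ITI"].copy()
        df["tms_time_ms"] = df["tms_time"].astype(float)
    df["t_norm_ms"] = df["tms_time_ms"] - df["trial"].map(decline_ms_by_trial)
    edges = np.arange(t_range[0], t_range[1] + bin_ms, bin_ms)
    df = df[(df["t_norm_ms"] >= edges[0]) & (df["t_norm_ms"] < edges[-1])]
    if df.empty:
        return pd.DataFrame(columns=["bin_lo_ms", "trial_type", "mean_pct", "n"])
    df["bin_lo_ms"] = edges[np.searchsorted(edges, df["t_norm_ms"], side="right") - 1]
    rows = []
    for (lo, ttype), grp in df.groupby(["bin_lo_ms", "trial_type"]):
        rows.append({"bin_lo_ms": float(lo), "trial_type": ttype,
                     "mean_pct": float(grp["amplitude_pct"].mean()), "n": len(grp)})
    out = pd.DataFrame(rows)
    counts = out.groupby("bin_lo_ms")["n"].sum()
    keep = counts[counts >= min_trials].index
    return out[out["bin_lo_ms"].isin(keep)].reset_index(drop=True)


def mep_onset_latency(wave: np.ndarray, fs: float, pre_ms: float = 20.0,
                      k_sd: float = 3.0, sustain_ms: float = 1.0):
    """Automated MEP onset: first point exceeding mean + ``k_sd`` SD of the
    pre-stimulus baseline for at least ``sustain_ms``; None if absent."""
    w = np.asarray(wave, dtype=float)
    n_pre = int(round(pre_ms * fs / 1000.0))
    base = w[:n_pre] if n_pre > 0 else w[:1]
    thresh = np.abs(base).mean() + k_sd * np.abs(base).std()
    above = np.abs(w) > thresh
    nb = max(1, int(round(sustain_ms * fs / 1000.0)))
    count = 0
    for i in range(n_pre, w.size):
        count = count + 1 if above[i] else 0
        if count >= nb:
            return (i - nb + 1) * 1000.0 / fs
    return None


def conduction_time(waves: list, fs: float, **kwargs):
    """Corticospinal conduction time: the earliest MEP onset latency across
    trials (minimum statistic over ~10 stimuli); None if no MEP detected."""
    onsets = [mep_onset_latency(w, fs, **kwargs) for w in waves]
    onsets = [o for o in onsets if o is not None]
    return min(onsets) if onsets else None
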