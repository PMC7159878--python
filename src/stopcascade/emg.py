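"""Single-trial EMG pipeline: preprocessing, burst detection, landmark
extraction, and CancelTime.

The processing chain mirrors standard practice for surface EMG in
stop-signal experiments:

1. notch out mains (60 Hz) and harmonics with 4th-order Butterworth
   band-stops, full-wave rectify, and smooth with a centred 50 ms RMS window;
2. mark a burst wherever the RMS exceeds baseline mean + 8 SD (baseline =
   fixation to Go cue);
3. backtrack from the burst peak to the onset: the point where activity last
   stayed below 20% of the peak for 5 consecutive ms;
4. the decline is the earliest post-peak point from which the RMS decreases
   strictly for 5 consecutive ms;
5. CancelTime = decline time minus Stop-signal time, on successfully stopped
   trials with a burst (partial-EMG trials), with a 50 ms lower cutoff and a
   Q3 + 1.5 IQR upper cutoff.

All landmark rules operate on sample indices and are gain-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt


@dataclass
class DetectionParams:
    notch_freqs: tuple = (60.0, 120.0, 180.0)
    notch_halfwidth: float = 2.0   # Hz, each band-stop spans f +/- halfwidth
    filter_order: int = 4
    rms_window_ms: float = 50.0
    burst_k_sd: float = 8.0
    onset_frac: float = 0.20
    hold_ms: float = 5.0
    canceltime_floor_ms: float = 50.0
    iqr_k: float = 1.5

    def validate(self) -> None:
        if not 0.0 < self.onset_frac < 1.0:
            raise ValueError("onset_frac must lie in (0, 1)")
        for name in ("rms_window_ms", "burst_k_sd", "hold_ms",
                     "canceltime_floor_ms", "iqr_k", "notch_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def hold_samples(self, fs: float) -> int:
        """'Five consecutive ms' in samples: ceil(hold_ms * fs / 1000)."""
        return int(math.ceil(self.hold_ms * fs / 1000.0))


@dataclass
class BurstAnnotation:
    """Landmarks of one detected EMG burst (times in ms, epoch-relative)."""

    trial: int
    muscle: str
    onset_ms: float
    peak_ms: float
    peak_amp_mv: float
    decline_ms: float | None
    offset_ms: float | None
    onset_flag: bool = False       # onset criterion never met; clamped to epoch start
    baseline_flag: bool = False    # zero-variance baseline; epsilon threshold used
    canceltime_ms: float | None = None
    outlier: bool = False


# ---------------------------------------------------------------- preprocessing

def preprocess(samples: np.ndarray, fs: float, params: DetectionParams | None = None,
               trial: int | None = None) -> np.ndarray:
    """Notch-filter, rectify and RMS-smooth one EMG epoch.

    Returns a non-negative trace of the same length.  Window edges use a
    shrink-to-valid window, so the first/last ~25 ms are averaged over fewer
    samples.
    """
    params = params or DetectionParams()
    params.validate()
    x = np.asarray(samples, dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"NaN in EMG input (trial {trial})")
    if x.size < max(params.rms_window_ms * fs / 1000.0, 3 * params.filter_order):
        raise ValueError("trace shorter than the RMS window")
    for f0 in params.notch_freqs:
        if f0 + params.notch_halfwidth >= fs / 2:
            continue
        b, a = butter(params.filter_order // 2,
                      [f0 - params.notch_halfwidth, f0 + params.notch_halfwidth],
                      btype="bandstop", fs=fs)
        x = filtfilt(b, a, x)
    x = np.abs(x)
    w = int(round(params.rms_window_ms * fs / 1000.0))
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


# ---------------------------------------------------------------- burst landmarks

def _runs_above(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs (stop exclusive)."""
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


def detect_burst(rms: np.ndarray, fs: float, baseline_stop_idx: int,
                 params: DetectionParams | None = None, search_start_idx: int | None = None):
    """Find supra-threshold excursions after the Go cue.

    ``baseline_stop_idx`` is the sample index of the Go cue; baseline spans
    [0, baseline_stop_idx).  Returns (excursions, chosen, baseline_flag) where
    ``excursions`` is a list of (start, stop, peak_idx) and ``chosen`` the
    excursion with the largest peak (or None).
    """
    params = params or DetectionParams()
    base = rms[:baseline_stop_idx]
    if base.size == 0:
        raise ValueError("empty baseline window")
    mu, sd = float(base.mean()), float(base.std())
    baseline_flag = False
    if sd == 0.0:
        thresh = mu + np.finfo(float).eps * max(1.0, abs(mu))
        baseline_flag = True
    else:
        thresh = mu + params.burst_k_sd * sd
    start = baseline_stop_idx if search_start_idx is None else search_start_idx
    mask = rms > thresh
    mask[:start] = False
    excursions = []
    for s, e in _runs_above(mask):
        peak = s + int(np.argmax(rms[s:e]))
        excursions.append((s, e, peak))
    chosen = max(excursions, key=lambda x: rms[x[2]]) if excursions else None
    return excursions, chosen, baseline_flag


def find_onset(rms: np.ndarray, fs: float, peak_idx: int,
               params: DetectionParams | None = None):
    """Backtrack from the peak to the last point where the RMS stayed below
    ``onset_frac * peak`` for ``hold_ms``.  Returns (onset_idx, flagged)."""
    params = params or DetectionParams()
    nb = params.hold_samples(fs)
    level = params.onset_frac * rms[peak_idx]
    below = rms[:peak_idx] < level
    count = 0
    for j in range(peak_idx - 1, -1, -1):
        count = count + 1 if below[j] else 0
        if count >= nb:
            return min(j + nb, peak_idx - 1), False
    return 0, True


def find_decline(rms: np.ndarray, fs: float, peak_idx: int,
                 params: DetectionParams | None = None):
    """Earliest index >= peak from which the RMS strictly decreases for
    ``hold_ms``; None if no such run occurs before the epoch end."""
    params = params or DetectionParams()
    nb = params.hold_samples(fs)
    dec = np.diff(rms[peak_idx:]) < 0
    if dec.size < nb:
        return None
    # run of nb consecutive strict decreases starting at offset t
    kernel = np.ones(nb)
    hits = np.convolve(dec.astype(float), kernel, mode="valid") == nb
    idx = np.flatnonzero(hits)
    return peak_idx + int(idx[0]) if idx.size else None


def find_offset(rms: np.ndarray, fs: float, peak_idx: int,
                params: DetectionParams | None = None):
    """Forward mirror of the onset rule (non-normative): first post-peak point
    where the RMS stays below ``onset_frac * peak`` for ``hold_ms``."""
    params = params or DetectionParams()
    nb = params.hold_samples(fs)
    level = params.onset_frac * rms[peak_idx]
    below = rms[peak_idx:] < level
    count = 0
    for j, b in enumerate(below):
        count = count + 1 if b else 0
        if count >= nb:
            return peak_idx + j - nb + 1
    return None


def annotate_trace(samples: np.ndarray, fs: float, go_ms: float,
                   params: DetectionParams | None = None, trial: int = -1,
                   muscle: str = "FDI", t0: float = 0.0) -> BurstAnnotation | None:
    """Run the full landmark chain on one raw epoch; None if no burst."""
    params = params or DetectionParams()
    rms = preprocess(samples, fs, params, trial=trial)
    go_idx = int(round((go_ms - t0) * fs / 1000.0))
    _, chosen, base_flag = detect_burst(rms, fs, go_idx, params)
    if chosen is None:
        return None
    _, _, peak = chosen
    onset, onset_flag = find_onset(rms, fs, peak, params)
    decline = find_decline(rms, fs, peak, params)
    offset = find_offset(rms, fs, peak, params)
    to_ms = lambda i: t0 + i * 1000.0 / fs
    return BurstAnnotation(
        trial=trial, muscle=muscle,
        onset_ms=to_ms(onset), peak_ms=to_ms(peak), peak_amp_mv=float(rms[peak]),
        decline_ms=to_ms(decline) if decline is not None else None,
        offset_ms=to_ms(offset) if offset is not None else None,
        onset_flag=onset_flag, baseline_flag=base_flag)


def annotate_trials(emg: dict, trials: pd.DataFrame, go_ms: float,
                    params: DetectionParams | None = None,
                    muscle_for_direction: dict | None = None) -> pd.DataFrame:
    """Annotate the direction-congruent muscle of each rendered trial.

    ``emg`` maps trial -> {muscle: EmgTrace} (see ``stopcascade.synth``).
    Returns one row per trial that has a detected burst.
    """
    from .synth.emg import MUSCLE_FOR_DIRECTION
    muscle_for_direction = muscle_for_direction or MUSCLE_FOR_DIRECTION
    trials_ix = trials.set_index("trial")
    rows = []
    for tr, muscles in emg.items():
        muscle = muscle_for_direction[trials_ix.loc[tr, "direction"]]
        trace = muscles[muscle]
        ann = annotate_trace(trace.samples, trace.fs, go_ms, params,
                             trial=tr, muscle=muscle, t0=trace.t0)
        if ann is not None:
            rows.append(ann.__dict__)
    cols = ["trial", "muscle", "onset_ms", "peak_ms", "peak_amp_mv", "decline_ms",
            "offset_ms", "onset_flag", "baseline_flag", "canceltime_ms", "outlier"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------- CancelTime

def iqr_bounds(values: np.ndarray, k: float = 1.5):
    q1, q3 = np.nanpercentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def compute_canceltimes(annotations: pd.DataFrame, trials: pd.DataFrame,
                        go_ms: float, params: DetectionParams | None = None) -> pd.DataFrame:
    """CancelTime per partial-EMG trial: decline time minus Stop-signal time.

    Values below the 50 ms floor or above Q3 + 1.5 IQR are flagged as
    outliers.  With fewer than 3 partial trials, the IQR rule is skipped
    (only the floor applies) and ``iqr_skipped`` is set.
    """
    params = params or DetectionParams()
    trials_ix = trials.set_index("trial")
    ann = annotations.merge(
        trials_ix[["type", "ssd_ms", "outcome"]], left_on="trial", right_index=True)
    is_partial = (ann["type"] == "stop") & ann["outcome"].str.startswith("SuccStop") \
        & ann["decline_ms"].notna()
    out = ann.loc[is_partial].copy()
    out["canceltime_ms"] = out["decline_ms"] - (go_ms + out["ssd_ms"])
    out["outlier"] = out["canceltime_ms"] < params.canceltime_floor_ms
    out["iqr_skipped"] = False
    valid = out.loc[~out["outlier"], "canceltime_ms"].to_numpy()
    if valid.size >= 3:
        _, hi = iqr_bounds(valid, params.iqr_k)
        out.loc[out["canceltime_ms"] > hi, "outlier"] = True
    else:
        out["iqr_skipped"] = True
    return out


def landmark_outliers(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Generic two-sided IQR outlier mask for landmark timing distributions."""
    values = np.asarray(values, dtype=float)
    lo, hi = iqr_bounds(values, k)
    return (values < lo) | (values > hi)


# ---------------------------------------------------------------- profiles

def normalize_profiles(profiles, muscles, groups):
    """Average RMS profiles per group after per-muscle peak normalisation.

    ``profiles`` is a sequence of equal-length arrays, ``muscles`` the muscle
    label and ``groups`` the trial-type label per profile.  Each muscle's
    profiles are divided by that muscle's peak activity across its trials
    before averaging, so outputs lie in [0, 1].  Zero-peak trials are skipped.
    Returns (group -> mean profile, per-trial normalised peaks).
    """
    profiles = [np.asarray(p, dtype=float) for p in profiles]
    muscles = np.asarray(muscles)
    groups = np.asarray(groups)
    peak_per_muscle = {}
    for m in np.unique(muscles):
        peak = max((p.max() for p, mm in zip(profiles, muscles) if mm == m), default=0.0)
        peak_per_muscle[m] = peak
    normed, keep = [], []
    for p, m in zip(profiles, muscles):
        if peak_per_muscle[m] > 0:
            normed.append(p / peak_per_muscle[m])
            keep.append(True)
        else:
            keep.append(False)
    groups = groups[np.asarray(keep, dtype=bool)]
    out = {}
    for g in np.unique(groups):
        out[str(g)] = np.mean([p for p, gg in zip(normed, groups) if gg == g], axis=0)
    peaks = np.array([p.max() for p in normed])
    return out, peaks


def profile_divergence(profile_a: np.ndarray, profile_b: np.ndarray, fs: float,
                       criterion: float = 0.05, hold_ms: float = 5.0):
    """First time (ms from profile start) at which two onset-aligned profiles
    differ by more than ``criterion`` sustained for ``hold_ms``; None if never."""
    a, b = np.asarray(profile_a, float), np.asarray(profile_b, float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    nb = max(1, int(math.ceil(hold_ms * fs / 1000.0)))
    above = np.abs(a - b) > criterion
    kernel = np.ones(nb)
    hits = np.convolve(above.astype(float), kernel, mode="valid") == nb
    idx = np.flatnonzero(hits)
    return float(idx[0] * 1000.0 / fs) if idx.size else None


def amplitude_by_ssd(canceltimes: pd.DataFrame, n_bins: int = 5,
                     value_col: str = "peak_amp_mv") -> pd.DataFrame:
    """Mean partial-burst amplitude per SSD bin (quantile bins, logged edges).

    Empty bins are reported with NaN means, never zero.
    """
    df = canceltimes.loc[~canceltimes["outlier"]].copy()
    if df.empty:
        return pd.DataFrame(columns=["bin", "ssd_lo", "ssd_hi", "n", "mean_amp"])
    edges = np.unique(np.quantile(df["ssd_ms"], np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        edges = np.array([df["ssd_ms"].min() - 0.5, df["ssd_ms"].max() + 0.5])
    df["bin"] = np.clip(np.searchsorted(edges, df["ssd_ms"], side="right") - 1,
                        0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        sel = df[df["bin"] == b]
        rows.append({"bin": b, "ssd_lo": edges[b], "ssd_hi": edges[b + 1],
                     "n": len(sel),
                     "mean_amp": sel[value_col].mean() if len(sel) else np.nan})
    return pd.DataFrame(rows)
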