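"""Trial classification, SSRT estimation, and inhibition-function fitting.

``ssrt_integration`` implements the consensus integration method: the
stopping latency is the P(respond|stop) quantile of the go-RT distribution
(n-th ordered RT with n = ceil(p * N), omissions replaced by the maximum RT)
minus the mean SSD.

``ssrt_emg`` recomputes the same quantity from EMG onsets: partial-EMG
trials are recoded as responses, the go-side distribution is the EMG onset
time on correct go trials, and — because P(EMG-respond|stop) is usually well
above 0.5 — SSRT is computed per SSD level and averaged.

The inhibition function w(t) = gamma - (gamma - delta) * exp(-(t/alpha)^beta)
is fitted to P(respond|SSD) by weighted nonlinear least squares; alpha is the
SSD at which w covers 1 - 1/e (~63%) of its range and beta the slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

RESPONDED_OUTCOMES = ("CorrectGo", "FailedStop")


def classify_trials(trials: pd.DataFrame, annotations: pd.DataFrame | None = None,
                    go_ms: float = 0.0) -> pd.DataFrame:
    """Label every trial and attach EMG-derived response times.

    Without annotations the input outcome labels are validated and passed
    through.  With annotations, successful stop trials are split into
    partial-EMG vs no-EMG according to burst detection, ``rt_emg_ms`` is set
    to the detected burst onset relative to the Go cue (annotation onsets
    are epoch-relative; pass the Go-cue time as ``go_ms``), and a keypress
    without a detected burst is flagged as ``anomaly`` (possible detection
    miss).
    """
    out = trials.copy()
    out["rt_emg_ms"] = np.nan
    out["anomaly"] = False
    if annotations is None or annotations.empty:
        return out
    ann = annotations.set_index("trial")
    has_burst = out["trial"].isin(ann.index)
    onset = out["trial"].map(ann["onset_ms"]) - go_ms
    out.loc[has_burst, "rt_emg_ms"] = onset[has_burst]
    is_stop = out["type"] == "stop"
    succ = is_stop & out["rt_ms"].isna()
    out.loc[succ & has_burst, "outcome"] = "SuccStop_PartialEMG"
    out.loc[succ & ~has_burst, "outcome"] = "SuccStop_NoEMG"
    out.loc[is_stop & out["rt_ms"].notna(), "outcome"] = "FailedStop"
    out.loc[out["rt_ms"].notna() & ~has_burst, "anomaly"] = True
    counts = out["outcome"].value_counts()
    n_go = int((out["type"] == "go").sum())
    assert counts.get("CorrectGo", 0) + counts.get("GoOmission", 0) == n_go
    return out


def ssrt_integration(go_rts, p_respond: float, mean_ssd: float,
                     n_omissions: int = 0):
    """Integration-method SSRT (ms).  Go omissions are replaced by the
    maximum observed RT.  Returns None (with no exception) if ``p_respond``
    is not strictly inside (0, 1)."""
    if not 0.0 < p_respond < 1.0:
        return None
    rts = np.sort(np.asarray(go_rts, dtype=float))
    if rts.size == 0:
        return None
    if n_omissions:
        rts = np.sort(np.concatenate([rts, np.full(n_omissions, rts.max())]))
    n = int(math.ceil(p_respond * rts.size))
    n = min(max(n, 1), rts.size)
    return float(rts[n - 1] - mean_ssd)


def ssrt_beh(trials: pd.DataFrame):
    """Behavioural SSRT of one session from its trial table."""
    go = trials[trials["type"] == "go"]
    stop = trials[trials["type"] == "stop"]
    if len(stop) == 0:
        return None
    p_respond = float((stop["outcome"] == "FailedStop").mean())
    return ssrt_integration(
        go.loc[go["outcome"] == "CorrectGo", "rt_ms"].to_numpy(),
        p_respond, float(stop["ssd_ms"].mean()),
        n_omissions=int((go["outcome"] == "GoOmission").sum()))


def ssrt_emg(trials: pd.DataFrame, min_trials_per_ssd: int = 5,
             p_range: tuple = (0.0, 1.0)):
    """EMG-based SSRT: per-SSD integration on EMG onsets, averaged over SSDs.

    Requires ``rt_emg_ms`` (from :func:`classify_trials`).  A response is any
    stop trial with an EMG burst (failed stops and partial-EMG trials).  SSD
    levels with fewer than ``min_trials_per_ssd`` stop trials, or with
    P(respond) outside the open interval ``p_range`` (always excluding exact
    0 and 1, where the quantile is undefined), are skipped.  Returns
    (ssrt, per_ssd table).
    """
    go_onsets = trials.loc[(trials["outcome"] == "CorrectGo")
                           & trials["rt_emg_ms"].notna(), "rt_emg_ms"].to_numpy()
    stop = trials[trials["type"] == "stop"]
    rows = []
    for ssd, grp in stop.groupby("ssd_ms"):
        n = len(grp)
        responded = grp["outcome"].isin(["FailedStop", "SuccStop_PartialEMG"])
        p = float(responded.mean())
        est = None
        lo = max(p_range[0], 0.0)
        hi = min(p_range[1], 1.0)
        if n >= min_trials_per_ssd and lo < p < hi:
            est = ssrt_integration(go_onsets, p, float(ssd))
        rows.append({"ssd_ms": ssd, "n": n, "p_respond_emg": p, "ssrt_ms": est})
    per_ssd = pd.DataFrame(rows)
    used = per_ssd["ssrt_ms"].dropna()
    return (float(used.mean()) if len(used) else None), per_ssd


def inhibition_function(trials: pd.DataFrame, by_emg: bool = False) -> pd.DataFrame:
    """P(respond|SSD) table from a trial table."""
    stop = trials[trials["type"] == "stop"]
    responded_set = ["FailedStop", "SuccStop_PartialEMG"] if by_emg else ["FailedStop"]
    rows = []
    for ssd, grp in stop.groupby("ssd_ms"):
        rows.append({"ssd_ms": float(ssd), "n": len(grp),
                     "p_respond": float(grp["outcome"].isin(responded_set).mean())})
    return pd.DataFrame(rows)


def weibull(t, alpha, beta, gamma, delta):
    t = np.asarray(t, dtype=float)
    return gamma - (gamma - delta) * np.exp(-((t / alpha) ** beta))


@dataclass
class WeibullFit:
    alpha: float
    beta: float
    gamma: float
    delta: float
    converged: bool = True
    message: str = ""

    def __call__(self, t):
        return weibull(t, self.alpha, self.beta, self.gamma, self.delta)


def fit_weibull(ssds, p_respond, weights=None) -> WeibullFit:
    """Weighted least-squares fit of the cumulative-Weibull inhibition
    function; parameters bounded (alpha, beta > 0; gamma, delta in [0, 1])."""
    ssds = np.asarray(ssds, dtype=float)
    p = np.asarray(p_respond, dtype=float)
    if np.unique(ssds).size < 4:
        raise ValueError("need at least 4 distinct SSDs for the Weibull fit")
    if weights is None:
        weights = np.ones_like(p)
    weights = np.asarray(weights, dtype=float)
    sigma = 1.0 / np.sqrt(np.maximum(weights, 1e-12))
    p0 = [float(np.interp(0.5, [0, 1], [ssds.min() + 1.0, ssds.max()])),
          2.0, float(p.max()), float(p.min())]
    lb = [1e-3, 1e-3, 0.0, 0.0]
    ub = [np.inf, np.inf, 1.0, 1.0]
    try:
        popt, _ = curve_fit(weibull, ssds, p, p0=p0, sigma=sigma,
                            bounds=(lb, ub), maxfev=20000)
    except RuntimeError as err:
        return WeibullFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                          message=str(err))
    fit = WeibullFit(*[float(v) for v in popt])
    if fit.gamma < fit.delta:   # monotone non-decreasing over the data range
        fit.converged = False
        fit.message = "fitted gamma < delta (non-monotone)"
    return fit


def session_summary(trials: pd.DataFrame) -> dict:
    """Per-session behavioural summary used by downstream modules."""
    stop = trials[trials["type"] == "stop"]
    succ = stop[stop["outcome"].str.startswith("SuccStop")]
    n_succ = len(succ)
    emg_based, per_ssd = ssrt_emg(trials) if "rt_emg_ms" in trials else (None, None)
    return {
        "n_trials": len(trials),
        "n_stop": len(stop),
        "p_respond_stop": float((stop["outcome"] == "FailedStop").mean()) if len(stop) else np.nan,
        "p_partial": float((succ["outcome"] == "SuccStop_PartialEMG").mean()) if n_succ else np.nan,
        "mean_ssd_ms": float(stop["ssd_ms"].mean()) if len(stop) else np.nan,
        "go_rt_ms": float(trials.loc[trials["outcome"] == "CorrectGo", "rt_ms"].mean()),
        "ssrt_beh_ms": ssrt_beh(trials),
        "ssrt_emg_ms": emg_based,
    }
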