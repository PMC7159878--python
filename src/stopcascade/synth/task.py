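"""Stop-signal task simulator: independent go/stop race with a ballistic stage.

The generative chain per trial:

* the go process crosses the response threshold at ``G`` ms after the Go cue
  (ex-Gaussian);
* the keypress registers at ``G + electromech_ms`` if it beats the deadline;
* the commitment point ("point of no return") is ``G - ballistic_ms``;
* on a triggered stop trial the stop command cancels the muscle drive at
  ``SSD + S + conduction_ms`` (``S`` ex-Gaussian from the Stop signal);
  a keypress results iff the cancellation arrives after the commitment point;
* the EMG burst starts a fixed rise-to-threshold interval before ``G``; a
  successful stop whose cancellation lands after that onset leaves a partial
  (truncated) burst.

Two independent +/-50 ms SSD staircases (one per response direction) track
P(respond|stop) ~ 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ..exgauss import exgauss_rvs
from .config import SimConfig

OUTCOMES = ("CorrectGo", "GoOmission", "FailedStop", "SuccStop_PartialEMG", "SuccStop_NoEMG")


def envelope_shape(u):
    """Normalised burst envelope rise: gamma-like, 0 at u=0, peaking at 1 at u=1."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    m = u > 0
    out[m] = u[m] ** 2 * np.exp(2.0 * (1.0 - u[m]))
    return out


def rise_to_threshold_ms(config: SimConfig) -> float:
    """Time from EMG onset to the press-threshold crossing, set by the
    envelope geometry and the threshold/peak ratio."""
    q = config.press_threshold_mv / config.emg_peak_mv
    f = lambda u: float(envelope_shape(u)) - q
    u_star = brentq(f, 1e-9, 1.0)
    return u_star * config.emg_rise_ms


def simulate_task(config: SimConfig, seed: int | None = None):
    """Simulate one session.

    Returns
    -------
    trials : DataFrame with columns trial, type, direction, ssd_ms, rt_ms, outcome
    truth : DataFrame with the per-trial ground truth (go_finish_ms from Go,
        stop_finish_ms and muscle_cancel_ms from Stop, triggered, partial,
        emg_onset_ms and true_keypress_ms from Go).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    r = config.race
    n = config.n_trials

    is_stop = rng.random(n) < config.prop_stop
    direction = np.where(rng.random(n) < 0.5, "left", "right")
    G = 1000.0 * exgauss_rvs(n, r.mu_go, r.sigma_go, r.tau_go, rng)  # ms from Go
    S = 1000.0 * exgauss_rvs(n, r.mu_stop, r.sigma_stop, r.tau_stop, rng)  # ms from Stop
    triggered = rng.random(n) >= r.p_tf

    rise_ms = rise_to_threshold_ms(config)
    onset = G - rise_ms                      # EMG burst onset, ms from Go
    commit = G - config.ballistic_ms         # point of no return, ms from Go
    keypress = G + config.electromech_ms     # ms from Go

    staircase = {"left": float(config.ssd_start), "right": float(config.ssd_start)}

    ssd = np.full(n, np.nan)
    rt = np.full(n, np.nan)
    outcome = np.empty(n, dtype=object)
    trig = np.zeros(n, dtype=bool)
    cancel = np.full(n, np.nan)   # muscle cancellation, ms from Stop
    stop_fin = np.full(n, np.nan)
    partial = np.zeros(n, dtype=bool)
    press = np.full(n, np.nan)
    emg_onset = np.full(n, np.nan)

    for i in range(n):
        if not is_stop[i]:
            if keypress[i] <= config.deadline:
                rt[i] = keypress[i]
                press[i] = keypress[i]
                outcome[i] = "CorrectGo"
            else:
                outcome[i] = "GoOmission"
            emg_onset[i] = onset[i]
            continue

        d = staircase[direction[i]]
        ssd[i] = d
        trig[i] = triggered[i]
        if triggered[i]:
            stop_fin[i] = S[i]
            cancel[i] = S[i] + config.conduction_ms
            cancel_from_go = d + cancel[i]
            responded = cancel_from_go > commit[i]
        else:
            responded = True
        responded = responded and keypress[i] <= config.deadline

        if responded:
            rt[i] = keypress[i]
            press[i] = keypress[i]
            outcome[i] = "FailedStop"
            emg_onset[i] = onset[i]
            staircase[direction[i]] = max(0.0, d - config.ssd_step)
        else:
            # successful stop: burst present iff the drive started before it
            # was cancelled (or was never cancelled but missed the deadline)
            if triggered[i]:
                has_emg = onset[i] < d + cancel[i]
            else:
                has_emg = True  # untriggered deadline miss: full burst, no press
            if has_emg:
                outcome[i] = "SuccStop_PartialEMG"
                partial[i] = True
                emg_onset[i] = onset[i]
            else:
                outcome[i] = "SuccStop_NoEMG"
            staircase[direction[i]] = min(config.deadline, d + config.ssd_step)

    trials = pd.DataFrame({
        "trial": np.arange(n),
        "type": np.where(is_stop, "stop", "go"),
        "direction": direction,
        "ssd_ms": ssd,
        "rt_ms": rt,
        "outcome": outcome,
    })
    truth = pd.DataFrame({
        "trial": np.arange(n),
        "go_finish_ms": G,
        "stop_finish_ms": stop_fin,
        "triggered": trig,
        "muscle_cancel_ms": cancel,
        "partial": partial,
        "true_keypress_ms": press,
        "emg_onset_ms": emg_onset,
    })
    return trials, truth


def respond_probability(ssd_ms, config: SimConfig, n_mc: int = 200_000, seed: int = 1):
    """Analytic-by-simulation oracle: P(respond|stop) at a fixed SSD under the
    race (1 - p_tf) * P(cancellation arrives after commitment) +
    p_tf * P(keypress <= deadline)."""
    rng = np.random.default_rng(seed)
    r = config.race
    G = 1000.0 * exgauss_rvs(n_mc, r.mu_go, r.sigma_go, r.tau_go, rng)
    S = 1000.0 * exgauss_rvs(n_mc, r.mu_stop, r.sigma_stop, r.tau_stop, rng)
    commit = G - config.ballistic_ms
    cancel_from_go = ssd_ms + S + config.conduction_ms
    beats_deadline = G + config.electromech_ms <= config.deadline
    p_race = np.mean((cancel_from_go > commit) & beats_deadline)
    p_free = np.mean(beats_deadline)
    return (1.0 - r.p_tf) * p_race + r.p_tf * p_free
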