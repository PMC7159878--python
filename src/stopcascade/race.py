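"""Ex-Gaussian race model with trigger failures.

The model assumes a race between stochastically independent go and stop
processes, each with an ex-Gaussian finish-time distribution, plus a
probability ``p_tf`` that the stop process is never triggered.  Internally
everything is in seconds (the uniform priors U(0,2)/U(0,0.5) only make sense
on that scale); module interfaces accept milliseconds where noted.

Likelihood contributions per trial (SSD ``d``, deadline ``T``):

* go trial with RT ``t``: ``f_G(t)``; go omission: ``S_G(T)``;
* failed stop with RT ``t``: ``f_G(t) * (p_tf + (1 - p_tf) * S_S(t - d))``;
* successful stop: ``(1 - p_tf) * E_S[S_G(min(d + S, T))] + p_tf * S_G(T)``
  (Gauss-Legendre quadrature over the stop finish time; with ``T = inf``
  this is the classic integral of ``f_G(t) F_S(t - d)``).

The hierarchical fit places truncated-normal group distributions over the
seven individual parameters, with uniform hyperpriors on the group means
(over the prior bounds) and SDs, and samples by Metropolis-within-Gibbs with
per-parameter Gaussian proposals adapted during burn-in.  Convergence is
monitored with the Gelman-Rubin statistic (R-hat < 1.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr

from .exgauss import (exgauss_logpdf, exgauss_pdf, exgauss_cdf, exgauss_sf,
                      exgauss_rvs)
from .synth.config import RaceParams

PARAM_NAMES = ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop", "tau_stop", "p_tf")
# prior bounds, seconds (p_tf unitless)
PARAM_BOUNDS = {
    "mu_go": (0.0, 2.0), "sigma_go": (1e-4, 0.5), "tau_go": (1e-4, 0.5),
    "mu_stop": (0.0, 2.0), "sigma_stop": (1e-4, 0.5), "tau_stop": (1e-4, 0.5),
    "p_tf": (0.0, 1.0),
}

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)
_GL_NODES = 0.5 * (_GL_NODES + 1.0)      # on [0, 1]
_GL_WEIGHTS = 0.5 * _GL_WEIGHTS

_ALL_IDX = np.arange(7)
_STOP_IDX = np.arange(3, 7)        # mu_stop, sigma_stop, tau_stop, p_tf
_STOP_SHAPE_IDX = np.arange(3, 6)  # mu_stop, sigma_stop, tau_stop ridge

# population-wide translation directions (see the sampler): single stop-side
# parameters, the sigma/tau trade-off, and the mu/tau trade-off
_TRANSLATIONS = np.array([
    [0, 0, 0, 1, 0, 0, 0],
    [0, 0, 0, 0, 1, 0, 0],
    [0, 0, 0, 0, 0, 1, 0],
    [0, 0, 0, 0, 0, 0, 1],
    [0, 0, 0, 0, 1, -1, 0],
    [0, 0, 0, 1, 0, -1, 0],
], dtype=float)


def params_to_array(p: RaceParams) -> np.ndarray:
    return np.array([getattr(p, n) for n in PARAM_NAMES], dtype=float)


def array_to_params(a) -> RaceParams:
    return RaceParams(**{n: float(v) for n, v in zip(PARAM_NAMES, a)})


# ------------------------------------------------------------------ likelihood

def _stop_quadrature(mu_s: float, sig_s: float, tau_s: float):
    """Gauss-Legendre nodes/weights over the effective support of the stop
    finish-time density.  The interval is centred on the distribution (not
    anchored at zero) so that near-degenerate sigma/tau are still resolved."""
    s_lo = mu_s - 8.0 * sig_s          # the Gaussian component may go negative
    s_hi = mu_s + 8.0 * sig_s + 20.0 * tau_s
    span = max(s_hi - s_lo, 1e-9)
    s = s_lo + _GL_NODES * span
    w = _GL_WEIGHTS * span * exgauss_pdf(s, mu_s, sig_s, tau_s)
    return s, w


def p_inhibit(ssd_s, params: RaceParams, deadline_s: float | None = None):
    """Analytic P(no response | stop trial at SSD) under the race model."""
    params.validate()
    ssd_s = np.atleast_1d(np.asarray(ssd_s, dtype=float))
    s, w = _stop_quadrature(params.mu_stop, params.sigma_stop, params.tau_stop)
    finish = ssd_s[:, None] + s[None, :]
    if deadline_s is not None:
        finish = np.minimum(finish, deadline_s)
    sg = exgauss_sf(finish, params.mu_go, params.sigma_go, params.tau_go)
    race_term = sg @ w
    tail = (exgauss_sf(deadline_s, params.mu_go, params.sigma_go, params.tau_go)
            if deadline_s is not None else 0.0)
    out = (1.0 - params.p_tf) * race_term + params.p_tf * tail
    return out if out.size > 1 else float(out[0])


@dataclass
class TrialData:
    """Compiled per-participant data for the likelihood (seconds)."""

    go_rts: np.ndarray
    n_go_omissions: int
    fs_rts: np.ndarray
    fs_ssds: np.ndarray
    succ_ssds: np.ndarray      # distinct SSDs of successful stops
    succ_counts: np.ndarray
    deadline: float | None = None


def compile_trials(trials: pd.DataFrame, deadline_ms: float | None = None) -> TrialData:
    """Convert a trial table (ms) into likelihood-ready arrays (seconds)."""
    go = trials[trials["type"] == "go"]
    go_rts = go.loc[go["outcome"] == "CorrectGo", "rt_ms"].to_numpy() / 1000.0
    if np.any(go_rts <= 0):
        raise ValueError("non-positive go RT in trial table")
    stop = trials[trials["type"] == "stop"]
    fs = stop[stop["outcome"] == "FailedStop"]
    if fs["rt_ms"].isna().any():
        raise ValueError("failed stop trial without an RT")
    succ = stop[stop["outcome"].str.startswith("SuccStop")]
    if "rt_ms" in succ and succ["rt_ms"].notna().any():
        raise ValueError("RT present on a successful stop trial")
    d, c = np.unique(succ["ssd_ms"].to_numpy() / 1000.0, return_counts=True)
    return TrialData(
        go_rts=go_rts,
        n_go_omissions=int((go["outcome"] == "GoOmission").sum()),
        fs_rts=fs["rt_ms"].to_numpy() / 1000.0,
        fs_ssds=fs["ssd_ms"].to_numpy() / 1000.0,
        succ_ssds=d, succ_counts=c.astype(float),
        deadline=deadline_ms / 1000.0 if deadline_ms is not None else None)


def _loglik_theta(theta: np.ndarray, data: TrialData) -> float:
    mu_g, sig_g, tau_g, mu_s, sig_s, tau_s, ptf = theta
    ll = 0.0
    if data.go_rts.size:
        ll += float(np.sum(exgauss_logpdf(data.go_rts, mu_g, sig_g, tau_g)))
    if data.n_go_omissions and data.deadline is not None:
        sf = exgauss_sf(data.deadline, mu_g, sig_g, tau_g)
        ll += data.n_go_omissions * np.log(max(float(sf), 1e-300))
    if data.fs_rts.size:
        lg = exgauss_logpdf(data.fs_rts, mu_g, sig_g, tau_g)
        ss = exgauss_sf(data.fs_rts - data.fs_ssds, mu_s, sig_s, tau_s)
        ll += float(np.sum(lg + np.log(np.maximum(ptf + (1.0 - ptf) * ss, 1e-300))))
    if data.succ_ssds.size:
        s, w = _stop_quadrature(mu_s, sig_s, tau_s)
        finish = data.succ_ssds[:, None] + s[None, :]
        if data.deadline is not None:
            finish = np.minimum(finish, data.deadline)
        sg = exgauss_sf(finish, mu_g, sig_g, tau_g)
        p = (1.0 - ptf) * (sg @ w)
        if data.deadline is not None:
            p = p + ptf * exgauss_sf(data.deadline, mu_g, sig_g, tau_g)
        ll += float(np.sum(data.succ_counts * np.log(np.maximum(p, 1e-300))))
    return ll


def race_loglik(trials: pd.DataFrame, params: RaceParams,
                deadline_ms: float | None = None) -> float:
    """Log-likelihood of one participant's trial table (ms) under ``params``."""
    params.validate()
    return _loglik_theta(params_to_array(params), compile_trials(trials, deadline_ms))


def simulate_race_outcomes(params: RaceParams, ssd_s: float, n: int,
                           rng: np.random.Generator,
                           deadline_s: float | None = None) -> float:
    """Brute-force empirical P(no response | SSD): the independent oracle for
    :func:`p_inhibit`."""
    G = exgauss_rvs(n, params.mu_go, params.sigma_go, params.tau_go, rng)
    S = exgauss_rvs(n, params.mu_stop, params.sigma_stop, params.tau_stop, rng)
    trig = rng.random(n) >= params.p_tf
    stop_wins = G >= ssd_s + S
    misses = G > deadline_s if deadline_s is not None else np.zeros(n, dtype=bool)
    inhibited = (trig & (stop_wins | misses)) | (~trig & misses)
    return float(inhibited.mean())


# ------------------------------------------------------------------ hierarchy

def _trunc_norm_logpdf(x, m, s, lo, hi):
    z = (x - m) / s
    norm = ndtr((hi - m) / s) - ndtr((lo - m) / s)
    return -0.5 * z * z - np.log(s) - 0.5 * np.log(2 * np.pi) - np.log(np.maximum(norm, 1e-300))


@dataclass
class RacePosterior:
    """Posterior samples from the hierarchical fit.

    ``group`` maps '<param>_mean'/'<param>_sd' to (chain, draw) arrays;
    ``individual`` maps param names to (chain, draw, participant) arrays.
    """

    group: dict
    individual: dict
    rhat: dict
    n_chains: int
    n_samples: int
    thin: int
    converged: bool = False
    accept_rates: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.group.items():
            rows.append({"param": name, "mean": float(arr.mean()),
                         "sd": float(arr.std()),
                         "q2.5": float(np.quantile(arr, 0.025)),
                         "q97.5": float(np.quantile(arr, 0.975)),
                         "rhat": self.rhat.get(name, np.nan)})
        return pd.DataFrame(rows)

    def ssrt_beests_ms(self) -> dict:
        """Posterior summary of the stopping-latency distribution:
        mean = E[mu_stop + tau_stop], SD = E[sqrt(sigma_stop^2 + tau_stop^2)],
        both in ms (posterior means over individual-participant draws)."""
        mu = self.individual["mu_stop"]
        sig = self.individual["sigma_stop"]
        tau = self.individual["tau_stop"]
        return {"mean_ms": 1000.0 * float((mu + tau).mean()),
                "sd_ms": 1000.0 * float(np.sqrt(sig**2 + tau**2).mean()),
                "p_tf": float(self.individual["p_tf"].mean())}


def _init_theta(data: TrialData, rng: np.random.Generator) -> np.ndarray:
    m = float(np.mean(data.go_rts)) if data.go_rts.size else 0.45
    sd = float(np.std(data.go_rts)) if data.go_rts.size > 1 else 0.1
    tau = min(max(0.8 * sd, 0.01), 0.45)
    sig = min(max(np.sqrt(max(sd**2 - tau**2, 1e-4)), 0.01), 0.45)
    theta = np.array([max(m - tau, 0.05), sig, tau, 0.18, 0.04, 0.05, 0.03])
    # overdispersed chain starts so the Gelman-Rubin diagnostic is honest
    theta = theta * np.exp(0.25 * rng.standard_normal(7))
    for k, name in enumerate(PARAM_NAMES):
        lo, hi = PARAM_BOUNDS[name]
        theta[k] = float(np.clip(theta[k], lo + 1e-4 * (hi - lo), hi - 1e-4 * (hi - lo)))
    return theta


def fit_hierarchical(trial_tables: list[pd.DataFrame], n_samples: int = 5000,
                     thin: int = 5, n_chains: int = 3, burn: int = 1000,
                     seed: int = 0, deadline_ms: float | None = None,
                     adapt_every: int = 25) -> RacePosterior:
    """Hierarchical Bayesian fit of the race model across participants.

    ``n_samples`` post-burn-in Metropolis-within-Gibbs sweeps per chain are
    retained every ``thin``-th sweep.  With a single participant the fit
    degrades gracefully to a non-hierarchical fit under the uniform priors
    (the group level is still sampled but carries no pooling information).
    """
    if len(trial_tables) == 0:
        raise ValueError("need at least one participant")
    datasets = [compile_trials(t, deadline_ms) for t in trial_tables]
    n_part = len(datasets)
    n_keep = n_samples // thin
    rng_master = np.random.default_rng(seed)

    bounds = np.array([PARAM_BOUNDS[n] for n in PARAM_NAMES])
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo

    group_chains = {f"{n}_{k}": np.empty((n_chains, n_keep)) for n in PARAM_NAMES
                    for k in ("mean", "sd")}
    indiv_chains = {n: np.empty((n_chains, n_keep, n_part)) for n in PARAM_NAMES}
    accept = {"individual": 0, "group": 0, "individual_n": 0, "group_n": 0}

    for c in range(n_chains):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        theta = np.stack([_init_theta(d, rng) for d in datasets])  # (n_part, 7)
        gmean = theta.mean(axis=0)
        gsd = np.maximum(theta.std(axis=0), 0.02 * width)
        loglik = np.array([_loglik_theta(theta[i], datasets[i]) for i in range(n_part)])

        scale_i = np.full((n_part, 7), 0.0) + 0.05 * width
        scale_g = np.full((2, 7), 0.02) * width
        acc_i = np.zeros((n_part, 7))
        acc_g = np.zeros((2, 7))
        # adaptive block proposals: running mean/covariance per participant
        blk_mean = theta.copy()
        blk_m2 = np.zeros((n_part, 7, 7))
        blk_count = 1
        blk_scale = np.full(n_part, 2.38**2 / 7.0)
        blk_scale_stop = np.full(n_part, 2.38**2 / 4.0)
        acc_blk = np.zeros(n_part)
        acc_blk_stop = np.zeros(n_part)
        scale_t = np.full(len(_TRANSLATIONS), 0.01)
        acc_t = np.zeros(len(_TRANSLATIONS))

        kept = 0
        total = burn + n_samples
        for it in range(total):
            # individual parameters
            for k in range(7):
                prop = theta[:, k] + scale_i[:, k] * rng.standard_normal(n_part)
                inside = (prop > lo[k]) & (prop < hi[k])
                for i in np.flatnonzero(inside):
                    th_new = theta[i].copy()
                    th_new[k] = prop[i]
                    ll_new = _loglik_theta(th_new, datasets[i])
                    z_old = (theta[i, k] - gmean[k]) / gsd[k]
                    z_new = (prop[i] - gmean[k]) / gsd[k]
                    log_a = ll_new - loglik[i] + 0.5 * (z_old**2 - z_new**2)
                    if np.log(rng.random()) < log_a:
                        theta[i, k] = prop[i]
                        loglik[i] = ll_new
                        acc_i[i, k] += 1
            # adaptive-covariance block update per participant: mixes along
            # the mu/sigma/tau/p_tf ridges that single-parameter moves crawl
            blk_count += 1
            delta = theta - blk_mean
            blk_mean += delta / blk_count
            blk_m2 += np.einsum("ij,ik->ijk", delta, theta - blk_mean)
            if blk_count > 50:
                for i in range(n_part):
                    cov = blk_m2[i] / (blk_count - 1)
                    # the stop-side ridge mixes slowest; hit it several times
                    schedule = ((_ALL_IDX, blk_scale[i]),
                                (_STOP_IDX, blk_scale_stop[i]),
                                (_STOP_SHAPE_IDX, blk_scale_stop[i]),
                                (_STOP_IDX, blk_scale_stop[i]),
                                (_STOP_SHAPE_IDX, blk_scale_stop[i]))
                    for sel, sc in schedule:
                        sub = cov[np.ix_(sel, sel)]
                        try:
                            chol = np.linalg.cholesky(
                                sc * sub + 1e-12 * np.eye(len(sel)))
                        except np.linalg.LinAlgError:
                            continue
                        prop = theta[i].copy()
                        prop[sel] = prop[sel] + chol @ rng.standard_normal(len(sel))
                        if np.any(prop <= lo) or np.any(prop >= hi):
                            continue
                        ll_new = _loglik_theta(prop, datasets[i])
                        z_old = ((theta[i] - gmean) / gsd) ** 2
                        z_new = ((prop - gmean) / gsd) ** 2
                        log_a = ll_new - loglik[i] + 0.5 * (z_old - z_new).sum()
                        if np.log(rng.random()) < log_a:
                            theta[i] = prop
                            loglik[i] = ll_new
                            if sel is _ALL_IDX:
                                acc_blk[i] += 1
                            else:
                                acc_blk_stop[i] += 1
            # joint translation moves: slide every participant and the group
            # mean together along weakly identified population directions
            # (single stop-side parameters, and the sigma/tau trade-off)
            for mi, move in enumerate(_TRANSLATIONS):
                delta = scale_t[mi] * rng.standard_normal()
                prop = theta + delta * move[None, :]
                gm_new = gmean + delta * move
                if np.any(prop <= lo[None, :]) or np.any(prop >= hi[None, :]) \
                        or np.any(gm_new <= lo) or np.any(gm_new >= hi):
                    continue
                ll_new = np.array([_loglik_theta(prop[i], datasets[i])
                                   for i in range(n_part)])
                touched = np.flatnonzero(move)
                lp_old = lp_new = 0.0
                for k in touched:
                    lp_old += _trunc_norm_logpdf(theta[:, k], gmean[k], gsd[k],
                                                 lo[k], hi[k]).sum()
                    lp_new += _trunc_norm_logpdf(prop[:, k], gm_new[k], gsd[k],
                                                 lo[k], hi[k]).sum()
                if np.log(rng.random()) < ll_new.sum() - loglik.sum() + lp_new - lp_old:
                    theta = prop
                    gmean = gm_new
                    loglik = ll_new
                    acc_t[mi] += 1
            # group means and SDs
            for k in range(7):
                m_new = gmean[k] + scale_g[0, k] * rng.standard_normal()
                if lo[k] < m_new < hi[k]:
                    cur = _trunc_norm_logpdf(theta[:, k], gmean[k], gsd[k], lo[k], hi[k]).sum()
                    new = _trunc_norm_logpdf(theta[:, k], m_new, gsd[k], lo[k], hi[k]).sum()
                    if np.log(rng.random()) < new - cur:
                        gmean[k] = m_new
                        acc_g[0, k] += 1
                s_new = gsd[k] + scale_g[1, k] * rng.standard_normal()
                if 1e-4 * width[k] < s_new < width[k]:
                    cur = _trunc_norm_logpdf(theta[:, k], gmean[k], gsd[k], lo[k], hi[k]).sum()
                    new = _trunc_norm_logpdf(theta[:, k], gmean[k], s_new, lo[k], hi[k]).sum()
                    if np.log(rng.random()) < new - cur:
                        gsd[k] = s_new
                        acc_g[1, k] += 1
            # proposal adaptation during burn-in, targeting ~30% acceptance
            if it < burn and (it + 1) % adapt_every == 0:
                rate_i = acc_i / adapt_every
                scale_i *= np.exp(np.clip(rate_i - 0.3, -0.5, 0.5))
                scale_i = np.clip(scale_i, 1e-5 * width, width)
                rate_g = acc_g / adapt_every
                scale_g *= np.exp(np.clip(rate_g - 0.3, -0.5, 0.5))
                scale_g = np.clip(scale_g, 1e-5 * np.array([width, width]), width)
                blk_scale *= np.exp(np.clip(acc_blk / adapt_every - 0.25, -0.5, 0.5))
                blk_scale = np.clip(blk_scale, 1e-4, 10.0)
                blk_scale_stop *= np.exp(
                    np.clip(acc_blk_stop / adapt_every - 0.25, -0.5, 0.5))
                blk_scale_stop = np.clip(blk_scale_stop, 1e-4, 10.0)
                scale_t *= np.exp(np.clip(acc_t / adapt_every - 0.3, -0.5, 0.5))
                scale_t = np.clip(scale_t, 1e-6, 0.5)
                acc_i[:] = 0
                acc_g[:] = 0
                acc_blk[:] = 0
                acc_blk_stop[:] = 0
                acc_t[:] = 0
            if it >= burn:
                accept["individual"] += acc_i.sum()
                accept["individual_n"] += n_part * 7
                accept["group"] += acc_g.sum()
                accept["group_n"] += 14
                acc_i[:] = 0
                acc_g[:] = 0
                acc_blk[:] = 0
                acc_blk_stop[:] = 0
                acc_t[:] = 0
                if (it - burn) % thin == 0 and kept < n_keep:
                    for k, name in enumerate(PARAM_NAMES):
                        group_chains[f"{name}_mean"][c, kept] = gmean[k]
                        group_chains[f"{name}_sd"][c, kept] = gsd[k]
                        indiv_chains[name][c, kept] = theta[:, k]
                    kept += 1

    rhat = {name: _gelman_rubin(arr) for name, arr in group_chains.items()}
    for name, arr in indiv_chains.items():
        rhat[f"{name}_individual_max"] = max(
            _gelman_rubin(arr[:, :, i]) for i in range(n_part))
    converged = all(np.isfinite(v) and v < 1.1 for v in rhat.values())
    rates = {
        "individual": accept["individual"] / max(accept["individual_n"], 1),
        "group": accept["group"] / max(accept["group_n"], 1),
    }
    return RacePosterior(group=group_chains, individual=indiv_chains, rhat=rhat,
                         n_chains=n_chains, n_samples=n_samples, thin=thin,
                         converged=converged, accept_rates=rates)


def _gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin R-hat for a (chain, draw) array."""
    c, d = chains.shape
    half = d // 2
    if half < 2:
        return np.nan
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    b = n * means.var(ddof=1)
    w = split.var(axis=1, ddof=1).mean()
    if w <= 0:
        return np.nan
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


# ------------------------------------------------------------------ ballistic stage

def simulate_ballistic(race: RaceParams, ballistic_ms: float, n_trials: int = 40_000,
                       seed: int = 0, electromech_ms: float = 0.0,
                       conduction_ms: float = 23.0,
                       min_trials_per_ssd: int = 50,
                       p_range: tuple = (0.25, 0.90)) -> dict:
    """Predict SSRT_Beh, SSRT_EMG and their gap for a given ballistic-stage
    duration, using the full task simulator (staircased SSDs) at behavioural
    scale but without EMG rendering.

    The EMG-side estimate uses burst-onset events; the behavioural estimate
    uses keypresses delayed by ``electromech_ms`` past the threshold
    crossing.  The gap is driven by ``ballistic_ms + electromech_ms``.

    The per-SSD average is restricted to levels with P(EMG-respond) inside
    ``p_range``: extreme-probability levels carry the largest quantile bias,
    and which levels the staircase populates shifts with the ballistic
    duration, so a fixed stable band keeps the sweep comparable across
    durations.
    """
    from .synth import SimConfig, simulate_task
    from .ssrt import ssrt_beh, ssrt_emg
    cfg = SimConfig(n_trials=n_trials, race=race, ballistic_ms=ballistic_ms,
                    electromech_ms=electromech_ms, conduction_ms=conduction_ms,
                    seed=seed)
    trials, truth = simulate_task(cfg)
    n_stop = int((trials["type"] == "stop").sum())
    trials = trials.copy()
    trials["rt_emg_ms"] = truth["emg_onset_ms"]
    beh = ssrt_beh(trials)
    emg, _ = ssrt_emg(trials, min_trials_per_ssd=min_trials_per_ssd,
                      p_range=p_range)
    cancel = truth.loc[truth["partial"], "muscle_cancel_ms"]
    return {
        "ssrt_beh_ms": beh,
        "ssrt_emg_ms": emg,
        "gap_ms": None if beh is None or emg is None else beh - emg,
        "mean_canceltime_ms": float(cancel.mean()) if len(cancel) else np.nan,
        "n_stop_trials": n_stop,
        "flagged_low_n": n_stop < 200,
    }


def sweep_ballistic(race: RaceParams, ballistic_grid, target_gap_ms: float,
                    n_trials: int = 40_000, seed: int = 0, **kwargs) -> tuple:
    """Sweep the ballistic-stage duration and report the smallest value whose
    predicted keypress-minus-EMG SSRT gap reaches ``target_gap_ms``.

    Common random numbers (one seed for every grid point) keep the gap curve
    monotone in the ballistic duration up to estimator noise.
    Returns (minimal duration or None, DataFrame of the sweep).
    """
    rows = []
    minimal = None
    for b in ballistic_grid:
        res = simulate_ballistic(race, float(b), n_trials=n_trials,
                                 seed=seed, **kwargs)
        res["ballistic_ms"] = float(b)
        rows.append(res)
        if minimal is None and res["gap_ms"] is not None and res["gap_ms"] >= target_gap_ms:
            minimal = float(b)
    return minimal, pd.DataFrame(rows)
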