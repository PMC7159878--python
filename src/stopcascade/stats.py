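"""Bespoke inference: the permutation test linking frontal beta BurstTime to
muscle CancelTime across participants, plus thin correlation utilities.

The null hypothesis is that each participant's mean BurstTime is an artifact
of their analysis window: per iteration, every observed burst is replaced by
a uniform draw on (0, SSRT_Beh) for that participant, the per-participant
draws are averaged, and the cross-participant correlation with the (fixed)
mean CancelTimes is recomputed.  p = (1 + #{r_perm >= r_obs}) / (1 + n_iter)
(add-one convention, so p is never exactly 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, spearmanr, rankdata


def correlate(x, y, method: str = "pearson"):
    """Correlation coefficient, or None for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def _row_pearson(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``rows`` against ``y`` (vectorised)."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rc @ yc) / denom


@dataclass
class PermResult:
    r_obs: float
    p: float
    n_iter: int
    seed: int
    statistic: str
    r_null: np.ndarray


def permutation_corr_test(mean_canceltimes, mean_bursttimes, ssrt_beh,
                          burst_counts=None, n_iter: int = 3000, seed: int = 0,
                          statistic: str = "pearson",
                          mode: str = "per_burst") -> PermResult:
    """Permutation test of the BurstTime-CancelTime correlation.

    Parameters are per-participant vectors.  ``mode='per_burst'`` draws one
    uniform BurstTime per observed burst and averages within participant
    (preserving each participant's averaging noise); ``'per_participant'``
    draws a single BurstTime per participant per iteration.
    """
    c = np.asarray(mean_canceltimes, dtype=float)
    b = np.asarray(mean_bursttimes, dtype=float)
    s = np.asarray(ssrt_beh, dtype=float)
    n = c.size
    if n < 4:
        raise ValueError("need at least 4 participants")
    if np.any(s <= 0):
        raise ValueError("SSRT_Beh must be positive for every participant")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    counts = np.ones(n, dtype=int) if (burst_counts is None or mode == "per_participant") \
        else np.asarray(burst_counts, dtype=int)
    if np.any(counts < 1):
        raise ValueError("burst counts must be >= 1")

    r_obs = correlate(b, c, statistic)
    if r_obs is None:
        raise ValueError("zero variance in the observed data")

    rng = np.random.default_rng(seed)
    null_means = np.empty((n_iter, n))
    for i in range(n):
        null_means[:, i] = s[i] * rng.random((n_iter, counts[i])).mean(axis=1)
    if statistic == "pearson":
        r_null = _row_pearson(null_means, c)
    else:
        ranks = rankdata(null_means, axis=1)
        r_null = _row_pearson(ranks, rankdata(c))
    p = (1.0 + np.sum(r_null >= r_obs)) / (1.0 + n_iter)
    return PermResult(r_obs=float(r_obs), p=float(p), n_iter=n_iter, seed=seed,
                      statistic=statistic, r_null=r_null)
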