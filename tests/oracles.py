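"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's own code paths and the libraries that
back them: plain-Python tabulations and exhaustive enumerations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def logrank_oracle(time, event, group):
    """Two-group log-rank by direct O-E/V tabulation over distinct event times.

    ``group`` is boolean membership of group A.  Returns (chi2, p).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    observed = expected = variance = 0.0
    for t in sorted(set(time[event])):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & group).sum()
        d = (event & (time == t)).sum()
        d_a = (event & (time == t) & group).sum()
        observed += d_a
        expected += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0, 1.0
    chi2 = (observed - expected) ** 2 / variance
    return chi2, chi2_sf(chi2)


def chi2_sf(x: float) -> float:
    """Upper tail of chi-square with 1 df via the complementary error function."""
    return math.erfc(math.sqrt(x / 2.0))


def auc_oracle(scores, labels):
    """Mann-Whitney AUC by explicit pairwise comparison, ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def km_oracle(time, event):
    """Product-limit estimator by direct looping; returns {event_time: S(t)}."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    surv = 1.0
    out = {}
    for t in sorted(set(time[event])):
        n = (time >= t).sum()
        d = (event & (time == t)).sum()
        surv *= 1.0 - d / n
        out[t] = surv
    return out


def best_single_oracle(values, time, event, candidates, min_group_size):
    """Exhaustive single-threshold scan; returns (threshold, p)."""
    best = None
    for t in sorted(candidates):
        high = np.asarray(values) >= t
        if high.sum() < min_group_size or (~high).sum() < min_group_size:
            continue
        _, p = logrank_oracle(time, event, high)
        if best is None or p < best[1]:
            best = (t, p)
    return best


def best_pair_oracle(values1, values2, time, event, cand1, cand2, min_group_size):
    """Exhaustive (threshold pair x quadrant) scan; returns (t1, t2, quadrant, p)."""
    v1, v2 = np.asarray(values1), np.asarray(values2)
    n = len(v1)
    best = None
    for t1 in sorted(cand1):
        for t2 in sorted(cand2):
            h1, h2 = v1 >= t1, v2 >= t2
            for q, mask in (
                ("Q1", h1 & ~h2),
                ("Q2", h1 & h2),
                ("Q3", ~h1 & ~h2),
                ("Q4", ~h1 & h2),
            ):
                if mask.sum() < min_group_size or n - mask.sum() < min_group_size:
                    continue
                _, p = logrank_oracle(time, event, mask)
                if best is None or p < best[3]:
                    best = (t1, t2, q, p)
    return best


def ranksum_exact_oracle(x, y):
    """Exact two-sided rank-sum p-value by enumerating all group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = _midranks(pooled)
    observed = ranks[:n].sum()
    mean = n * (n + m + 1) / 2.0
    dev = abs(observed - mean)
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= dev - 1e-9:
            count += 1
    return count / total


def _midranks(values):
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def permutation_logrank_p(time, event, group, n_perm, seed):
    """Monte-Carlo permutation p-value of the log-rank statistic."""
    rng = np.random.default_rng(seed)
    stat_obs, _ = logrank_oracle(time, event, group)
    group = np.asarray(group, bool)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        stat, _ = logrank_oracle(time, event, perm)
        if stat >= stat_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
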