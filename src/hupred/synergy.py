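"""Maximally selected log-rank cutpoints, biomarker-pair synergy, quadrants.

This is the analytical core of the package: single- and two-variable threshold
scans over time-to-resistance data, the synergy score

    S_ab = (P_a * P_b) / P_ab

where ``P_a`` and ``P_b`` are the most significant (smallest) log-rank p-values
attainable by dichotomizing variables a and b on a candidate threshold grid,
and ``P_ab`` is the most significant p-value attainable by any threshold pair
combined with any of the four quadrants it induces (quadrant vs. rest,
two-group log-rank).  ``S_ab`` near 1 indicates the pair behaves like two
independent effects; ``S_ab >> 1`` flags super-multiplicative (synergistic)
significance.  Quadrant enrichment compares resistant prevalence inside each
quadrant with the cohort prevalence.

Grid convention: candidate thresholds are unique observed values clipped to a
quantile band (default 10th-90th percentile), "high" means value >= threshold,
and each side of a split must contain ``min_group_size`` patients.  Scans are
exhaustive over the grid; a vectorized O-E/V tabulation evaluates thousands of
candidate groupings in one pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy.stats import chi2 as _chi2

__all__ = [
    "SurvivalData",
    "GridRule",
    "SplitResult",
    "PairSplit",
    "PairSynergyResult",
    "NoValidSplitError",
    "logrank_test",
    "logrank_scan",
    "best_single_split",
    "best_pair_split",
    "synergy_score",
    "quadrant_enrichment",
    "compute_pair_synergy",
    "rank_pairs",
    "QUADRANTS",
]

#: Quadrant labels in tie-break priority order.  Q1 = var1 high & var2 low,
#: Q2 = both high, Q3 = both low, Q4 = var1 low & var2 high.
QUADRANTS: tuple[str, ...] = ("Q1", "Q2", "Q3", "Q4")


class NoValidSplitError(ValueError):
    """Raised when no candidate threshold yields two admissible groups."""


@dataclass(frozen=True)
class SurvivalData:
    """Per-patient time to resistance event (days) and event indicator."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=bool)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if len(time) and time.min() <= 0:
            raise ValueError("survival times must be > 0")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, mask: np.ndarray) -> "SurvivalData":
        return SurvivalData(self.time[mask], self.event[mask])


@dataclass(frozen=True)
class GridRule:
    """Candidate-threshold rule for maximally selected splits."""

    lower_quantile: float = 0.10
    upper_quantile: float = 0.90
    min_group_size: int = 10
    max_candidates: int | None = None
    candidates: tuple[float, ...] | None = None  # explicit override

    def candidate_thresholds(self, values: np.ndarray) -> np.ndarray:
        if self.candidates is not None:
            return np.unique(np.asarray(self.candidates, dtype=float))
        uniq = np.unique(values)
        lo, hi = np.quantile(values, [self.lower_quantile, self.upper_quantile])
        cand = uniq[(uniq >= lo) & (uniq <= hi)]
        if self.max_candidates is not None and cand.size > self.max_candidates:
            idx = np.unique(
                np.round(np.linspace(0, cand.size - 1, self.max_candidates)).astype(int)
            )
            cand = cand[idx]
        return cand


@dataclass(frozen=True)
class SplitResult:
    """Best single-variable threshold split."""

    variable: str
    threshold: float
    p_value: float
    statistic: float
    group_sizes: tuple[int, int]  # (above/high, below/low)


@dataclass(frozen=True)
class PairSplit:
    """Best threshold pair and quadrant for a variable pair."""

    threshold1: float
    threshold2: float
    quadrant: str
    p_value: float
    statistic: float
    group_sizes: tuple[int, int]  # (quadrant, rest)


@dataclass(frozen=True)
class PairSynergyResult:
    """Single-split, pairwise-split, synergy and enrichment for one pair."""

    var1: str
    var2: str
    p1: float
    p2: float
    p12: float
    expected_p: float
    synergy: float
    t1: float
    t2: float
    quadrant: str
    quadrant_enrichment: dict[str, float]
    quadrant_counts: dict[str, tuple[int, int]]  # (n, n_resistant)

    def to_row(self) -> dict:
        row = {
            "var1": self.var1,
            "var2": self.var2,
            "p1": self.p1,
            "p2": self.p2,
            "expected_p": self.expected_p,
            "p12": self.p12,
            "synergy": self.synergy,
            "t1": self.t1,
            "t2": self.t2,
            "quadrant": self.quadrant,
        }
        for q in QUADRANTS:
            row[f"enrichment_{q}"] = self.quadrant_enrichment[q]
        return row


# ---------------------------------------------------------------------------
# Log-rank machinery


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Symmetric in group order; requires both groups non-empty and at least one
    event overall.
    """
    time_a, time_b = np.asarray(time_a, float), np.asarray(time_b, float)
    event_a, event_b = np.asarray(event_a, bool), np.asarray(event_b, bool)
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (event_a.any() or event_b.any()):
        raise ValueError("log-rank test requires at least one event")
    res = _lifelines_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def logrank_scan(
    time: np.ndarray,
    event: np.ndarray,
    membership: np.ndarray,
    block_size: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group log-rank over many candidate groupings.

    ``membership`` is (n_patients, n_groupings) boolean; column g defines
    group A of grouping g (the rest form group B).  Returns per-grouping
    (chi2, p).  Groupings with zero log-rank variance (e.g. one empty group)
    get statistic 0 and p 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    membership = np.asarray(membership, dtype=bool)
    n, n_groupings = membership.shape
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    n_at_risk = (n - starts).astype(float)
    d = np.add.reduceat(e, starts)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_base = np.where(n_at_risk > 1, d * (n_at_risk - d) / (n_at_risk - 1), 0.0)

    chi = np.empty(n_groupings)
    pvals = np.empty(n_groupings)
    for lo in range(0, n_groupings, block_size):
        m = membership[order, lo : lo + block_size].astype(np.float64)
        suffix = np.cumsum(m[::-1], axis=0)[::-1]
        n_a = suffix[starts]  # at risk in group A per tie-time
        d_a = np.add.reduceat(m * e[:, None], starts, axis=0)
        frac = n_a / n_at_risk[:, None]
        observed = d_a.sum(axis=0)
        expected = (d[:, None] * frac).sum(axis=0)
        variance = (var_base[:, None] * frac * (1.0 - frac)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(variance > 0, (observed - expected) ** 2 / variance, 0.0)
        chi[lo : lo + m.shape[1]] = stat
        pvals[lo : lo + m.shape[1]] = np.where(variance > 0, _chi2.sf(stat, 1), 1.0)
    return chi, pvals


# ---------------------------------------------------------------------------
# Threshold scans


def best_single_split(
    values: np.ndarray,
    survival: SurvivalData,
    grid_rule: GridRule = GridRule(),
    variable: str = "",
) -> SplitResult:
    """Most significant single-threshold split (high = value >= threshold).

    Evaluates the log-rank test at every admissible candidate threshold and
    returns the one minimizing the p-value; ties break toward the smaller
    threshold.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(survival):
        raise ValueError("values and survival must have equal length")
    if np.unique(values).size < 2:
        raise NoValidSplitError(f"variable {variable or '<unnamed>'} is constant")
    cand = grid_rule.candidate_thresholds(values)
    n = len(values)
    n_high = (values[:, None] >= cand[None, :]).sum(axis=0)
    ok = (n_high >= grid_rule.min_group_size) & (n - n_high >= grid_rule.min_group_size)
    cand = cand[ok]
    if cand.size == 0:
        raise NoValidSplitError(
            f"no admissible threshold for variable {variable or '<unnamed>'} "
            f"(min_group_size={grid_rule.min_group_size})"
        )
    membership = values[:, None] >= cand[None, :]
    chi, pvals = logrank_scan(survival.time, survival.event, membership)
    best = int(np.argmin(pvals))  # first minimum = smallest threshold (cand sorted)
    n_hi = int(membership[:, best].sum())
    return SplitResult(
        variable=variable,
        threshold=float(cand[best]),
        p_value=float(pvals[best]),
        statistic=float(chi[best]),
        group_sizes=(n_hi, n - n_hi),
    )


def _pair_candidates(values: np.ndarray, grid_rule: GridRule) -> np.ndarray:
    """Candidates for one axis of the pair scan.

    A variable constant within the grid degenerates to a single all-high
    threshold so the scan reduces to the other variable's single split.
    """
    cand = grid_rule.candidate_thresholds(values)
    if cand.size == 0:
        cand = np.array([float(np.min(values))])
    return cand


def best_pair_split(
    values1: np.ndarray,
    values2: np.ndarray,
    survival: SurvivalData,
    grid_rule: GridRule = GridRule(max_candidates=20),
) -> PairSplit:
    """Most significant quadrant-vs-rest split over the 2-D threshold grid.

    For each threshold pair the four quadrants are formed ("high" = value >=
    threshold); every quadrant with at least ``min_group_size`` patients on
    both sides is tested against the rest with a two-group log-rank test.
    The minimum p-value wins; ties break deterministically toward the smaller
    threshold1, then threshold2, then quadrant order Q1 < Q2 < Q3 < Q4.
    """
    values1 = np.asarray(values1, dtype=float)
    values2 = np.asarray(values2, dtype=float)
    n = len(values1)
    if len(values2) != n or len(survival) != n:
        raise ValueError("values and survival must have equal length")
    cand1 = _pair_candidates(values1, grid_rule)
    cand2 = _pair_candidates(values2, grid_rule)
    hi1 = values1[:, None] >= cand1[None, :]  # (n, G1)
    hi2 = values2[:, None] >= cand2[None, :]  # (n, G2)
    g1, g2 = cand1.size, cand2.size

    # columns ordered (t1, t2, quadrant) lexicographically for tie-breaking
    quadrant_masks = []
    for i in range(g1):
        h1 = hi1[:, i : i + 1]
        for j in range(g2):
            h2 = hi2[:, j : j + 1]
            quadrant_masks.append(np.hstack([h1 & ~h2, h1 & h2, ~h1 & ~h2, ~h1 & h2]))
    membership = np.hstack(quadrant_masks)  # (n, G1*G2*4)
    sizes = membership.sum(axis=0)
    valid = (sizes >= grid_rule.min_group_size) & (n - sizes >= grid_rule.min_group_size)
    if not valid.any():
        raise NoValidSplitError("no admissible quadrant split for this pair")
    chi, pvals = logrank_scan(survival.time, survival.event, membership[:, valid])
    full_p = np.full(membership.shape[1], np.inf)
    full_chi = np.zeros(membership.shape[1])
    full_p[valid] = pvals
    full_chi[valid] = chi
    best = int(np.argmin(full_p))  # first minimum respects the tie-break order
    i, rem = divmod(best, g2 * 4)
    j, q = divmod(rem, 4)
    quadrant = ("Q1", "Q2", "Q3", "Q4")[q]
    n_q = int(sizes[best])
    return PairSplit(
        threshold1=float(cand1[i]),
        threshold2=float(cand2[j]),
        quadrant=quadrant,
        p_value=float(full_p[best]),
        statistic=float(full_chi[best]),
        group_sizes=(n_q, n - n_q),
    )


# ---------------------------------------------------------------------------
# Synergy and enrichment


def synergy_score(p1: float, p2: float, p12: float) -> float:
    """Synergy S = (p1 * p2) / p12 of a variable pair.

    All inputs must be p-values in (0, 1]; values > 1 indicate
    super-multiplicative (synergistic) combined significance.
    """
    for name, p in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {p}")
    return (p1 * p2) / p12


def quadrant_enrichment(
    values1: np.ndarray,
    values2: np.ndarray,
    t1: float,
    t2: float,
    resistant: np.ndarray,
) -> tuple[dict[str, float], dict[str, tuple[int, int]]]:
    """Resistant-patient enrichment of the four threshold quadrants.

    enrichment(Q) = (resistant_Q / n_Q) / (resistant_total / n_total); NaN for
    empty quadrants.  "High" means value >= threshold.
    """
    values1 = np.asarray(values1, dtype=float)
    values2 = np.asarray(values2, dtype=float)
    resistant = np.asarray(resistant, dtype=bool)
    total = resistant.sum()
    if total == 0:
        raise ValueError("cohort has no resistant patients (prevalence zero)")
    prevalence = total / len(resistant)
    h1, h2 = values1 >= t1, values2 >= t2
    masks = {"Q1": h1 & ~h2, "Q2": h1 & h2, "Q3": ~h1 & ~h2, "Q4": ~h1 & h2}
    enrich: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    for q, mask in masks.items():
        n_q = int(mask.sum())
        r_q = int((mask & resistant).sum())
        counts[q] = (n_q, r_q)
        enrich[q] = (r_q / n_q) / prevalence if n_q else float("nan")
    return enrich, counts


def compute_pair_synergy(
    var1: str,
    var2: str,
    values1: np.ndarray,
    values2: np.ndarray,
    survival: SurvivalData,
    grid_rule: GridRule = GridRule(),
    pair_grid_rule: GridRule | None = None,
) -> PairSynergyResult:
    """Full synergy analysis of one variable pair."""
    if pair_grid_rule is None:
        pair_grid_rule = replace(grid_rule, max_candidates=20)
    s1 = best_single_split(values1, survival, grid_rule, variable=var1)
    s2 = best_single_split(values2, survival, grid_rule, variable=var2)
    pair = best_pair_split(values1, values2, survival, pair_grid_rule)
    expected = s1.p_value * s2.p_value
    synergy = synergy_score(s1.p_value, s2.p_value, pair.p_value)
    enrich, counts = quadrant_enrichment(
        values1, values2, pair.threshold1, pair.threshold2, survival.event
    )
    return PairSynergyResult(
        var1=var1,
        var2=var2,
        p1=s1.p_value,
        p2=s2.p_value,
        p12=pair.p_value,
        expected_p=expected,
        synergy=synergy,
        t1=pair.threshold1,
        t2=pair.threshold2,
        quadrant=pair.quadrant,
        quadrant_enrichment=enrich,
        quadrant_counts=counts,
    )


def rank_pairs(
    features: pd.DataFrame,
    survival: SurvivalData,
    feature_names: list[str] | None = None,
    grid_rule: GridRule = GridRule(),
    pair_grid_rule: GridRule | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synergy analysis of all C(k, 2) pairs of the given features.

    Rows with a missing value in any selected feature are dropped
    (complete-case).  Returns (pairs table sorted by synergy descending,
    association table sorted by combined p-value ascending).
    """
    if feature_names is None:
        feature_names = list(features.columns)
    if len(feature_names) < 2:
        raise ValueError("need at least 2 features to rank pairs")
    sub = features[feature_names]
    complete = ~sub.isna().any(axis=1).to_numpy()
    sub = sub.loc[complete]
    surv = survival.subset(complete)

    singles = {
        name: best_single_split(sub[name].to_numpy(), surv, grid_rule, variable=name)
        for name in feature_names
    }
    rows = []
    for var1, var2 in itertools.combinations(feature_names, 2):
        if pair_grid_rule is None:
            pgr = replace(grid_rule, max_candidates=20)
        else:
            pgr = pair_grid_rule
        pair = best_pair_split(sub[var1].to_numpy(), sub[var2].to_numpy(), surv, pgr)
        p1, p2 = singles[var1].p_value, singles[var2].p_value
        enrich, counts = quadrant_enrichment(
            sub[var1].to_numpy(), sub[var2].to_numpy(), pair.threshold1, pair.threshold2, surv.event
        )
        rows.append(
            PairSynergyResult(
                var1=var1,
                var2=var2,
                p1=p1,
                p2=p2,
                p12=pair.p_value,
                expected_p=p1 * p2,
                synergy=synergy_score(p1, p2, pair.p_value),
                t1=pair.threshold1,
                t2=pair.threshold2,
                quadrant=pair.quadrant,
                quadrant_enrichment=enrich,
                quadrant_counts=counts,
            ).to_row()
        )
    pairs = pd.DataFrame(rows).sort_values("synergy", ascending=False).reset_index(drop=True)
    associations = (
        pairs[["var1", "var2", "p12", "t1", "t2", "quadrant"]]
        .sort_values("p12", ascending=True)
        .reset_index(drop=True)
    )
    return pairs, associations
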