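"""Kaplan-Meier stratification, the RDW/HGB risk rule, group comparisons, precision.

The two-threshold risk rule classifies patients by red cell distribution width
(RDW, default cutoff 17%) and hemoglobin (HGB, default cutoff 15.5 g/dL):
high-RDW/low-HGB patients (Q1) carry the highest resistance risk, low-RDW/
low-HGB patients (Q3) the lowest, and the remaining quadrants are
intermediate.  Values at the threshold count as "high".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .synergy import SurvivalData

__all__ = [
    "SurvivalCurve",
    "RiskRule",
    "km_curve",
    "classify_quadrant",
    "compare_groups",
    "ci_halfwidth",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: times, survival probabilities, at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


@dataclass(frozen=True)
class RiskRule:
    """Two-threshold RDW/HGB decision rule (fixed, not a fitted tree)."""

    rdw_threshold: float = 17.0
    hgb_threshold: float = 15.5

    def validate(self) -> None:
        if self.rdw_threshold <= 0 or self.hgb_threshold <= 0:
            raise ValueError("thresholds must be > 0")


#: Quadrant -> risk class of the RDW/HGB rule.
RISK_CLASSES = {"Q1": "high", "Q2": "intermediate", "Q4": "intermediate", "Q3": "low"}


def km_curve(survival: SurvivalData) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator of resistance-free survival.

    Censored-only data yields the constant curve 1; with events at distinct
    days and no censoring the curve equals 1 minus the empirical CDF.
    """
    if len(survival) == 0:
        raise ValueError("survival data must be non-empty")
    kmf = KaplanMeierFitter()
    kmf.fit(survival.time, event_observed=survival.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    at_risk[np.isnan(at_risk)] = len(survival)
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk)


def classify_quadrant(rdw: float, hgb: float, rule: RiskRule = RiskRule()) -> tuple[str, str]:
    """Map an (RDW %, HGB g/dL) pair to its quadrant and risk class.

    Q1 = high RDW & low HGB (highest risk), Q3 = low RDW & low HGB (lowest),
    Q2/Q4 intermediate; a value equal to its threshold counts as high.
    """
    rule.validate()
    if not (np.isfinite(rdw) and np.isfinite(hgb)) or rdw <= 0 or hgb <= 0:
        raise ValueError("rdw and hgb must be finite and positive")
    high_rdw = rdw >= rule.rdw_threshold
    high_hgb = hgb >= rule.hgb_threshold
    quadrant = {(True, False): "Q1", (True, True): "Q2", (False, False): "Q3", (False, True): "Q4"}[
        (high_rdw, high_hgb)
    ]
    return quadrant, RISK_CLASSES[quadrant]


def compare_groups(
    cohort: pd.DataFrame,
    grouping_variable: str,
    threshold: float,
    lab_variables: list[str] | None = None,
    label_column: str = "resistant",
) -> tuple[pd.DataFrame, dict]:
    """High-vs-low group comparison at a threshold (high = value >= threshold).

    Per lab variable: group medians and a two-sided Mann-Whitney rank-sum p;
    plus the high/low resistance-proportion ratio with a two-proportion z-test.
    """
    values = cohort[grouping_variable].to_numpy(dtype=float)
    high = values >= threshold
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("both groups must be non-empty at this threshold")
    if lab_variables is None:
        lab_variables = [
            c
            for c in cohort.columns
            if c not in (grouping_variable, label_column, "patient_id")
            and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    rows = []
    for var in lab_variables:
        x = cohort.loc[high, var].dropna().to_numpy(dtype=float)
        y = cohort.loc[~high, var].dropna().to_numpy(dtype=float)
        if len(x) and len(y):
            if np.array_equal(np.sort(x), np.sort(y)):
                p = 1.0  # identical samples: no evidence of a shift
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "variable": var,
                "median_high": float(np.median(x)) if len(x) else float("nan"),
                "median_low": float(np.median(y)) if len(y) else float("nan"),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).set_index("variable")

    labels = cohort[label_column].to_numpy(dtype=bool)
    n_high, n_low = int(high.sum()), int((~high).sum())
    r_high, r_low = int(labels[high].sum()), int(labels[~high].sum())
    prop_high = r_high / n_high
    prop_low = r_low / n_low
    if r_high == r_low and n_high == n_low:
        p_prop = 1.0
    else:
        stat, p_prop = proportions_ztest([r_high, r_low], [n_high, n_low])
        p_prop = float(p_prop)
    summary = {
        "n_high": n_high,
        "n_low": n_low,
        "prop_high": prop_high,
        "prop_low": prop_low,
        "ratio": prop_high / prop_low if prop_low > 0 else float("inf"),
        "p_value": p_prop,
    }
    return table, summary


def ci_halfwidth(p: float, n: int, level: float = 0.95) -> float:
    """Normal-approximation half-width of a proportion's confidence interval.

    z_{1-(1-level)/2} * sqrt(p (1 - p) / n); used for trial sample-size
    precision statements (e.g. p=0.80, n=120, 95% -> +/-0.072).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return float(z * np.sqrt(p * (1.0 - p) / n))
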