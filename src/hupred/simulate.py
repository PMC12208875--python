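"""Synthetic EHR-like polycythemia vera cohorts with a plantable resistance signal.

The generator emulates a cohort of PV patients starting first-line hydroxyurea
(HU): one row of pre-index demographics and laboratory values per patient, plus
a longitudinal event timeline (prescriptions, phlebotomies, serial labs,
diagnoses) anchored at the index date (day 0 = first HU prescription).

Generative model
----------------
Patients belong to one of two latent outcome groups, HU-resistant (RES) or
non-resistant (NON), mixed with probability ``resistant_fraction``.  Each
continuous variable has group-specific marginal distributions: truncated
normals whose *post-truncation* mean/SD are matched to the configured group
moments, except the annualized phlebotomy count, which uses a gamma marginal
(its configured coefficient of variation exceeds what a zero-truncated normal
can express).  Cross-variable correlation is induced by a Gaussian copula with
a one-factor ("myeloproliferation") correlation structure shared by both
groups, so WBC/ANC/RBC/RDW and friends co-vary.

The resistance outcome is then assigned by Bernoulli sampling from

    P(resistant | x) = logistic( baseline_logit
                                 + separation_scale * log LR(x)
                                 + interaction_effect * 1[RDW >= r, HGB < h] )

where ``log LR`` is the exact log likelihood ratio of the two group densities
(copula included).  With the default ``baseline_logit = logit(resistant
fraction)``, ``separation_scale = 1`` and ``interaction_effect = 0`` this is
the exact Bayes posterior of group membership, so per-group sample moments
recover the configured moments in expectation.  A positive
``interaction_effect`` plants additional resistance risk in the
high-RDW/low-HGB quadrant on the log-odds scale, creating the synergistic
biomarker-pair structure the downstream threshold scan is designed to detect.

Timelines encode the assigned outcome so that window-based labeling can be
validated against the returned ground-truth flags: resistant patients receive
one qualifying trigger (phlebotomy, uncontrolled HCT, or same-day
leukocytosis + thrombocytosis) inside the 6-9 month post-index window, while
non-resistant timelines are kept clean of qualifying events throughout the
tolerance-extended window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cholesky, solve_triangular
from scipy.special import expit, logit, ndtr, ndtri

__all__ = [
    "GeneratorConfig",
    "GeneratorConfigError",
    "CohortIOError",
    "generate_cohort",
    "resistance_probability",
    "resistance_probabilities",
    "write_cohort",
    "read_cohort",
    "LAB_ANALYTES",
    "CONTINUOUS_VARIABLES",
    "EVENT_KINDS",
    "PATIENT_COLUMNS",
    "EVENT_COLUMNS",
]

#: Continuous per-patient variables drawn by the generator, in a fixed order.
CONTINUOUS_VARIABLES: tuple[str, ...] = (
    "age_at_index",
    "weight",
    "time_dx_to_tx",
    "annualized_phlebotomy_count",
    "RBC",
    "HCT",
    "HGB",
    "RDW",
    "WBC",
    "ANC",
    "lymphocytes",
    "PLT",
)

#: Analytes written as serial ``lab`` events on the timeline.
LAB_ANALYTES: tuple[str, ...] = (
    "RBC", "HCT", "HGB", "RDW", "WBC", "ANC", "lymphocytes", "PLT",
)

EVENT_KINDS: frozenset[str] = frozenset(
    {
        "hu_prescription",
        "rux_prescription",
        "other_cytoreductive",
        "phlebotomy",
        "lab",
        "pv_diagnosis",
        "mf_diagnosis",
        "et_diagnosis",
        "te_event",
    }
)

PATIENT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "gender",
    "age_at_index",
    "te_history",
    "weight",
    "time_dx_to_tx",
    "annualized_phlebotomy_count",
    "RBC",
    "HCT",
    "HGB",
    "RDW",
    "WBC",
    "ANC",
    "lymphocytes",
    "PLT",
    "NLR",
)

EVENT_COLUMNS: tuple[str, ...] = ("patient_id", "day_offset", "kind", "analyte", "value")

# Group moments as {variable: ((mean_res, sd_res), (mean_non, sd_non))}.
# Moments for RBC, PLT, lymphocytes, weight and time-from-diagnosis-to-treatment
# are synthetic defaults (no group-level reference values exist for them); they
# are flagged as such in docs/methods.md.
DEFAULT_GROUP_MOMENTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "age_at_index": ((68.4, 11.2), (71.2, 10.8)),
    "annualized_phlebotomy_count": ((0.74, 1.44), (0.28, 0.77)),
    "ANC": ((9.58, 6.00), (8.36, 5.58)),
    "HCT": ((49.0, 7.40), (47.2, 7.37)),
    "HGB": ((15.6, 2.61), (15.4, 2.49)),
    "RDW": ((18.1, 3.22), (17.1, 3.05)),
    "WBC": ((13.1, 9.02), (11.1, 6.36)),
    "RBC": ((5.5, 0.95), (5.3, 0.90)),
    "PLT": ((465.0, 185.0), (430.0, 170.0)),
    "lymphocytes": ((1.55, 0.55), (1.65, 0.60)),
    "weight": ((86.0, 19.0), (84.0, 18.0)),
    "time_dx_to_tx": ((420.0, 300.0), (360.0, 280.0)),
}

#: Binary covariates as {name: (P(res group), P(non group))}.
DEFAULT_BINARY_RATES: dict[str, tuple[float, float]] = {
    "female": (0.419, 0.574),
    "te_history": (0.146, 0.163),
}

#: One-factor copula loadings; variables not listed load 0 on the factor.
DEFAULT_FACTOR_LOADINGS: dict[str, float] = {
    "WBC": 0.65,
    "ANC": 0.65,
    "RBC": 0.45,
    "HCT": 0.40,
    "RDW": 0.35,
    "PLT": 0.35,
    "annualized_phlebotomy_count": 0.30,
    "HGB": 0.15,
    "lymphocytes": -0.15,
}

#: Support bounds for the truncated-normal marginals.
VARIABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "age_at_index": (18.0, 105.0),
    "weight": (30.0, math.inf),
    "time_dx_to_tx": (1.0, math.inf),
    "annualized_phlebotomy_count": (0.0, math.inf),
    "RBC": (0.0, math.inf),
    "HCT": (0.0, 100.0),
    "HGB": (0.0, math.inf),
    "RDW": (0.0, math.inf),
    "WBC": (0.0, math.inf),
    "ANC": (0.0, math.inf),
    "lymphocytes": (0.05, math.inf),
    "PLT": (0.0, math.inf),
}

#: Variables whose marginal is a gamma distribution instead of a truncated normal.
GAMMA_VARIABLES: frozenset[str] = frozenset({"annualized_phlebotomy_count"})

_TABLE1_RESISTANT = 733
_TABLE1_TOTAL = 1304


class GeneratorConfigError(ValueError):
    """Raised when a GeneratorConfig field violates its invariants."""


class CohortIOError(ValueError):
    """Raised when cohort CSV files fail schema validation."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_patients:
        Number of funnel-eligible patients to generate.
    resistant_fraction:
        Mixture weight of the resistant group (default 733/1304).
    group_moments:
        Per-variable ``((mean, sd) resistant, (mean, sd) non-resistant)``.
    binary_rates:
        Per-binary-covariate ``(P(res), P(non))``.
    factor_loadings:
        Copula loadings on the latent myeloproliferation factor, in [-1, 1].
    interaction_effect:
        Planted log-odds increment for records in the high-RDW/low-HGB
        quadrant.  0 (default) disables the planted interaction.
    interaction_rdw_threshold, interaction_hgb_threshold:
        Quadrant boundaries of the planted effect ("high" means >= threshold).
    baseline_logit:
        Intercept of the outcome model; ``None`` resolves to
        ``logit(resistant_fraction)``.
    separation_scale:
        Multiplier on the group log-likelihood-ratio term; 1 gives the exact
        Bayes posterior, 0 removes all covariate information ("all
        coefficients zero").
    event_window_days:
        Half-open ``[start, end)`` post-index window (days) in which resistant
        patients receive their qualifying trigger event.
    followup_days:
        End of follow-up; censoring day for non-resistant patients.
    pre_index_days:
        Length of the documented pre-index history.
    lab_interval_days:
        Spacing of serial laboratory panels.
    n_ineligible:
        Extra patients appended with one inclusion-criterion violation each
        (minors, single prescription, early ruxolitinib, MF diagnosis, missing
        pre-index labs, other cytoreductives, short history), to exercise the
        inclusion funnel.
    seed:
        Seed for all randomness; identical configs give bit-identical output.
    """

    n_patients: int = _TABLE1_TOTAL
    resistant_fraction: float = _TABLE1_RESISTANT / _TABLE1_TOTAL
    group_moments: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MOMENTS)
    )
    binary_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_RATES)
    )
    factor_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_LOADINGS)
    )
    interaction_effect: float = 0.0
    interaction_rdw_threshold: float = 17.0
    interaction_hgb_threshold: float = 15.5
    baseline_logit: float | None = None
    separation_scale: float = 1.0
    event_window_days: tuple[int, int] = (183, 274)
    followup_days: int = 365
    pre_index_days: int = 183
    lab_interval_days: int = 42
    n_ineligible: int = 0
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients <= 0:
            raise GeneratorConfigError("n_patients must be a positive integer")
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise GeneratorConfigError("resistant_fraction must lie in [0, 1]")
        for var, ((m_r, s_r), (m_n, s_n)) in self.group_moments.items():
            if s_r < 0 or s_n < 0:
                raise GeneratorConfigError(f"group_moments[{var!r}]: sd must be >= 0")
            lo, hi = VARIABLE_BOUNDS.get(var, (-math.inf, math.inf))
            if not (lo < m_r < hi and lo < m_n < hi):
                raise GeneratorConfigError(
                    f"group_moments[{var!r}]: means must lie inside the support ({lo}, {hi})"
                )
        for name, (p_r, p_n) in self.binary_rates.items():
            if not (0.0 <= p_r <= 1.0 and 0.0 <= p_n <= 1.0):
                raise GeneratorConfigError(f"binary_rates[{name!r}] must lie in [0, 1]")
        for name, lam in self.factor_loadings.items():
            if not -1.0 <= lam <= 1.0:
                raise GeneratorConfigError(f"factor_loadings[{name!r}] must lie in [-1, 1]")
        start, end = self.event_window_days
        if not start < end <= self.followup_days:
            raise GeneratorConfigError(
                "event_window_days must satisfy start < end <= followup_days"
            )
        if self.pre_index_days <= 0 or self.lab_interval_days <= 0:
            raise GeneratorConfigError("pre_index_days and lab_interval_days must be > 0")
        if self.n_ineligible < 0:
            raise GeneratorConfigError("n_ineligible must be >= 0")

    @property
    def resolved_baseline_logit(self) -> float:
        if self.baseline_logit is not None:
            return float(self.baseline_logit)
        return float(logit(self.resistant_fraction))

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for v in CONTINUOUS_VARIABLES if v in self.group_moments)


# ---------------------------------------------------------------------------
# Moment-matched marginals


@lru_cache(maxsize=512)
def _matched_truncnorm(mean: float, sd: float, lower: float, upper: float):
    """Truncated normal whose post-truncation mean/SD equal (mean, sd)."""

    def residual(params: np.ndarray) -> list[float]:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residual, x0=np.array([mean, math.log(sd)]), method="hybr")
    if not sol.success or max(abs(r) for r in residual(sol.x)) > 1e-6 * max(sd, 1.0):
        raise GeneratorConfigError(
            f"cannot match a truncated normal to mean={mean}, sd={sd} on ({lower}, {upper})"
        )
    mu, sigma = float(sol.x[0]), math.exp(float(sol.x[1]))
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


@lru_cache(maxsize=128)
def _matched_gamma(mean: float, sd: float):
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return stats.gamma(a=shape, scale=scale)


def _marginals(config: GeneratorConfig) -> dict[str, tuple]:
    """Frozen (resistant, non-resistant) marginal distributions per variable."""
    out: dict[str, tuple] = {}
    for var in config.variables:
        (m_r, s_r), (m_n, s_n) = config.group_moments[var]
        lo, hi = VARIABLE_BOUNDS.get(var, (-math.inf, math.inf))
        if var in GAMMA_VARIABLES:
            out[var] = (_matched_gamma(m_r, s_r), _matched_gamma(m_n, s_n))
        else:
            out[var] = (
                _matched_truncnorm(m_r, s_r, lo, hi),
                _matched_truncnorm(m_n, s_n, lo, hi),
            )
    return out


def _copula_cholesky(config: GeneratorConfig) -> np.ndarray:
    lam = np.array([config.factor_loadings.get(v, 0.0) for v in config.variables])
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return cholesky(corr, lower=True)


# ---------------------------------------------------------------------------
# Outcome model

_U_EPS = 1e-13


def _group_log_density(x: np.ndarray, dists: list, chol: np.ndarray) -> np.ndarray:
    """Joint log density of one group's copula model, row-wise.

    ``log f(x) = log phi_R(z) - sum_v log phi(z_v) + sum_v log f_v(x_v)`` with
    ``z_v = Phi^{-1}(F_v(x_v))``.
    """
    n, p = x.shape
    z = np.empty_like(x)
    log_marg = np.zeros(n)
    for j, dist in enumerate(dists):
        u = np.clip(dist.cdf(x[:, j]), _U_EPS, 1.0 - _U_EPS)
        z[:, j] = ndtri(u)
        with np.errstate(divide="ignore"):
            log_marg += dist.logpdf(x[:, j])
    w = solve_triangular(chol, z.T, lower=True)
    quad = np.einsum("ij,ij->j", w, w)
    log_det = 2.0 * np.sum(np.log(np.diag(chol)))
    # the p/2*log(2*pi) terms of phi_R and sum_v phi cancel
    return -0.5 * quad - 0.5 * log_det + 0.5 * np.einsum("ij,ij->i", z, z) + log_marg


def _posterior_logits(frame: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    marginals = _marginals(config)
    chol = _copula_cholesky(config)
    x = frame[list(config.variables)].to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = [v for v in config.variables if frame[v].isna().any()]
        raise ValueError(f"missing required field(s) for resistance probability: {bad}")
    log_lr = _group_log_density(
        x, [marginals[v][0] for v in config.variables], chol
    ) - _group_log_density(x, [marginals[v][1] for v in config.variables], chol)
    for name, (p_r, p_n) in config.binary_rates.items():
        flag = _binary_column(frame, name)
        log_lr += np.where(
            flag,
            math.log(max(p_r, 1e-12)) - math.log(max(p_n, 1e-12)),
            math.log(max(1 - p_r, 1e-12)) - math.log(max(1 - p_n, 1e-12)),
        )
    eta = config.resolved_baseline_logit + config.separation_scale * log_lr
    if config.interaction_effect != 0.0:
        in_quadrant = (
            frame["RDW"].to_numpy(dtype=float) >= config.interaction_rdw_threshold
        ) & (frame["HGB"].to_numpy(dtype=float) < config.interaction_hgb_threshold)
        eta = eta + config.interaction_effect * in_quadrant
    return eta


def _binary_column(frame: pd.DataFrame, name: str) -> np.ndarray:
    if name == "female":
        if "gender" in frame.columns:
            return frame["gender"].to_numpy() == "female"
        if "female" in frame.columns:
            return frame["female"].to_numpy(dtype=bool)
        raise ValueError("missing required field(s) for resistance probability: ['gender']")
    if name not in frame.columns:
        raise ValueError(f"missing required field(s) for resistance probability: [{name!r}]")
    return frame[name].to_numpy(dtype=bool)


def resistance_probabilities(patients: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Vectorized :func:`resistance_probability` over a patient table."""
    config.validate()
    return expit(_posterior_logits(patients, config))


def resistance_probability(record: Mapping | pd.Series, config: GeneratorConfig) -> float:
    """Probability that a patient record belongs to the resistant group.

    ``record`` must carry every continuous variable in ``config.group_moments``
    plus ``gender`` (or ``female``) and ``te_history``.  With
    ``separation_scale = 0`` and ``interaction_effect = 0`` the result is
    ``logistic(baseline_logit)`` for every record.
    """
    if isinstance(record, pd.Series):
        frame = record.to_frame().T
    else:
        frame = pd.DataFrame([dict(record)])
    missing = [v for v in config.variables if v not in frame.columns]
    if missing:
        raise ValueError(f"missing required field(s) for resistance probability: {missing}")
    return float(resistance_probabilities(frame, config)[0])


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate a synthetic cohort.

    Returns
    -------
    patients:
        One row per patient (:data:`PATIENT_COLUMNS` schema).
    events:
        Long-format timeline (:data:`EVENT_COLUMNS` schema), sorted by
        patient and day offset; day 0 is the index date.
    truth:
        Ground-truth resistance flags, indexed by patient_id.  Stored apart
        from the records so window-based labeling can be validated against it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients + config.n_ineligible
    variables = config.variables
    marginals = _marginals(config)
    chol = _copula_cholesky(config)

    latent_res = rng.random(n) < config.resistant_fraction
    z = rng.standard_normal((n, len(variables))) @ chol.T
    u = ndtr(z)
    x = np.empty_like(u)
    for j, var in enumerate(variables):
        d_res, d_non = marginals[var]
        x[:, j] = np.where(latent_res, d_res.ppf(u[:, j]), d_non.ppf(u[:, j]))

    patients = pd.DataFrame(x, columns=list(variables))
    patients.insert(0, "patient_id", [f"P{i:05d}" for i in range(1, n + 1)])
    for name, (p_r, p_n) in config.binary_rates.items():
        draw = rng.random(n) < np.where(latent_res, p_r, p_n)
        if name == "female":
            patients.insert(1, "gender", np.where(draw, "female", "male"))
        else:
            patients[name] = draw
    patients["NLR"] = patients["ANC"] / patients["lymphocytes"]
    patients = patients.reindex(columns=list(PATIENT_COLUMNS))

    p_res = expit(_posterior_logits(patients, config))
    resistant = rng.random(n) < p_res

    events = _build_timelines(patients, resistant, config, rng)
    if config.n_ineligible:
        patients, events = _plant_ineligible(patients, events, config, rng)

    truth = pd.Series(
        resistant, index=pd.Index(patients["patient_id"], name="patient_id"), name="resistant"
    )
    return patients, events, truth


def _build_timelines(
    patients: pd.DataFrame,
    resistant: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(patients)
    pid = patients["patient_id"].to_numpy()
    frames: list[pd.DataFrame] = []

    def add(ids, days, kind, analyte=None, value=None):
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": ids,
                    "day_offset": np.asarray(days, dtype=np.int64),
                    "kind": kind,
                    "analyte": analyte if analyte is not None else pd.NA,
                    "value": np.nan if value is None else value,
                }
            )
        )

    # diagnoses and treatment anchors
    dx_day = -np.maximum(1, np.round(patients["time_dx_to_tx"].to_numpy()).astype(np.int64))
    add(pid, dx_day, "pv_diagnosis")
    te = patients["te_history"].to_numpy(dtype=bool)
    if te.any():
        add(pid[te], -rng.integers(30, 1000, size=int(te.sum())), "te_event")
    add(pid, np.zeros(n, dtype=np.int64), "hu_prescription")
    add(pid, 90 + rng.integers(0, 14, size=n), "hu_prescription")

    # serial laboratory panels; the most recent pre-index panel carries the
    # exact baseline values so timeline-derived features equal the record.
    lab_days = np.arange(-config.pre_index_days, config.followup_days, config.lab_interval_days)
    lab_days = np.append(lab_days, config.followup_days)
    last_pre = lab_days[lab_days < 0].max()
    baseline = patients[list(LAB_ANALYTES)].to_numpy()
    pooled_sd = np.array(
        [
            0.5 * (config.group_moments[a][0][1] + config.group_moments[a][1][1])
            for a in LAB_ANALYTES
        ]
    )
    values = baseline[:, None, :] + rng.standard_normal(
        (n, len(lab_days), len(LAB_ANALYTES))
    ) * (0.05 * pooled_sd)
    values[:, lab_days == last_pre, :] = baseline[:, None, :]
    post = lab_days > 0
    # post-index disease control: HCT < 45, WBC <= 10, PLT <= 400 for everyone;
    # resistant patients get their qualifying trigger as extra events below.
    idx = {a: k for k, a in enumerate(LAB_ANALYTES)}
    values[:, post, idx["HCT"]] = rng.uniform(38.0, 44.5, size=(n, int(post.sum())))
    values[:, post, idx["WBC"]] = rng.uniform(4.0, 9.8, size=(n, int(post.sum())))
    values[:, post, idx["PLT"]] = rng.uniform(150.0, 395.0, size=(n, int(post.sum())))
    lower = np.array([VARIABLE_BOUNDS[a][0] for a in LAB_ANALYTES])
    upper = np.array([VARIABLE_BOUNDS[a][1] for a in LAB_ANALYTES])
    values = np.clip(values, lower + 1e-3, np.minimum(upper - 1e-3, 1e9))
    add(
        np.repeat(pid, len(lab_days) * len(LAB_ANALYTES)),
        np.tile(np.repeat(lab_days, len(LAB_ANALYTES)), n),
        "lab",
        analyte=np.tile(list(LAB_ANALYTES), n * len(lab_days)),
        value=values.reshape(-1),
    )

    # pre-index phlebotomies: Poisson with the patient's annualized rate
    rate = patients["annualized_phlebotomy_count"].to_numpy()
    k = rng.poisson(rate * config.pre_index_days / 365.0)
    if k.sum():
        add(
            np.repeat(pid, k),
            -rng.integers(1, config.pre_index_days, size=int(k.sum())),
            "phlebotomy",
        )

    # qualifying trigger for resistant patients inside the labeling window
    res_idx = np.flatnonzero(resistant)
    if res_idx.size:
        start, end = config.event_window_days
        day = rng.integers(start + 7, end - 14, size=res_idx.size)
        criterion = rng.choice(3, size=res_idx.size, p=[0.5, 0.3, 0.2])
        a_mask, b_mask, c_mask = (criterion == 0), (criterion == 1), (criterion == 2)
        if a_mask.any():
            add(pid[res_idx[a_mask]], day[a_mask], "phlebotomy")
        if b_mask.any():
            add(
                pid[res_idx[b_mask]],
                day[b_mask],
                "lab",
                analyte="HCT",
                value=rng.uniform(45.5, 53.0, size=int(b_mask.sum())),
            )
        if c_mask.any():
            m = int(c_mask.sum())
            add(pid[res_idx[c_mask]], day[c_mask], "lab", analyte="WBC",
                value=rng.uniform(10.5, 16.0, size=m))
            add(pid[res_idx[c_mask]], day[c_mask], "lab", analyte="PLT",
                value=rng.uniform(410.0, 700.0, size=m))

    events = pd.concat(frames, ignore_index=True)
    events["analyte"] = events["analyte"].astype("string")
    events = events.sort_values(
        ["patient_id", "day_offset", "kind", "analyte"], kind="stable"
    ).reset_index(drop=True)
    return events[list(EVENT_COLUMNS)]


_INELIGIBLE_KINDS = (
    "underage",
    "single_prescription",
    "early_rux",
    "mf_diagnosis",
    "no_pre_index_labs",
    "other_cytoreductive",
    "short_history",
)


def _plant_ineligible(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Give the last ``n_ineligible`` patients one funnel violation each."""
    patients = patients.copy()
    extra_rows: list[dict] = []
    drop = np.zeros(len(events), dtype=bool)
    ids = patients["patient_id"].to_numpy()[config.n_patients:]
    for i, pid in enumerate(ids):
        mode = _INELIGIBLE_KINDS[i % len(_INELIGIBLE_KINDS)]
        mine = events["patient_id"] == pid
        if mode == "underage":
            patients.loc[patients["patient_id"] == pid, "age_at_index"] = 16.0
        elif mode == "single_prescription":
            hu = mine & (events["kind"] == "hu_prescription") & (events["day_offset"] > 0)
            drop |= hu.to_numpy()
        elif mode == "early_rux":
            extra_rows.append(
                {"patient_id": pid, "day_offset": 60, "kind": "rux_prescription",
                 "analyte": pd.NA, "value": np.nan}
            )
        elif mode == "mf_diagnosis":
            extra_rows.append(
                {"patient_id": pid, "day_offset": -30, "kind": "mf_diagnosis",
                 "analyte": pd.NA, "value": np.nan}
            )
        elif mode == "no_pre_index_labs":
            pre_lab = mine & (events["kind"] == "lab") & (events["day_offset"] < 0)
            drop |= pre_lab.to_numpy()
        elif mode == "other_cytoreductive":
            extra_rows.append(
                {"patient_id": pid, "day_offset": 30, "kind": "other_cytoreductive",
                 "analyte": pd.NA, "value": np.nan}
            )
        elif mode == "short_history":
            early = mine & (events["day_offset"] < -60)
            drop |= early.to_numpy()
            # keep a recent PV diagnosis so only the history span fails
            extra_rows.append(
                {"patient_id": pid, "day_offset": -45, "kind": "pv_diagnosis",
                 "analyte": pd.NA, "value": np.nan}
            )
    events = events.loc[~drop]
    if extra_rows:
        extra = pd.DataFrame(extra_rows)
        extra["analyte"] = extra["analyte"].astype("string")
        extra["value"] = extra["value"].astype(float)
        extra["day_offset"] = extra["day_offset"].astype(np.int64)
        events = pd.concat([events, extra], ignore_index=True)
    events["analyte"] = events["analyte"].astype("string")
    events = events.sort_values(
        ["patient_id", "day_offset", "kind", "analyte"], kind="stable"
    ).reset_index(drop=True)
    return patients, events[list(EVENT_COLUMNS)]


# ---------------------------------------------------------------------------
# Cohort persistence (patients.csv / events.csv / truth.csv)


def write_cohort(
    path: str | Path,
    patients: pd.DataFrame,
    events: pd.DataFrame,
    truth: pd.Series | None = None,
) -> dict[str, Path]:
    """Write a cohort to ``patients.csv``/``events.csv`` (and ``truth.csv``)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {}
    out["patients"] = path / "patients.csv"
    patients.to_csv(out["patients"], index=False)
    out["events"] = path / "events.csv"
    events.to_csv(out["events"], index=False)
    if truth is not None:
        out["truth"] = path / "truth.csv"
        truth.rename("resistant").to_csv(out["truth"])
    return out


def read_cohort(
    path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series | None]:
    """Read and validate a cohort directory written by :func:`write_cohort`.

    Raises :class:`CohortIOError` naming the offending file row for unknown
    event kinds, lab events without analyte/value, or unsorted timelines.
    """
    path = Path(path)
    patients = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise CohortIOError(f"patients.csv: missing columns {missing}")
    if len(patients):
        patients = patients.astype({"te_history": bool})
    else:
        patients = pd.DataFrame(columns=list(PATIENT_COLUMNS))

    events = pd.read_csv(
        path / "events.csv",
        dtype={"patient_id": str, "kind": str, "analyte": "string"},
    )
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise CohortIOError(f"events.csv: missing columns {missing}")
    if len(events) == 0:
        events = pd.DataFrame(columns=list(EVENT_COLUMNS))
    else:
        events["day_offset"] = events["day_offset"].astype(np.int64)
        bad_kind = ~events["kind"].isin(EVENT_KINDS)
        if bad_kind.any():
            row = int(np.flatnonzero(bad_kind.to_numpy())[0])
            raise CohortIOError(
                f"events.csv row {row + 2}: unknown event kind {events['kind'].iloc[row]!r}"
            )
        is_lab = events["kind"] == "lab"
        bad_lab = is_lab & (events["analyte"].isna() | events["value"].isna())
        if bad_lab.any():
            row = int(np.flatnonzero(bad_lab.to_numpy())[0])
            raise CohortIOError(f"events.csv row {row + 2}: lab event without analyte/value")
        unsorted = (
            events.groupby("patient_id", sort=False)["day_offset"].diff().to_numpy() < 0
        )
        if unsorted.any():
            row = int(np.flatnonzero(unsorted)[0])
            raise CohortIOError(f"events.csv row {row + 2}: timeline not sorted by day_offset")

    truth_path = path / "truth.csv"
    truth = None
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, dtype={"patient_id": str})
        truth = tdf.set_index("patient_id")["resistant"].astype(bool)
    return patients, events, truth
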