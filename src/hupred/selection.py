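"""Inclusion funnel, resistance labeling, and pre-index feature derivation.

The funnel mirrors a retrospective first-line hydroxyurea (HU) study design:
adults with a polycythemia vera diagnosis preceding their first HU
prescription, at least two HU prescriptions, no myelofibrosis / essential
thrombocythemia diagnosis, HU-only cytoreduction through the labeling horizon,
a documented pre-index history and a post-index follow-up span, and (by
default) at least one pre-index laboratory value.

Resistance labeling adapts the European LeukemiaNet (ELN) consensus criteria
to real-world timelines where the HU dose is unknown (the >= 2 g/day dose
clause is dropped).  Within the 6-9 month post-index window, extended by a
measurement tolerance on both sides, a patient is labeled resistant if any of
the following holds, checked in priority order:

(a) at least one therapeutic phlebotomy,
(b) any hematocrit measurement >= 45% (the control target), or
(c) leukocytosis (WBC > 10 x10^9/L) together with thrombocytosis
    (PLT > 400 x10^9/L) measured within the tolerance of each other.

Non-resistant patients are censored at the end of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synergy import SurvivalData

__all__ = [
    "InclusionCriteria",
    "FunnelReport",
    "ResistanceLabel",
    "MissingTimelineError",
    "apply_inclusion_funnel",
    "label_hu_res",
    "label_cohort",
    "derive_features",
    "survival_from_labels",
    "FEATURE_COLUMNS",
    "HCT_CONTROL_THRESHOLD",
    "WBC_THRESHOLD",
    "PLT_THRESHOLD",
]

HCT_CONTROL_THRESHOLD = 45.0  # % — uncontrolled hematocrit
WBC_THRESHOLD = 10.0  # x10^9/L, exclusive
PLT_THRESHOLD = 400.0  # x10^9/L, exclusive

#: Feature vector column order produced by :func:`derive_features`.
FEATURE_COLUMNS: tuple[str, ...] = (
    "age_at_index",
    "gender_male",
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


class MissingTimelineError(ValueError):
    """Raised when patients have no timeline rows at all."""


@dataclass(frozen=True)
class InclusionCriteria:
    """Thresholds of the inclusion/exclusion funnel."""

    min_age: float = 18.0
    pre_index_history_days: int = 183
    post_index_followup_days: int = 365
    min_hu_prescriptions: int = 2
    hu_only_days: int = 274
    require_lab_in_pre_index: bool = True

    def validate(self) -> None:
        for name in ("pre_index_history_days", "post_index_followup_days", "hu_only_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_hu_prescriptions < 1:
            raise ValueError("min_hu_prescriptions must be >= 1")
        if self.min_age < 0:
            raise ValueError("min_age must be >= 0")


@dataclass(frozen=True)
class FunnelReport:
    """Ordered (stage name, patients remaining) attrition counts."""

    stages: tuple[tuple[str, int], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "patients_remaining"])

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(n for _, n in self.stages)


@dataclass(frozen=True)
class ResistanceLabel:
    """Outcome of window-based HU-resistance labeling for one patient."""

    resistant: bool
    criterion: str  # phlebotomy_in_window | hct_uncontrolled | myeloproliferation_uncontrolled | none
    event_day: int  # trigger day if resistant, else censoring day

    def __post_init__(self) -> None:
        if (self.criterion == "none") != (not self.resistant):
            raise ValueError("criterion 'none' must coincide with resistant=False")


def apply_inclusion_funnel(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    criteria: InclusionCriteria = InclusionCriteria(),
) -> tuple[pd.DataFrame, FunnelReport]:
    """Apply the inclusion funnel; returns retained patients and the report.

    Stage order is fixed: all patients -> adult age -> PV diagnosis before
    index -> enough HU prescriptions -> no MF/ET diagnosis -> HU-only therapy
    -> pre-index history span -> post-index follow-up span -> pre-index lab.
    """
    criteria.validate()
    ids = patients["patient_id"]
    have_timeline = set(events["patient_id"].unique())
    missing = sorted(set(ids) - have_timeline)
    if missing:
        raise MissingTimelineError(f"patients without timeline: {missing}")

    ev = events[events["patient_id"].isin(set(ids))]
    grp = ev.groupby("patient_id")
    n_hu = (
        ev.loc[ev["kind"] == "hu_prescription"].groupby("patient_id").size()
    ).reindex(ids, fill_value=0).to_numpy()
    pv_day = (
        ev.loc[ev["kind"] == "pv_diagnosis"].groupby("patient_id")["day_offset"].min()
    ).reindex(ids).to_numpy()
    has_mf_et = (
        ev.loc[ev["kind"].isin(["mf_diagnosis", "et_diagnosis"])]
        .groupby("patient_id")
        .size()
    ).reindex(ids, fill_value=0).to_numpy() > 0
    non_hu = ev.loc[
        ev["kind"].isin(["rux_prescription", "other_cytoreductive"])
        & (ev["day_offset"] < criteria.hu_only_days)
    ]
    has_early_non_hu = non_hu.groupby("patient_id").size().reindex(ids, fill_value=0).to_numpy() > 0
    first_day = grp["day_offset"].min().reindex(ids).to_numpy()
    last_day = grp["day_offset"].max().reindex(ids).to_numpy()
    pre_lab = ev.loc[
        (ev["kind"] == "lab")
        & (ev["day_offset"] < 0)
        & (ev["day_offset"] >= -criteria.pre_index_history_days)
    ]
    has_pre_lab = pre_lab.groupby("patient_id").size().reindex(ids, fill_value=0).to_numpy() > 0

    keep = np.ones(len(patients), dtype=bool)
    stages: list[tuple[str, int]] = [("all patients", int(keep.sum()))]

    def stage(name: str, ok: np.ndarray) -> None:
        nonlocal keep
        keep = keep & ok
        stages.append((name, int(keep.sum())))

    stage(f"age >= {criteria.min_age:g} at index", patients["age_at_index"].to_numpy() >= criteria.min_age)
    stage("PV diagnosis before first HU", ~np.isnan(pv_day) & (pv_day < 0))
    stage(f">= {criteria.min_hu_prescriptions} HU prescriptions", n_hu >= criteria.min_hu_prescriptions)
    stage("no MF/ET diagnosis", ~has_mf_et)
    stage(f"HU-only therapy through day {criteria.hu_only_days}", ~has_early_non_hu)
    stage(
        f">= {criteria.pre_index_history_days} days pre-index history",
        first_day <= -criteria.pre_index_history_days,
    )
    stage(
        f">= {criteria.post_index_followup_days} days post-index follow-up",
        last_day >= criteria.post_index_followup_days,
    )
    if criteria.require_lab_in_pre_index:
        stage(">= 1 pre-index lab", has_pre_lab)

    return patients.loc[keep].reset_index(drop=True), FunnelReport(tuple(stages))


# ---------------------------------------------------------------------------
# Resistance labeling


def _first_qualifying_pair(
    wbc_days: np.ndarray, plt_days: np.ndarray, tolerance_days: int
) -> int | None:
    """Earliest confirmation day of a WBC/PLT pair within the tolerance."""
    best: int | None = None
    for dw in wbc_days:
        near = plt_days[np.abs(plt_days - dw) <= tolerance_days]
        if near.size:
            day = int(max(dw, near.min()))
            if best is None or day < best:
                best = day
    return best


def _label_from_window_events(
    phleb_days: np.ndarray,
    hct_days: np.ndarray,
    wbc_days: np.ndarray,
    plt_days: np.ndarray,
    tolerance_days: int,
    censor_day: int,
) -> ResistanceLabel:
    if phleb_days.size:
        return ResistanceLabel(True, "phlebotomy_in_window", int(phleb_days.min()))
    if hct_days.size:
        return ResistanceLabel(True, "hct_uncontrolled", int(hct_days.min()))
    pair_day = _first_qualifying_pair(wbc_days, plt_days, tolerance_days)
    if pair_day is not None:
        return ResistanceLabel(True, "myeloproliferation_uncontrolled", pair_day)
    return ResistanceLabel(False, "none", censor_day)


def label_hu_res(
    timeline: pd.DataFrame,
    window: tuple[int, int] = (183, 274),
    tolerance_days: int = 14,
    followup_days: int = 365,
) -> ResistanceLabel:
    """ELN-adapted resistance label for one patient's sorted timeline.

    The window is half-open ``[start, end)`` and is extended by
    ``tolerance_days`` on both sides before rule evaluation.
    """
    start, end = window
    if not (0 <= start < end <= followup_days):
        raise ValueError("window must satisfy 0 <= start < end <= followup_days")
    day = timeline["day_offset"].to_numpy()
    if np.any(np.diff(day) < 0):
        raise ValueError("timeline must be sorted by day_offset")
    lo, hi = start - tolerance_days, end + tolerance_days
    in_win = (day >= lo) & (day < hi)
    win = timeline.loc[in_win]
    labs = win[win["kind"] == "lab"]
    return _label_from_window_events(
        win.loc[win["kind"] == "phlebotomy", "day_offset"].to_numpy(),
        labs.loc[
            (labs["analyte"] == "HCT") & (labs["value"] >= HCT_CONTROL_THRESHOLD),
            "day_offset",
        ].to_numpy(),
        labs.loc[(labs["analyte"] == "WBC") & (labs["value"] > WBC_THRESHOLD), "day_offset"].to_numpy(),
        labs.loc[(labs["analyte"] == "PLT") & (labs["value"] > PLT_THRESHOLD), "day_offset"].to_numpy(),
        tolerance_days,
        followup_days,
    )


def label_cohort(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    window: tuple[int, int] = (183, 274),
    tolerance_days: int = 14,
    followup_days: int = 365,
) -> pd.DataFrame:
    """Vectorized :func:`label_hu_res` over a cohort.

    Returns a DataFrame with columns patient_id, resistant, criterion,
    event_day (trigger day, or the censoring day for non-resistant patients).
    """
    start, end = window
    if not (0 <= start < end <= followup_days):
        raise ValueError("window must satisfy 0 <= start < end <= followup_days")
    lo, hi = start - tolerance_days, end + tolerance_days
    ids = patients["patient_id"]
    win = events.loc[
        (events["day_offset"] >= lo)
        & (events["day_offset"] < hi)
        & events["patient_id"].isin(set(ids))
    ]
    labs = win[win["kind"] == "lab"]

    def first_day(sub: pd.DataFrame) -> pd.Series:
        return sub.groupby("patient_id")["day_offset"].min()

    phleb = first_day(win[win["kind"] == "phlebotomy"]).reindex(ids)
    hct = first_day(
        labs[(labs["analyte"] == "HCT") & (labs["value"] >= HCT_CONTROL_THRESHOLD)]
    ).reindex(ids)

    wbc_hi = labs[(labs["analyte"] == "WBC") & (labs["value"] > WBC_THRESHOLD)]
    plt_hi = labs[(labs["analyte"] == "PLT") & (labs["value"] > PLT_THRESHOLD)]
    pair = pd.Series(np.nan, index=pd.Index(ids, name="patient_id"))
    both = set(wbc_hi["patient_id"]) & set(plt_hi["patient_id"])
    if both:
        wbc_map = {p: g["day_offset"].to_numpy() for p, g in wbc_hi.groupby("patient_id") if p in both}
        plt_map = {p: g["day_offset"].to_numpy() for p, g in plt_hi.groupby("patient_id") if p in both}
        for p in both:
            d = _first_qualifying_pair(wbc_map[p], plt_map[p], tolerance_days)
            if d is not None:
                pair.loc[p] = d

    out = pd.DataFrame({"patient_id": ids})
    criterion = np.full(len(ids), "none", dtype=object)
    event_day = np.full(len(ids), followup_days, dtype=np.int64)
    for col, name in ((phleb, "phlebotomy_in_window"), (hct, "hct_uncontrolled"), (pair, "myeloproliferation_uncontrolled")):
        hit = col.notna().to_numpy() & (criterion == "none")
        criterion[hit] = name
        event_day[hit] = col.to_numpy()[hit].astype(np.int64)
    out["resistant"] = criterion != "none"
    out["criterion"] = criterion
    out["event_day"] = event_day
    return out


def survival_from_labels(labels: pd.DataFrame) -> SurvivalData:
    """Time-to-resistance data: trigger day for events, follow-up end otherwise."""
    return SurvivalData(
        time=labels["event_day"].to_numpy(dtype=float),
        event=labels["resistant"].to_numpy(dtype=bool),
    )


# ---------------------------------------------------------------------------
# Feature derivation


def derive_features(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    pre_index_days: int = 183,
) -> pd.DataFrame:
    """Pre-index feature vectors, one row per patient (indexed by patient_id).

    Laboratory features take the most recent pre-index value per analyte
    within the ``pre_index_days`` window; the annualized phlebotomy count is
    the pre-index count scaled by 365/``pre_index_days``; NLR = ANC /
    lymphocytes (missing when either is); missing data propagates as NaN.
    """
    if pre_index_days <= 0:
        raise ValueError("pre_index_days must be > 0")
    ids = pd.Index(patients["patient_id"], name="patient_id")
    ev = events[events["patient_id"].isin(set(ids))]
    pre = ev[(ev["day_offset"] < 0) & (ev["day_offset"] >= -pre_index_days)]

    labs = pre[pre["kind"] == "lab"].sort_values("day_offset", kind="stable")
    lab_latest = (
        labs.groupby(["patient_id", "analyte"])["value"].last().unstack("analyte")
        if len(labs)
        else pd.DataFrame(index=ids)
    )

    n_phleb = pre[pre["kind"] == "phlebotomy"].groupby("patient_id").size().reindex(ids, fill_value=0)
    pv_day = (
        ev.loc[ev["kind"] == "pv_diagnosis"].groupby("patient_id")["day_offset"].min().reindex(ids)
    )

    out = pd.DataFrame(index=ids)
    pat = patients.set_index("patient_id")
    out["age_at_index"] = pat["age_at_index"]
    out["gender_male"] = (pat["gender"] == "male").astype(float)
    out["te_history"] = pat["te_history"].astype(float)
    out["weight"] = pat["weight"]
    out["time_dx_to_tx"] = -pv_day
    out["annualized_phlebotomy_count"] = n_phleb * 365.0 / pre_index_days
    for analyte in ("RBC", "HCT", "HGB", "RDW", "WBC", "ANC", "lymphocytes", "PLT"):
        out[analyte] = lab_latest[analyte] if analyte in lab_latest.columns else np.nan
    out["NLR"] = out["ANC"] / out["lymphocytes"]
    return out[list(FEATURE_COLUMNS)]
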