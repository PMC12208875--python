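"""Funnel, ELN-adapted labeling, and feature derivation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import make_events, make_patient
from hupred.selection import (
    InclusionCriteria,
    MissingTimelineError,
    apply_inclusion_funnel,
    derive_features,
    label_cohort,
    label_hu_res,
    survival_from_labels,
)
from hupred.simulate import GeneratorConfig, generate_cohort


class TestFunnel:
    def test_all_pass_identity_funnel(self, toy_cohort_frames):
        patients, events = toy_cohort_frames({f"P{i:05d}": {} for i in range(1, 6)})
        retained, report = apply_inclusion_funnel(patients, events)
        assert len(retained) == 5
        assert all(n == 5 for n in report.counts)

    @pytest.mark.parametrize(
        "spec, stage_fragment",
        [
            ({"patient": {"age": 17.0}}, "age >="),
            ({"rows": [(30, "pv_diagnosis", None, None)]}, "PV diagnosis"),
            ({"rows": [(-30, "et_diagnosis", None, None)]}, "MF/ET"),
            ({"rows": [(60, "rux_prescription", None, None)]}, "HU-only"),
            ({"rows": [(100, "other_cytoreductive", None, None)]}, "HU-only"),
        ],
    )
    def test_violators_excluded_at_named_stage(self, toy_cohort_frames, spec, stage_fragment):
        patients, events = toy_cohort_frames({"P00001": {}, "P00002": spec})
        if "PV diagnosis" in stage_fragment:
            # replace the compliant diagnosis with a post-index one
            events = events[
                ~((events["patient_id"] == "P00002")
                  & (events["kind"] == "pv_diagnosis")
                  & (events["day_offset"] == -200))
            ]
        retained, report = apply_inclusion_funnel(patients, events)
        assert list(retained["patient_id"]) == ["P00001"]
        stages = dict(report.stages)
        drop_stage = next(s for s, n in report.stages if n == 1)
        assert stage_fragment in drop_stage

    def test_single_prescription_excluded(self, toy_cohort_frames):
        patients, events = toy_cohort_frames({"P00001": {}, "P00002": {}})
        events = events[
            ~((events["patient_id"] == "P00002")
              & (events["kind"] == "hu_prescription")
              & (events["day_offset"] > 0))
        ]
        retained, report = apply_inclusion_funnel(patients, events)
        assert list(retained["patient_id"]) == ["P00001"]
        assert dict(report.stages)[">= 2 HU prescriptions"] == 1

    def test_counts_non_increasing(self):
        patients, events, _ = generate_cohort(
            GeneratorConfig(n_patients=150, seed=9, n_ineligible=14)
        )
        _, report = apply_inclusion_funnel(patients, events)
        counts = report.counts
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[0] == 164 and counts[-1] == 150

    def test_missing_timeline_lists_ids(self, toy_cohort_frames):
        patients, events = toy_cohort_frames({"P00001": {}, "P00002": {}})
        events = events[events["patient_id"] != "P00002"]
        with pytest.raises(MissingTimelineError, match="P00002"):
            apply_inclusion_funnel(patients, events)


class TestLabeling:
    def test_phlebotomy_in_window(self):
        tl = make_events(rows=[(200, "phlebotomy", None, None)])
        label = label_hu_res(tl)
        assert (label.resistant, label.criterion, label.event_day) == (
            True, "phlebotomy_in_window", 200,
        )

    def test_uncontrolled_hct(self):
        tl = make_events(rows=[(250, "lab", "HCT", 46.0)])
        label = label_hu_res(tl)
        assert (label.resistant, label.criterion, label.event_day) == (
            True, "hct_uncontrolled", 250,
        )

    def test_wbc_plt_pair_within_tolerance(self):
        tl = make_events(rows=[(200, "lab", "WBC", 11.0), (210, "lab", "PLT", 450.0)])
        label = label_hu_res(tl)
        assert (label.resistant, label.criterion, label.event_day) == (
            True, "myeloproliferation_uncontrolled", 210,
        )

    def test_wbc_plt_pair_outside_tolerance_censors(self):
        tl = make_events(rows=[(190, "lab", "WBC", 11.0), (230, "lab", "PLT", 450.0)])
        label = label_hu_res(tl)
        assert not label.resistant and label.event_day == 365

    def test_no_qualifying_event_censors_at_followup(self):
        tl = make_events(rows=[(250, "lab", "HCT", 42.0), (250, "lab", "WBC", 8.0)])
        label = label_hu_res(tl)
        assert (label.resistant, label.criterion, label.event_day) == (False, "none", 365)

    def test_priority_phlebotomy_over_hct(self):
        tl = make_events(
            rows=[(240, "lab", "HCT", 47.0), (250, "phlebotomy", None, None)]
        )
        label = label_hu_res(tl)
        assert label.criterion == "phlebotomy_in_window" and label.event_day == 250

    @pytest.mark.parametrize(
        "day, resistant", [(169, True), (168, False), (287, True), (288, False)]
    )
    def test_tolerance_extended_window_boundaries(self, day, resistant):
        tl = make_events(rows=[(day, "phlebotomy", None, None)])
        assert label_hu_res(tl).resistant is resistant

    def test_hct_boundary_and_strict_wbc(self):
        assert label_hu_res(make_events(rows=[(200, "lab", "HCT", 45.0)])).resistant
        tl = make_events(rows=[(200, "lab", "WBC", 10.0), (200, "lab", "PLT", 500.0)])
        assert not label_hu_res(tl).resistant  # WBC threshold is exclusive

    def test_unsorted_timeline_rejected(self):
        tl = make_events().iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            label_hu_res(tl)

    def test_window_outside_followup_rejected(self):
        with pytest.raises(ValueError, match="window"):
            label_hu_res(make_events(), window=(183, 400), followup_days=365)

    def test_vectorized_labeling_matches_per_patient(self):
        patients, events, _ = generate_cohort(GeneratorConfig(n_patients=150, seed=21))
        bulk = label_cohort(patients, events)
        for pid, sub in events.groupby("patient_id"):
            single = label_hu_res(sub.reset_index(drop=True))
            row = bulk.loc[bulk["patient_id"] == pid].iloc[0]
            assert (single.resistant, single.criterion, single.event_day) == (
                row["resistant"], row["criterion"], row["event_day"],
            )

    def test_labels_recover_ground_truth(self):
        """Window labeling recovers the generator's true flags (>= 99%)."""
        patients, events, truth = generate_cohort(GeneratorConfig(n_patients=400, seed=4))
        labels = label_cohort(patients, events).set_index("patient_id")
        agreement = (labels["resistant"] == truth).mean()
        assert agreement >= 0.99

    def test_survival_times_positive_and_censored_at_followup(self):
        patients, events, _ = generate_cohort(GeneratorConfig(n_patients=100, seed=6))
        labels = label_cohort(patients, events)
        surv = survival_from_labels(labels)
        assert (surv.time > 0).all()
        assert (surv.time[~surv.event] == 365).all()


class TestFeatures:
    def test_nlr_definition(self, toy_cohort_frames):
        patients, events = toy_cohort_frames({"P00001": {}})
        feats = derive_features(patients, events)
        assert feats.loc["P00001", "NLR"] == pytest.approx(9.0 / 1.6)

    def test_annualized_phlebotomy_count(self, toy_cohort_frames):
        patients, events = toy_cohort_frames(
            {"P00001": {"rows": [(-100, "phlebotomy", None, None), (-50, "phlebotomy", None, None)]}}
        )
        feats = derive_features(patients, events, pre_index_days=183)
        assert feats.loc["P00001", "annualized_phlebotomy_count"] == pytest.approx(
            2 * 365 / 183
        )

    def test_missing_lymphocytes_gives_missing_nlr_only(self, toy_cohort_frames):
        patients, events = toy_cohort_frames({"P00001": {}})
        events = events[~((events["kind"] == "lab") & (events["analyte"] == "lymphocytes"))]
        feats = derive_features(patients, events)
        assert np.isnan(feats.loc["P00001", "NLR"])
        assert np.isnan(feats.loc["P00001", "lymphocytes"])
        assert feats.loc["P00001", "HCT"] == 48.0

    def test_most_recent_pre_index_value_wins(self, toy_cohort_frames):
        patients, events = toy_cohort_frames(
            {"P00001": {"rows": [(-120, "lab", "HCT", 55.0)]}}
        )
        feats = derive_features(patients, events)
        assert feats.loc["P00001", "HCT"] == 48.0  # day -15 beats day -120

    def test_time_dx_to_tx_from_diagnosis_event(self, toy_cohort_frames):
        patients, events = toy_cohort_frames({"P00001": {}})
        feats = derive_features(patients, events)
        assert feats.loc["P00001", "time_dx_to_tx"] == 200

    def test_derivation_is_pure(self, toy_cohort_frames):
        patients, events = toy_cohort_frames({"P00001": {}})
        first = derive_features(patients, events)
        second = derive_features(patients, events)
        pd.testing.assert_frame_equal(first, second)
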