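"""Shared fixtures: small synthetic cohorts and hand-built timelines."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hupred.simulate import GeneratorConfig, generate_cohort
from hupred.synergy import SurvivalData

#: Planted interaction strength (log-odds) used by every planted-signal test.
STRONG_INTERACTION = 2.0


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 300-patient cohort with a planted RDW x HGB interaction."""
    cfg = GeneratorConfig(n_patients=300, seed=11, interaction_effect=STRONG_INTERACTION)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def survival_50():
    """50 patients with mixed events/censoring for oracle-equivalence checks."""
    rng = np.random.default_rng(7)
    time = rng.integers(10, 360, size=50).astype(float)
    event = rng.random(50) < 0.6
    return SurvivalData(time=time, event=event)


def make_patient(patient_id="P00001", age=60.0, gender="female", te=False, weight=80.0,
                 **labs):
    base = {
        "patient_id": patient_id,
        "gender": gender,
        "age_at_index": age,
        "te_history": te,
        "weight": weight,
        "time_dx_to_tx": 200.0,
        "annualized_phlebotomy_count": 0.5,
        "RBC": 5.4, "HCT": 48.0, "HGB": 15.5, "RDW": 17.5,
        "WBC": 12.0, "ANC": 9.0, "lymphocytes": 1.6, "PLT": 430.0,
    }
    base.update(labs)
    base["NLR"] = base["ANC"] / base["lymphocytes"]
    return base


def make_events(patient_id="P00001", rows=()):
    """Standard eligible timeline plus extra (day, kind, analyte, value) rows."""
    events = [
        (-200, "pv_diagnosis", None, None),
        (-183, "lab", "HCT", 47.0),
        (-15, "lab", "HCT", 48.0),
        (-15, "lab", "ANC", 9.0),
        (-15, "lab", "lymphocytes", 1.6),
        (0, "hu_prescription", None, None),
        (95, "hu_prescription", None, None),
        (365, "lab", "HCT", 42.0),
    ]
    events.extend(rows)
    frame = pd.DataFrame(events, columns=["day_offset", "kind", "analyte", "value"])
    frame.insert(0, "patient_id", patient_id)
    frame["analyte"] = frame["analyte"].astype("string")
    frame["value"] = frame["value"].astype(float)
    return frame.sort_values(["patient_id", "day_offset", "kind"], kind="stable").reset_index(drop=True)


@pytest.fixture
def toy_cohort_frames():
    """Builder for hand-crafted patient/event tables."""

    def build(specs):
        patients = pd.DataFrame([make_patient(**{**s.get("patient", {}), "patient_id": pid}) for pid, s in specs.items()])
        events = pd.concat(
            [make_events(pid, rows=s.get("rows", ())) for pid, s in specs.items()],
            ignore_index=True,
        )
        return patients, events

    return build
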