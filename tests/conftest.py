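"""Shared fixtures: a patient factory, the shipped model configs, and the
rule-forced CTRCD adjudication truth table used by both the unit and the
acceptance suites."""

from __future__ import annotations

import pytest

from riskval.cohort import LVEFMeasurement, LVEFSeries, PatientRecord
from riskval.models import shipped_model


def make_patient(**overrides) -> PatientRecord:
    """A 50-year-old with no cardiovascular risk factors; override freely."""
    base = dict(
        patient_id="P1",
        age=50.0,
        stage="II",
        laterality="left",
        hormone_receptor_positive=True,
        post_menopausal=False,
        anthracycline_received=False,
        cumulative_anthracycline=None,
        radiotherapy=True,
        diabetes=False,
        hypertension=False,
        dyslipidemia=False,
        current_smoker=False,
        ex_smoker=False,
        coronary_artery_disease=False,
        heart_failure_history=False,
        atrial_fibrillation=False,
        baseline_lvef=65.0,
        baseline_modality="MUGA",
        troponin=None,
        bnp=None,
    )
    base.update(overrides)
    return PatientRecord(**base)


def make_series(patient_id: str, values, modality: str = "MUGA",
                symptoms_at: frozenset = frozenset()) -> LVEFSeries:
    """Series from a list of LVEF values at 90-day spacing; ``symptoms_at``
    holds the visit indices (0-based) flagged with HF symptoms."""
    ms = [
        LVEFMeasurement(90.0 * i, float(v), modality,
                        hf_symptoms=True if i in symptoms_at else None)
        for i, v in enumerate(values)
    ]
    return LVEFSeries(patient_id=patient_id, measurements=ms)


@pytest.fixture(scope="session")
def ezaz_spec():
    return shipped_model("ezaz")


@pytest.fixture(scope="session")
def nsabp_spec():
    return shipped_model("nsabp31_crs")


@pytest.fixture(scope="session")
def hfa_spec():
    return shipped_model("hfa_icos_trastuzumab")


# Rule-forced adjudication examples: (label, definition name, baseline,
# follow-up LVEF, symptomatic flag, expected event, expected criterion).
# The below-LLN cases use a baseline under the definition's floor so the
# pure >10-point-drop branch applies.
ADJUDICATION_CASES = [
    ("crec_asymptomatic_drop", "crec", 65.0, 54.0, False, True, "asymptomatic_drop"),
    ("esc_floor_not_breached", "esc", 65.0, 54.0, False, False, "none"),
    ("ase_floor_not_breached", "ase", 65.0, 54.0, False, False, "none"),
    ("crec_symptomatic_drop", "crec", 60.0, 52.0, True, True, "symptomatic_drop"),
    ("crec_small_drop_no_symptoms", "crec", 60.0, 52.0, False, False, "none"),
    ("crec_below_lln_big_drop", "crec", 50.0, 39.0, False, True, "below_lln_baseline_drop"),
    ("crec_below_lln_small_drop", "crec", 50.0, 41.0, False, False, "none"),
    ("esc_strict_gt10_event", "esc", 61.0, 49.0, False, True, "asymptomatic_drop"),
    ("esc_drop_exactly_10_no_event", "esc", 59.0, 49.0, False, False, "none"),
    ("ase_event_below_53", "ase", 64.0, 52.0, False, True, "asymptomatic_drop"),
]
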