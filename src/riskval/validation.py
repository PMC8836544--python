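"""End-to-end validation runs: score -> adjudicate -> evaluate.

``run_validation`` crosses every requested risk model with every CTRCD
definition and produces, per pair, the incidence-by-category table, the
between-category association test, the AUC with its confidence
interval (for numeric-score models both on the raw score and on the
ordinal categories), and per-category calibration points.  Subset
filters mirror the sensitivity analyses of an external validation:
an age floor, restriction to anthracycline-exposed patients, and
biomarker-aware scoring.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

from .adjudication import CtrcdDefinition, adjudicate_cohort
from .cohort import LVEFSeries, PatientRecord
from .models import (
    RiskAssignment,
    RiskModelSpec,
    attach_predicted_risk,
    score_patient,
)
from .stats import (
    AssociationResult,
    CalibrationPoint,
    ContingencySummary,
    DiscriminationResult,
    association_test,
    auc_with_ci,
    calibration_points,
    incidence_table,
)

__all__ = ["ValidationOptions", "ValidationReport", "run_validation",
           "report_to_dict", "report_from_dict"]


@dataclass
class ValidationOptions:
    """Knobs of one validation run."""

    modality_policy: str = "same_modality_only"
    association_method: str = "chi_square"
    auc_ci_method: str = "delong"
    seed: int = 0
    age_min: Optional[float] = None          # e.g. 67 for an older-patient subset
    anthracycline_only: bool = False
    include_biomarkers: bool = False
    biomarker_subset_only: bool = False      # restrict to measured patients


@dataclass
class ValidationReport:
    """Everything measured for one (model, definition) pair."""

    model_id: str
    definition: str
    contingency: ContingencySummary
    association: AssociationResult
    discrimination: Optional[DiscriminationResult]
    discrimination_ordinal: Optional[DiscriminationResult]
    calibration: list[CalibrationPoint]
    n_unscorable: int
    unscorable_reasons: dict[str, int] = field(default_factory=dict)
    error: Optional[str] = None


def _apply_subsets(
    patients: Sequence[PatientRecord], options: ValidationOptions
) -> list[PatientRecord]:
    out = list(patients)
    if options.age_min is not None:
        out = [p for p in out if p.age >= options.age_min]
    if options.anthracycline_only:
        out = [p for p in out if p.anthracycline_received]
    if options.biomarker_subset_only:
        out = [p for p in out if p.troponin is not None or p.bnp is not None]
    return out


def run_validation(
    patients: Sequence[PatientRecord],
    series: Sequence[LVEFSeries],
    model_specs: Sequence[RiskModelSpec],
    definitions: Sequence[CtrcdDefinition],
    options: Optional[ValidationOptions] = None,
) -> dict[tuple[str, str], ValidationReport]:
    """Validate each model against each CTRCD definition.

    A failure in one (model, definition) pair is recorded in that
    report's ``error`` field and does not abort the others.
    """
    options = options or ValidationOptions()
    subset = _apply_subsets(patients, options)
    pids = {p.patient_id for p in subset}
    subset_series = [s for s in series if s.patient_id in pids]

    reports: dict[tuple[str, str], ValidationReport] = {}
    for definition in definitions:
        calls, _ = adjudicate_cohort(subset_series, definition, options.modality_policy)
        call_events = {c.patient_id: c.event for c in calls}
        for spec in model_specs:
            key = (spec.model_id, definition.name)
            try:
                assignments = [
                    attach_predicted_risk(
                        score_patient(p, spec, options.include_biomarkers), spec
                    )
                    for p in subset
                ]
                scorable = [a for a in assignments if a.scorable]
                unscorable = [a for a in assignments if not a.scorable]
                reasons: dict[str, int] = {}
                for a in unscorable:
                    reasons[a.unscorable_reason or "unknown"] = (
                        reasons.get(a.unscorable_reason or "unknown", 0) + 1
                    )
                cats = [c for c in spec.categories
                        if any(a.category == c for a in scorable)]
                table = incidence_table(scorable, calls, categories=cats)
                assoc = association_test(table, options.association_method)
                outcomes = [call_events[a.patient_id] for a in scorable]
                rank = {c: i for i, c in enumerate(spec.categories)}
                ordinal = auc_with_ci(
                    [rank[a.category] for a in scorable], outcomes,
                    method=options.auc_ci_method, seed=options.seed,
                )
                numeric = None
                if all(isinstance(a.raw_score, (int, float)) for a in scorable):
                    numeric = auc_with_ci(
                        [float(a.raw_score) for a in scorable], outcomes,
                        method=options.auc_ci_method, seed=options.seed,
                    )
                calib = calibration_points(scorable, calls, categories=cats)
                reports[key] = ValidationReport(
                    model_id=spec.model_id,
                    definition=definition.name,
                    contingency=table,
                    association=assoc,
                    discrimination=numeric,
                    discrimination_ordinal=ordinal,
                    calibration=calib,
                    n_unscorable=len(unscorable),
                    unscorable_reasons=reasons,
                )
            except Exception as exc:  # isolate per-pair failures
                reports[key] = ValidationReport(
                    model_id=spec.model_id,
                    definition=definition.name,
                    contingency=ContingencySummary([], [], []),
                    association=AssociationResult(float("nan"), float("nan"), None, "none"),
                    discrimination=None,
                    discrimination_ordinal=None,
                    calibration=[],
                    n_unscorable=0,
                    error=f"{type(exc).__name__}: {exc}",
                )
    return reports


# ---------------------------------------------------------------------------
# JSON round-trip

def report_to_dict(report: ValidationReport) -> dict:
    return asdict(report)


def report_from_dict(doc: dict) -> ValidationReport:
    return ValidationReport(
        model_id=doc["model_id"],
        definition=doc["definition"],
        contingency=ContingencySummary(**doc["contingency"]),
        association=AssociationResult(**doc["association"]),
        discrimination=(
            DiscriminationResult(**doc["discrimination"])
            if doc.get("discrimination") else None),
        discrimination_ordinal=(
            DiscriminationResult(**doc["discrimination_ordinal"])
            if doc.get("discrimination_ordinal") else None),
        calibration=[CalibrationPoint(**c) for c in doc["calibration"]],
        n_unscorable=doc["n_unscorable"],
        unscorable_reasons=doc.get("unscorable_reasons", {}),
        error=doc.get("error"),
    )


def reports_to_json(reports: dict[tuple[str, str], ValidationReport]) -> str:
    payload = {f"{m}::{d}": report_to_dict(r) for (m, d), r in sorted(reports.items())}
    return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
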