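"""Patient-level domain types and delimited-text I/O.

A cohort is two tables: one baseline row per patient (demographics,
cardiovascular risk factors, cancer/treatment variables, optional
biomarkers) and a longitudinal table of serial LVEF measurements
(time in days since the pre-therapy study, LVEF %, imaging modality,
optional heart-failure-symptom flag).  The CSV schemas are documented
in ``docs/schema.md``: comma-separated, UTF-8, header row required,
missing values encoded as empty fields, flags as 0/1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "PatientRecord",
    "LVEFMeasurement",
    "LVEFSeries",
    "SchemaError",
    "CohortValidationError",
    "ExclusionRecord",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_filter",
    "write_exclusion_log",
]

STAGES = ("I", "II", "III")
LATERALITIES = ("left", "right", "bilateral")
MODALITIES = ("MUGA", "echo")


class SchemaError(ValueError):
    """A required column is missing or a file does not match its schema."""


class CohortValidationError(ValueError):
    """A row violates a domain invariant; message names patient and row."""


@dataclass
class PatientRecord:
    """Baseline covariates for one woman treated with trastuzumab.

    Flags are booleans; ``cumulative_anthracycline`` is in mg/m^2;
    ``troponin`` (ng/L) and ``bnp`` (pg/mL) are optional biomarkers.
    """

    patient_id: str
    age: float
    stage: str
    laterality: str
    hormone_receptor_positive: bool
    post_menopausal: bool
    anthracycline_received: bool
    cumulative_anthracycline: Optional[float]
    radiotherapy: bool
    diabetes: bool
    hypertension: bool
    dyslipidemia: bool
    current_smoker: bool
    ex_smoker: bool
    coronary_artery_disease: bool
    heart_failure_history: bool
    atrial_fibrillation: bool
    baseline_lvef: float
    baseline_modality: str
    troponin: Optional[float] = None
    bnp: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id must be non-empty")
        if not self.age > 18:
            raise CohortValidationError(
                f"patient {self.patient_id}: age must exceed 18 years, got {self.age}"
            )
        if self.stage not in STAGES:
            raise CohortValidationError(
                f"patient {self.patient_id}: stage must be one of {STAGES}, got {self.stage!r}"
            )
        if self.laterality not in LATERALITIES:
            raise CohortValidationError(
                f"patient {self.patient_id}: laterality must be one of {LATERALITIES}"
            )
        if self.baseline_modality not in MODALITIES:
            raise CohortValidationError(
                f"patient {self.patient_id}: baseline_modality must be one of {MODALITIES}"
            )
        if not (0 < self.baseline_lvef <= 100):
            raise CohortValidationError(
                f"patient {self.patient_id}: baseline LVEF {self.baseline_lvef} outside (0, 100]"
            )
        if self.cumulative_anthracycline is not None and self.cumulative_anthracycline < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: cumulative anthracycline dose must be >= 0"
            )
        if not self.anthracycline_received and self.cumulative_anthracycline not in (None, 0, 0.0):
            raise CohortValidationError(
                f"patient {self.patient_id}: anthracycline dose given but "
                "anthracycline_received is false"
            )


@dataclass(frozen=True)
class LVEFMeasurement:
    """One LVEF study: days since baseline, LVEF %, modality, symptom flag."""

    time: float
    lvef: float
    modality: str
    hf_symptoms: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise CohortValidationError(f"measurement time {self.time} is negative")
        if not (0 < self.lvef <= 100):
            raise CohortValidationError(f"LVEF {self.lvef} outside (0, 100]")
        if self.modality not in MODALITIES:
            raise CohortValidationError(f"modality must be one of {MODALITIES}")


@dataclass
class LVEFSeries:
    """Ordered LVEF measurements for one patient; index 0 at time 0 is the
    pre-therapy study."""

    patient_id: str
    measurements: list[LVEFMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [m.time for m in self.measurements]
        if sorted(times) != times or len(set(times)) != len(times):
            # equal times are allowed only for distinct modalities
            key = [(m.time, m.modality) for m in self.measurements]
            if sorted(key) != key or len(set(key)) != len(key):
                raise CohortValidationError(
                    f"patient {self.patient_id}: measurement times must be strictly "
                    "ascending (ties allowed only across modalities)"
                )
        if not self.measurements or self.measurements[0].time != 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: series must start with a time-0 baseline"
            )

    @property
    def baseline(self) -> LVEFMeasurement:
        return self.measurements[0]

    def followups(self) -> list[LVEFMeasurement]:
        return [m for m in self.measurements if m.time > 0]


@dataclass(frozen=True)
class ExclusionRecord:
    patient_id: str
    reason: str


# ---------------------------------------------------------------------------
# CSV parsing helpers

_BASELINE_COLUMNS = [f.name for f in dc_fields(PatientRecord)]
_LVEF_COLUMNS = ["patient_id", "time", "lvef", "modality", "hf_symptoms"]
_OPTIONAL_BASELINE = {"cumulative_anthracycline", "troponin", "bnp"}
_FLAG_FIELDS = {
    "hormone_receptor_positive", "post_menopausal", "anthracycline_received",
    "radiotherapy", "diabetes", "hypertension", "dyslipidemia", "current_smoker",
    "ex_smoker", "coronary_artery_disease", "heart_failure_history",
    "atrial_fibrillation",
}
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_flag(raw: str, where: str) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise CohortValidationError(f"{where}: cannot parse flag value {raw!r}")


def _parse_float(raw: str, where: str) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise CohortValidationError(f"{where}: cannot parse number {raw!r}") from exc


def _check_header(header: list[str], required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_cohort(
    baseline_path: str | Path, lvef_path: str | Path
) -> tuple[list[PatientRecord], list[LVEFSeries]]:
    """Read a baseline + longitudinal cohort from the two CSV files.

    Every patient appearing in the LVEF table must have a baseline row.
    Series are sorted by time; enum and numeric coercions are applied and
    invariant violations are reported with the offending row number.
    """
    baseline_path, lvef_path = Path(baseline_path), Path(lvef_path)
    patients: list[PatientRecord] = []
    with baseline_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or [], _BASELINE_COLUMNS, baseline_path)
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            where = f"{baseline_path.name} row {i}"
            kwargs: dict = {}
            for name in _BASELINE_COLUMNS:
                raw = (row.get(name) or "").strip()
                if raw == "":
                    if name in _OPTIONAL_BASELINE:
                        kwargs[name] = None
                        continue
                    raise CohortValidationError(f"{where}: missing value for {name}")
                if name in _FLAG_FIELDS:
                    kwargs[name] = _parse_flag(raw, where)
                elif name in ("age", "baseline_lvef", "cumulative_anthracycline",
                              "troponin", "bnp"):
                    kwargs[name] = _parse_float(raw, where)
                else:
                    kwargs[name] = raw
            try:
                rec = PatientRecord(**kwargs)
            except CohortValidationError as exc:
                raise CohortValidationError(f"{where}: {exc}") from exc
            if rec.patient_id in seen:
                raise CohortValidationError(f"{where}: duplicate patient_id {rec.patient_id}")
            seen.add(rec.patient_id)
            patients.append(rec)

    per_patient: dict[str, list[LVEFMeasurement]] = {}
    keys: set[tuple[str, float, str]] = set()
    with lvef_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or [], _LVEF_COLUMNS[:4], lvef_path)
        for i, row in enumerate(reader, start=2):
            pid = (row.get("patient_id") or "").strip()
            where = f"{lvef_path.name} row {i} (patient {pid or '?'})"
            if not pid:
                raise CohortValidationError(f"{where}: missing patient_id")
            if pid not in seen:
                raise CohortValidationError(f"{where}: no baseline row for this patient")
            time = _parse_float((row.get("time") or "").strip(), where)
            lvef = _parse_float((row.get("lvef") or "").strip(), where)
            modality = (row.get("modality") or "").strip()
            raw_sym = (row.get("hf_symptoms") or "").strip()
            hf = None if raw_sym == "" else _parse_flag(raw_sym, where)
            key = (pid, time, modality)
            if key in keys:
                raise CohortValidationError(f"{where}: duplicate (patient, time, modality)")
            keys.add(key)
            try:
                m = LVEFMeasurement(time=time, lvef=lvef, modality=modality, hf_symptoms=hf)
            except CohortValidationError as exc:
                raise CohortValidationError(f"{where}: {exc}") from exc
            per_patient.setdefault(pid, []).append(m)

    series = []
    for pid, ms in per_patient.items():
        ms.sort(key=lambda m: (m.time, m.modality))
        series.append(LVEFSeries(patient_id=pid, measurements=ms))
    series.sort(key=lambda s: s.patient_id)
    return patients, series


def write_cohort(
    patients: list[PatientRecord],
    series: list[LVEFSeries],
    baseline_path: str | Path,
    lvef_path: str | Path,
) -> None:
    """Write the two cohort CSVs; output is bit-stable given fixed input."""

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, bool):
            return "1" if v else "0"
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    with Path(baseline_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_BASELINE_COLUMNS)
        for p in patients:
            w.writerow([fmt(getattr(p, c)) for c in _BASELINE_COLUMNS])
    with Path(lvef_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_LVEF_COLUMNS)
        for s in sorted(series, key=lambda s: s.patient_id):
            for m in s.measurements:
                w.writerow(
                    [s.patient_id, fmt(m.time), fmt(m.lvef), m.modality, fmt(m.hf_symptoms)]
                )


def apply_inclusion_filter(
    patients: list[PatientRecord],
    series: list[LVEFSeries],
    min_followups: int = 3,
) -> tuple[list[PatientRecord], list[LVEFSeries], list[ExclusionRecord]]:
    """Keep patients with a pre-therapy study and >= ``min_followups`` later scans.

    Returns the retained (patients, series) plus an exclusion log naming
    each dropped patient and the reason.  Idempotent, and
    ``len(retained) + len(excluded) == len(input)``.
    """
    if min_followups < 0:
        raise ValueError("min_followups must be >= 0")
    by_pid = {s.patient_id: s for s in series}
    kept_p, kept_s, log = [], [], []
    for p in patients:
        s = by_pid.get(p.patient_id)
        if s is None:
            log.append(ExclusionRecord(p.patient_id, "no LVEF series"))
            continue
        if len(s.followups()) < min_followups:
            log.append(ExclusionRecord(p.patient_id, "insufficient follow-up"))
            continue
        kept_p.append(p)
        kept_s.append(s)
    return kept_p, kept_s, log


def write_exclusion_log(log: list[ExclusionRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("patient_id\treason\n")
        for rec in log:
            fh.write(f"{rec.patient_id}\t{rec.reason}\n")
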