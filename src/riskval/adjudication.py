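"""Rule-based CTRCD adjudication from serial LVEF measurements.

Three consensus definitions of cancer-therapeutics-related cardiac
dysfunction are implemented:

* CREC — absolute LVEF decline >=10 percentage points to <55% without
  heart-failure symptoms, or >=5 points to <55% with symptoms;
* ESC  — absolute decline >10 points to a value below 50%;
* ASE  — absolute decline >10 points to below 53%.

For all definitions, when the baseline LVEF is below the lower limit of
normal (LLN), CTRCD is instead defined by an additional >10-point drop.
The LLN defaults to each definition's floor (55/50/53) and is
overridable.  Drops are absolute percentage points, not relative
fractions.  Because MUGA and 2D-echo LVEF values are not
interchangeable, the default policy compares each follow-up only to the
earliest measurement of its own modality; a pooled mode is provided for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional

from .cohort import LVEFMeasurement, LVEFSeries

__all__ = [
    "CtrcdDefinition",
    "CTRCDCall",
    "CREC",
    "ESC",
    "ASE",
    "DEFINITIONS",
    "adjudicate",
    "adjudicate_cohort",
]

ModalityPolicy = Literal["same_modality_only", "pooled"]
Criterion = Literal[
    "asymptomatic_drop", "symptomatic_drop", "below_lln_baseline_drop", "none"
]


@dataclass(frozen=True)
class CtrcdDefinition:
    """Parameters of one CTRCD rule set.

    ``strict_drop`` selects strictly ``> drop_asymptomatic`` (ESC/ASE)
    versus inclusive ``>=`` (CREC).  ``drop_symptomatic`` enables the
    symptomatic branch (CREC only).  ``lln`` defaults to ``floor``.
    """

    name: str
    drop_asymptomatic: float
    floor: float
    strict_drop: bool
    drop_symptomatic: Optional[float] = None
    lln: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.floor < 100):
            raise ValueError("floor must lie in (0, 100)")
        if self.drop_asymptomatic <= 0:
            raise ValueError("drop_asymptomatic must be positive")
        if self.drop_symptomatic is not None and self.drop_symptomatic <= 0:
            raise ValueError("drop_symptomatic must be positive")

    @property
    def effective_lln(self) -> float:
        return self.floor if self.lln is None else self.lln

    def with_lln(self, lln: float) -> "CtrcdDefinition":
        return replace(self, lln=lln)


CREC = CtrcdDefinition("CREC", drop_asymptomatic=10.0, floor=55.0,
                       strict_drop=False, drop_symptomatic=5.0)
ESC = CtrcdDefinition("ESC", drop_asymptomatic=10.0, floor=50.0, strict_drop=True)
ASE = CtrcdDefinition("ASE", drop_asymptomatic=10.0, floor=53.0, strict_drop=True)
DEFINITIONS = {"crec": CREC, "esc": ESC, "ase": ASE}


@dataclass(frozen=True)
class CTRCDCall:
    """Adjudication result for one patient under one definition."""

    patient_id: str
    definition: str
    event: bool
    first_event_time: Optional[float] = None
    triggering_measurement: Optional[LVEFMeasurement] = None
    criterion: Criterion = "none"
    baseline_used: Optional[tuple[str, float]] = None
    skipped_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.event and (
            self.first_event_time is not None or self.criterion != "none"
        ):
            raise ValueError("non-events must carry no event time or criterion")


def _qualifies(
    baseline: LVEFMeasurement, m: LVEFMeasurement, definition: CtrcdDefinition
) -> Criterion:
    drop = baseline.lvef - m.lvef
    if baseline.lvef < definition.effective_lln:
        # below-LLN baseline: pure >10-point-drop rule takes precedence
        return "below_lln_baseline_drop" if drop > 10.0 else "none"
    symptomatic = bool(m.hf_symptoms)  # unknown symptoms treated as absent
    if (
        symptomatic
        and definition.drop_symptomatic is not None
        and drop >= definition.drop_symptomatic
        and m.lvef < definition.floor
    ):
        return "symptomatic_drop"
    meets_drop = (
        drop > definition.drop_asymptomatic
        if definition.strict_drop
        else drop >= definition.drop_asymptomatic
    )
    if meets_drop and m.lvef < definition.floor:
        return "asymptomatic_drop"
    return "none"


def adjudicate(
    series: LVEFSeries,
    definition: CtrcdDefinition,
    modality_policy: ModalityPolicy = "same_modality_only",
) -> CTRCDCall:
    """Adjudicate one LVEF series; any time point during or immediately
    after therapy is eligible.

    Under ``same_modality_only`` each follow-up is compared to the
    earliest measurement of its own modality; follow-ups in a modality
    with no baseline are skipped and recorded in ``skipped_times``.
    Under ``pooled`` every follow-up is compared to the overall baseline.
    """
    overall_baseline = series.baseline
    baselines: dict[str, LVEFMeasurement] = {}
    if modality_policy == "same_modality_only":
        for m in series.measurements:
            baselines.setdefault(m.modality, m)
    elif modality_policy != "pooled":
        raise ValueError(f"unknown modality policy {modality_policy!r}")

    skipped: list[float] = []
    for m in sorted(series.measurements, key=lambda m: (m.time, m.modality)):
        if modality_policy == "same_modality_only":
            base = baselines[m.modality]
            if m.time <= base.time:
                # a follow-up that is itself the earliest study of its
                # modality has no same-modality reference: skip and log
                if m.time > 0:
                    skipped.append(m.time)
                continue
        else:
            base = overall_baseline
            if m.time <= base.time:
                continue
        crit = _qualifies(base, m, definition)
        if crit != "none":
            return CTRCDCall(
                patient_id=series.patient_id,
                definition=definition.name,
                event=True,
                first_event_time=m.time,
                triggering_measurement=m,
                criterion=crit,
                baseline_used=(base.modality, base.lvef),
                skipped_times=tuple(skipped),
            )
    return CTRCDCall(
        patient_id=series.patient_id,
        definition=definition.name,
        event=False,
        baseline_used=(overall_baseline.modality, overall_baseline.lvef),
        skipped_times=tuple(skipped),
    )


def adjudicate_cohort(
    series_list: list[LVEFSeries],
    definition: CtrcdDefinition,
    modality_policy: ModalityPolicy = "same_modality_only",
) -> tuple[list[CTRCDCall], dict]:
    """Adjudicate every series and summarize incidence.

    The summary proportion is ``None`` (flagged) for an empty cohort.
    """
    calls = [adjudicate(s, definition, modality_policy) for s in series_list]
    n = len(calls)
    n_events = sum(c.event for c in calls)
    summary = {
        "definition": definition.name,
        "n": n,
        "n_events": n_events,
        "proportion": (n_events / n) if n else None,
    }
    return calls, summary


def write_calls(calls: list[CTRCDCall], path) -> None:
    """Write adjudication calls as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tdefinition\tevent\tfirst_event_time\tcriterion\n")
        for c in calls:
            t = "" if c.first_event_time is None else f"{c.first_event_time:g}"
            fh.write(f"{c.patient_id}\t{c.definition}\t{int(c.event)}\t{t}\t{c.criterion}\n")
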