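"""Seeded synthetic cohorts of trastuzumab-treated HER2+ breast cancer
patients.

The default covariate marginals reproduce the baseline table of a
629-woman external-validation cohort (age 52.4 +/- 10.9 y; baseline
LVEF 64 +/- 7%; hypertension 18%; anthracycline exposure 90%; MUGA 70%,
and so on).  Covariates are drawn independently — the published table
gives marginals only — with an optional hook for a user-supplied
correlation structure.

The event process is this module's own stand-in (no generative model
accompanies the real cohort): a logistic model on standardized baseline
covariates decides which patients develop CTRCD; event patients receive
one follow-up whose LVEF drop is drawn to breach the configured
definition's threshold, all other visits fluctuate around baseline with
measurement noise (default SD 2.5 LVEF points, a typical test-retest
variability scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .adjudication import CREC, CtrcdDefinition, adjudicate_cohort
from .cohort import LVEFMeasurement, LVEFSeries, PatientRecord
from .models import RiskModelSpec, score_patient, stratify_by_quantiles
from .stats import ContingencySummary, incidence_table

__all__ = ["GeneratorConfig", "generate_cohort", "recover_category_gradient",
           "is_monotone_nondecreasing"]


@dataclass
class GeneratorConfig:
    """All dials of the synthetic cohort.

    Continuous marginals are truncated normals; flags are Bernoulli;
    smoking status is a three-level categorical (current/ex/never).
    ``event_coefficients`` are log-odds per standardized covariate
    (continuous: (x - mean)/sd; flags: centered at their prevalence);
    ``event_intercept`` is the log-odds at the covariate means.
    """

    n_patients: int = 629
    seed: int = 0

    # covariate marginals (defaults: the validation cohort's baseline table)
    age_mean: float = 52.4
    age_sd: float = 10.9
    age_bounds: tuple[float, float] = (18.5, 90.0)
    lvef_mean: float = 64.0
    lvef_sd: float = 7.0
    lvef_bounds: tuple[float, float] = (45.0, 80.0)
    p_stage: dict = field(default_factory=lambda: {"I": 0.20, "II": 0.52, "III": 0.28})
    p_laterality: dict = field(
        default_factory=lambda: {"left": 0.54, "right": 0.43, "bilateral": 0.03})
    p_hormone_receptor_positive: float = 0.66
    p_post_menopausal: float = 0.49
    p_anthracycline: float = 0.90
    anthracycline_dose_mean: float = 272.4
    anthracycline_dose_sd: float = 76.0
    p_radiotherapy: float = 0.78
    p_diabetes: float = 0.07
    p_hypertension: float = 0.18
    p_dyslipidemia: float = 0.13
    p_current_smoker: float = 0.07
    p_ex_smoker: float = 0.19
    p_coronary_artery_disease: float = 0.03
    p_heart_failure_history: float = 0.01
    p_atrial_fibrillation: float = 0.02
    p_muga: float = 0.70

    # optional biomarkers: fraction of patients measured, log-normal draws
    biomarker_fraction: float = 0.29
    troponin_log_median: float = np.log(5.0)   # ng/L; ~7% exceed 16 ng/L
    troponin_log_sd: float = 0.8
    bnp_log_median: float = np.log(30.0)       # pg/mL; ~9% exceed 100 pg/mL
    bnp_log_sd: float = 0.9

    # visit schedule: baseline plus n_followups at fixed spacing
    n_followups: int = 4
    visit_spacing_days: float = 90.0

    # event model
    event_intercept: float = -1.1527  # logit(0.24), the cohort's CREC incidence
    event_coefficients: dict = field(default_factory=lambda: {
        "age": 0.25,
        "baseline_lvef": -0.35,
        "anthracycline_received": 0.20,
        "hypertension": 0.15,
        "diabetes": 0.15,
    })

    # drop model
    noise_sd: float = 2.5              # truncated at +/- 3 SD (test-retest scale)
    drop_max: float = 30.0
    drop_margin: float = 0.5           # clearance past floor and strict thresholds
    target_definition: CtrcdDefinition = CREC
    apply_event_drops: bool = True     # disable to null out detectable events
    symptom_fraction: float = 0.0      # fraction of event visits flagged symptomatic

    # optional dependence hook: maps the uniform draws used for the flags
    # (patients x flags array) before thresholding; identity by default
    correlation_hook: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("age_sd", "lvef_sd", "anthracycline_dose_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name, v in list(self.__dict__.items()):
            if name.startswith("p_") and isinstance(v, float) and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               bounds: tuple[float, float], size: int) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _categorical(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=size, p=p)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[PatientRecord], list[LVEFSeries], pd.DataFrame]:
    """Draw a cohort; deterministic given ``config.seed``.

    Returns patients, their LVEF series, and a latent-truth table with
    one row per patient (linear predictor, event indicator, event visit
    time and drawn drop).  Raises when the configured maximum drop
    cannot breach the target definition's floor from a drawn baseline.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    age = _truncnorm(rng, cfg.age_mean, cfg.age_sd, cfg.age_bounds, n)
    lvef = _truncnorm(rng, cfg.lvef_mean, cfg.lvef_sd, cfg.lvef_bounds, n)
    stage = _categorical(rng, cfg.p_stage, n)
    laterality = _categorical(rng, cfg.p_laterality, n)
    smoking = _categorical(
        rng,
        {"current": cfg.p_current_smoker, "ex": cfg.p_ex_smoker,
         "never": 1 - cfg.p_current_smoker - cfg.p_ex_smoker},
        n,
    )
    flag_names = [
        "hormone_receptor_positive", "post_menopausal", "anthracycline_received",
        "radiotherapy", "diabetes", "hypertension", "dyslipidemia",
        "coronary_artery_disease", "heart_failure_history", "atrial_fibrillation",
    ]
    flag_p = {
        "hormone_receptor_positive": cfg.p_hormone_receptor_positive,
        "post_menopausal": cfg.p_post_menopausal,
        "anthracycline_received": cfg.p_anthracycline,
        "radiotherapy": cfg.p_radiotherapy,
        "diabetes": cfg.p_diabetes,
        "hypertension": cfg.p_hypertension,
        "dyslipidemia": cfg.p_dyslipidemia,
        "coronary_artery_disease": cfg.p_coronary_artery_disease,
        "heart_failure_history": cfg.p_heart_failure_history,
        "atrial_fibrillation": cfg.p_atrial_fibrillation,
    }
    u = rng.random((n, len(flag_names)))
    if cfg.correlation_hook is not None:
        u = cfg.correlation_hook(u)
    flags = {name: u[:, j] < flag_p[name] for j, name in enumerate(flag_names)}

    dose = np.maximum(
        rng.normal(cfg.anthracycline_dose_mean, cfg.anthracycline_dose_sd, n), 0.0
    )
    modality = np.where(rng.random(n) < cfg.p_muga, "MUGA", "echo")
    has_bio = rng.random(n) < cfg.biomarker_fraction
    troponin = np.exp(rng.normal(cfg.troponin_log_median, cfg.troponin_log_sd, n))
    bnp = np.exp(rng.normal(cfg.bnp_log_median, cfg.bnp_log_sd, n))

    # event model: logistic on standardized covariates
    eta = np.full(n, cfg.event_intercept)
    std = {
        "age": (age - cfg.age_mean) / cfg.age_sd,
        "baseline_lvef": (lvef - cfg.lvef_mean) / cfg.lvef_sd,
    }
    for name, coef in cfg.event_coefficients.items():
        if name in std:
            eta += coef * std[name]
        elif name in flags:
            eta += coef * (flags[name].astype(float) - flag_p[name])
        else:
            raise ValueError(f"event coefficient references unknown covariate {name!r}")
    p_event = expit(eta)
    is_event = rng.random(n) < p_event

    event_visit = rng.integers(1, cfg.n_followups + 1, size=n)  # 1-based follow-up index
    # noise truncated at 3 SD: physiological test-retest variability is not
    # heavy-tailed, and truncation keeps non-event visits (default SD 2.5,
    # bound 7.5 points) from ever mimicking a >=10-point diagnostic drop
    noise = np.clip(rng.normal(0.0, cfg.noise_sd, size=(n, cfg.n_followups)),
                    -3 * cfg.noise_sd, 3 * cfg.noise_sd)
    drop_u = rng.random(n)
    symptomatic = rng.random(n) < cfg.symptom_fraction

    d = cfg.target_definition
    strict_pad = cfg.drop_margin if d.strict_drop else 0.0
    patients: list[PatientRecord] = []
    series: list[LVEFSeries] = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i:05d}"
        patients.append(PatientRecord(
            patient_id=pid,
            age=float(age[i]),
            stage=str(stage[i]),
            laterality=str(laterality[i]),
            hormone_receptor_positive=bool(flags["hormone_receptor_positive"][i]),
            post_menopausal=bool(flags["post_menopausal"][i]),
            anthracycline_received=bool(flags["anthracycline_received"][i]),
            cumulative_anthracycline=(
                float(dose[i]) if flags["anthracycline_received"][i] else None),
            radiotherapy=bool(flags["radiotherapy"][i]),
            diabetes=bool(flags["diabetes"][i]),
            hypertension=bool(flags["hypertension"][i]),
            dyslipidemia=bool(flags["dyslipidemia"][i]),
            current_smoker=smoking[i] == "current",
            ex_smoker=smoking[i] == "ex",
            coronary_artery_disease=bool(flags["coronary_artery_disease"][i]),
            heart_failure_history=bool(flags["heart_failure_history"][i]),
            atrial_fibrillation=bool(flags["atrial_fibrillation"][i]),
            baseline_lvef=float(lvef[i]),
            baseline_modality=str(modality[i]),
            troponin=float(troponin[i]) if has_bio[i] else None,
            bnp=float(bnp[i]) if has_bio[i] else None,
        ))

        drop_used = np.nan
        measurements = [LVEFMeasurement(0.0, float(lvef[i]), str(modality[i]))]
        for v in range(1, cfg.n_followups + 1):
            t = v * cfg.visit_spacing_days
            if cfg.apply_event_drops and is_event[i] and v == event_visit[i]:
                drop_min = max(d.drop_asymptomatic + strict_pad,
                               lvef[i] - d.floor + cfg.drop_margin)
                if drop_min > cfg.drop_max or lvef[i] - drop_min <= 0:
                    raise ValueError(
                        f"infeasible drop configuration: baseline {lvef[i]:.1f} cannot "
                        f"breach floor {d.floor} within drop_max {cfg.drop_max}"
                    )
                drop_used = drop_min + drop_u[i] * (cfg.drop_max - drop_min)
                value = float(lvef[i] - drop_used)
                measurements.append(LVEFMeasurement(
                    t, value, str(modality[i]),
                    hf_symptoms=bool(symptomatic[i]) or None,
                ))
            else:
                value = float(np.clip(lvef[i] + noise[i, v - 1], 1.0, 100.0))
                measurements.append(LVEFMeasurement(t, value, str(modality[i])))
        series.append(LVEFSeries(patient_id=pid, measurements=measurements))
        truth_rows.append({
            "patient_id": pid,
            "linear_predictor": float(eta[i]),
            "p_event": float(p_event[i]),
            "event": bool(is_event[i]),
            "event_time": (float(event_visit[i] * cfg.visit_spacing_days)
                           if is_event[i] else np.nan),
            "drop": float(drop_used),
        })
    return patients, series, pd.DataFrame(truth_rows)


def is_monotone_nondecreasing(values, tolerance: float = 0.0) -> bool:
    """True when each value is at least the previous one minus ``tolerance``."""
    vals = list(values)
    return all(b >= a - tolerance for a, b in zip(vals, vals[1:]))


def recover_category_gradient(
    config: GeneratorConfig,
    spec: RiskModelSpec,
    definition: CtrcdDefinition = CREC,
    quantile_k: Optional[int] = None,
    include_biomarkers: bool = False,
) -> ContingencySummary:
    """Generate a cohort, score it with ``spec``, adjudicate, and return
    observed incidence by risk category — the parameter-recovery surface
    for the full pipeline.

    For numeric-score models set ``quantile_k`` to stratify by empirical
    quantiles of the raw score instead of the configured cutpoints.
    """
    patients, series, _ = generate_cohort(config)
    assignments = [score_patient(p, spec, include_biomarkers) for p in patients]
    calls, _ = adjudicate_cohort(series, definition)
    if quantile_k is not None:
        scorable = [a for a in assignments if a.scorable]
        labels, _, degenerate = stratify_by_quantiles(
            [a.raw_score for a in scorable], quantile_k)
        if degenerate:
            raise ValueError("all scores identical; quantile stratification degenerate")
        assignments = [replace(a, category=f"Q{int(g) + 1}")
                       for a, g in zip(scorable, labels)]
        cats = [f"Q{j + 1}" for j in range(quantile_k)]
        return incidence_table(assignments, calls, categories=cats)
    cats = [c for c in spec.categories
            if any(a.category == c for a in assignments if a.scorable)]
    return incidence_table(assignments, calls, categories=cats)
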