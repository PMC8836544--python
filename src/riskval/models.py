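"""Declarative risk-score engine and the three shipped model configurations.

The engine evaluates ``RiskModelSpec`` objects loaded from YAML.  Three
combination modes cover the shipped models:

* ``points_sum`` — each satisfied factor contributes integer points;
  the total maps to an ordered category through cutpoints (the Ezaz
  heart-failure/cardiomyopathy model, points 0-12, categories
  0-3 low / 4-5 medium / 6-9 high).
* ``formula`` — a closed-form score of baseline covariates (the
  NSABP B-31 cardiac risk score, a function of age and baseline LVEF,
  categorized by the validation cohort's tertiles <=50 / 51-64 / >=65),
  with an optional restricted-cubic-spline score->risk curve for
  calibration.
* ``level_combination`` — factors trigger at medium / high / very_high
  levels and a combination rule yields the final category (the HFA-ICOS
  trastuzumab proforma, with optional biomarker factors:
  troponin > 16 ng/L, BNP > 100 pg/mL).

Formula expressions are parsed with :mod:`ast` and evaluated over a
whitelist of arithmetic operations and named covariates only — a config
file can define a score, never run code.

Scoring is a pure function of (patient, spec).  A patient missing a
covariate a points/formula model needs yields an explicit unscorable
assignment naming the covariate — never a silent zero.  Absent optional
covariates of a level model simply do not trigger their factors.
"""

from __future__ import annotations

import ast
import math
import operator
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .cohort import PatientRecord
from .spline import CrsRiskFunction, fit_crs_risk_function

__all__ = [
    "FactorRule",
    "RiskModelSpec",
    "RiskAssignment",
    "UnscorableError",
    "FormulaError",
    "evaluate_formula",
    "load_model_spec",
    "shipped_model",
    "SHIPPED_MODELS",
    "score_points_model",
    "score_formula_model",
    "score_nsabp_crs",
    "score_hfa_icos",
    "score_patient",
    "attach_predicted_risk",
    "stratify_by_quantiles",
]

LEVELS = ("medium", "high", "very_high")
LEVEL_CATEGORIES = ("low", "medium", "high", "very_high")
SHIPPED_MODELS = ("ezaz", "nsabp31_crs", "hfa_icos_trastuzumab")

_OPS = {
    "ge": lambda v, t: v >= t,
    "gt": lambda v, t: v > t,
    "le": lambda v, t: v <= t,
    "lt": lambda v, t: v < t,
    "eq": lambda v, t: v == t,
    "between": lambda v, t: t[0] <= v <= t[1],
    "is_true": lambda v, t: bool(v),
    "is_false": lambda v, t: not bool(v),
}


class UnscorableError(ValueError):
    """Raised only on malformed specs; missing covariates never raise."""


class FormulaError(ValueError):
    """A score formula uses a construct outside the arithmetic whitelist."""


# ---------------------------------------------------------------------------
# Safe arithmetic-expression evaluation (no eval): the parse tree is walked
# and only the node types below are permitted.

_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Pow: operator.pow,
    ast.Mod: operator.mod,
    ast.FloorDiv: operator.floordiv,
}
_UNARYOPS = {ast.UAdd: operator.pos, ast.USub: operator.neg}
_FUNCS = {
    "min": min, "max": max, "abs": abs,
    "log": math.log, "exp": math.exp, "sqrt": math.sqrt,
}


def evaluate_formula(expression: str, variables: dict[str, float]) -> float:
    """Evaluate an arithmetic expression over named covariates.

    Only numeric literals, the named variables, + - * / ** % //, unary
    signs, and the functions min/max/abs/log/exp/sqrt are allowed; any
    other syntax raises :class:`FormulaError`.
    """
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise FormulaError(f"cannot parse formula {expression!r}: {exc}") from exc

    def walk(node: ast.AST) -> float:
        if isinstance(node, ast.Expression):
            return walk(node.body)
        if isinstance(node, ast.Constant):
            if isinstance(node.value, (int, float)) and not isinstance(node.value, bool):
                return float(node.value)
            raise FormulaError(f"non-numeric literal {node.value!r}")
        if isinstance(node, ast.Name):
            if node.id in variables:
                return float(variables[node.id])
            raise FormulaError(f"unknown variable {node.id!r}")
        if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            return _BINOPS[type(node.op)](walk(node.left), walk(node.right))
        if isinstance(node, ast.UnaryOp) and type(node.op) in _UNARYOPS:
            return _UNARYOPS[type(node.op)](walk(node.operand))
        if isinstance(node, ast.Call):
            if (
                isinstance(node.func, ast.Name)
                and node.func.id in _FUNCS
                and not node.keywords
            ):
                return float(_FUNCS[node.func.id](*[walk(a) for a in node.args]))
            raise FormulaError("only min/max/abs/log/exp/sqrt calls are allowed")
        raise FormulaError(f"disallowed syntax {type(node).__name__} in formula")

    return float(walk(tree))


@dataclass(frozen=True)
class FactorRule:
    """One predicate on a baseline covariate and its contribution."""

    field: str
    op: str
    value: Any = None
    points: Optional[float] = None      # points_sum contribution
    level: Optional[str] = None         # level_combination contribution
    biomarker: bool = False             # only evaluated when biomarkers enabled

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise UnscorableError(f"unknown predicate op {self.op!r}")
        if self.level is not None and self.level not in LEVELS:
            raise UnscorableError(f"factor level must be one of {LEVELS}")
        if self.field not in PatientRecord.__dataclass_fields__:
            raise UnscorableError(f"factor references unknown covariate {self.field!r}")

    def satisfied(self, patient: PatientRecord) -> Optional[bool]:
        """True/False, or ``None`` when the covariate is missing."""
        v = getattr(patient, self.field)
        if v is None:
            return None
        return bool(_OPS[self.op](v, self.value))


@dataclass
class RiskModelSpec:
    """Declarative definition of one scoring model."""

    model_id: str
    combination: str  # points_sum | formula | level_combination
    factors: list[FactorRule] = field(default_factory=list)
    formula: Optional[str] = None
    formula_fields: tuple[str, ...] = ()
    category_rule: list[dict] = field(default_factory=list)  # [{category, max}]
    categories: tuple[str, ...] = ()
    predicted_risk: dict[str, float] = field(default_factory=dict)
    combination_rule: dict[str, int] = field(default_factory=dict)
    risk_function: Optional[CrsRiskFunction] = None
    metadata: str = ""

    def __post_init__(self) -> None:
        if self.combination not in ("points_sum", "formula", "level_combination"):
            raise UnscorableError(f"unknown combination mode {self.combination!r}")
        if self.combination == "level_combination" and not self.categories:
            self.categories = LEVEL_CATEGORIES
        if not self.categories and self.category_rule:
            self.categories = tuple(r["category"] for r in self.category_rule)
        for cat, p in self.predicted_risk.items():
            if not (0.0 <= p <= 1.0):
                raise UnscorableError(f"predicted risk for {cat!r} outside [0, 1]")

    def categorize(self, score: float) -> str:
        """Map a numeric score through the ordered cutpoint rule; a score
        equal to a cutpoint goes to the lower category."""
        for rule in self.category_rule:
            if rule.get("max") is None or score <= rule["max"]:
                return rule["category"]
        raise UnscorableError(f"{self.model_id}: no category for score {score}")


@dataclass(frozen=True)
class RiskAssignment:
    """One model's verdict for one patient.

    ``category is None`` iff the patient was unscorable, in which case
    ``unscorable_reason`` names the missing covariate.
    """

    patient_id: str
    model_id: str
    raw_score: Any = None
    category: Optional[str] = None
    predicted_risk: Optional[float] = None
    unscorable_reason: Optional[str] = None

    @property
    def scorable(self) -> bool:
        return self.category is not None


# ---------------------------------------------------------------------------
# Config loading

def _build_spec(doc: dict) -> RiskModelSpec:
    factors = [
        FactorRule(
            field=f["field"],
            op=f["op"],
            value=f.get("value"),
            points=f.get("points"),
            level=f.get("level"),
            biomarker=bool(f.get("biomarker", False)),
        )
        for f in doc.get("factors", [])
    ]
    rf = None
    if doc.get("risk_function"):
        anchors = [tuple(a) for a in doc["risk_function"]["anchors"]]
        rf = fit_crs_risk_function(anchors, doc["risk_function"]["knots"])
    return RiskModelSpec(
        model_id=doc["model_id"],
        combination=doc["combination"],
        factors=factors,
        formula=doc.get("formula"),
        formula_fields=tuple(doc.get("formula_fields", ())),
        category_rule=doc.get("category_rule", []),
        categories=tuple(doc.get("categories", ())),
        predicted_risk=dict(doc.get("predicted_risk", {})),
        combination_rule=dict(doc.get("combination_rule", {})),
        risk_function=rf,
        metadata=str(doc.get("metadata", "")),
    )


def load_model_spec(path: str | Path) -> RiskModelSpec:
    """Load a model definition from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _build_spec(yaml.safe_load(fh))


def shipped_model(name: str) -> RiskModelSpec:
    """Load one of the bundled configurations by name
    (``ezaz``, ``nsabp31_crs``, ``hfa_icos_trastuzumab``)."""
    if name not in SHIPPED_MODELS:
        raise KeyError(f"unknown shipped model {name!r}; choose from {SHIPPED_MODELS}")
    text = resources.files("riskval.configs").joinpath(f"{name}.yaml").read_text("utf-8")
    return _build_spec(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Scoring

def score_points_model(patient: PatientRecord, spec: RiskModelSpec) -> RiskAssignment:
    """Sum the points of satisfied factor predicates and categorize.

    A factor whose covariate is missing makes the patient unscorable
    (explicitly, naming the covariate) rather than contributing zero.
    """
    if spec.combination != "points_sum":
        raise UnscorableError("spec is not a points_sum model")
    total = 0.0
    for f in spec.factors:
        sat = f.satisfied(patient)
        if sat is None:
            return RiskAssignment(
                patient.patient_id, spec.model_id,
                unscorable_reason=f"missing covariate {f.field}",
            )
        if sat:
            total += float(f.points or 0)
    return RiskAssignment(
        patient.patient_id, spec.model_id, raw_score=total,
        category=spec.categorize(total),
    )


def score_formula_model(patient: PatientRecord, spec: RiskModelSpec) -> RiskAssignment:
    """Evaluate a closed-form score expression over baseline covariates."""
    if spec.combination != "formula" or not spec.formula:
        raise UnscorableError("spec is not a formula model")
    env: dict[str, float] = {}
    for name in spec.formula_fields:
        v = getattr(patient, name)
        if v is None:
            return RiskAssignment(
                patient.patient_id, spec.model_id,
                unscorable_reason=f"missing covariate {name}",
            )
        env[name] = float(v)
    score = evaluate_formula(spec.formula, env)
    return RiskAssignment(
        patient.patient_id, spec.model_id, raw_score=score,
        category=spec.categorize(score),
    )


def score_nsabp_crs(patient: PatientRecord, spec: RiskModelSpec) -> RiskAssignment:
    """The NSABP-31 cardiac risk score: a formula of age and baseline LVEF."""
    return score_formula_model(patient, spec)


def _combine_levels(levels: list[str], rule: dict[str, int]) -> str:
    """Default combination: any very_high factor -> very_high; else any
    high factor or >= ``high_for_medium_count`` medium factors -> high;
    else >= ``medium_for_medium_count`` medium factors -> medium; else low."""
    high_k = int(rule.get("high_for_medium_count", 5))
    med_k = int(rule.get("medium_for_medium_count", 2))
    n_med = levels.count("medium")
    if "very_high" in levels:
        return "very_high"
    if "high" in levels or n_med >= high_k:
        return "high"
    if n_med >= med_k:
        return "medium"
    return "low"


def score_hfa_icos(
    patient: PatientRecord,
    spec: RiskModelSpec,
    include_biomarkers: bool = False,
) -> RiskAssignment:
    """Collect triggered factor levels and combine them into the final
    proforma category.  Biomarker factors fire only when
    ``include_biomarkers`` is set and the measurement is present; absent
    optional covariates never trigger."""
    if spec.combination != "level_combination":
        raise UnscorableError("spec is not a level_combination model")
    triggered: list[str] = []
    for f in spec.factors:
        if f.biomarker and not include_biomarkers:
            continue
        if f.satisfied(patient):  # None (missing) is falsy: not triggered
            triggered.append(f.level or "medium")
    category = _combine_levels(triggered, spec.combination_rule)
    return RiskAssignment(
        patient.patient_id, spec.model_id,
        raw_score=tuple(sorted(triggered)), category=category,
    )


def score_patient(
    patient: PatientRecord, spec: RiskModelSpec, include_biomarkers: bool = False
) -> RiskAssignment:
    """Dispatch on the spec's combination mode."""
    if spec.combination == "points_sum":
        return score_points_model(patient, spec)
    if spec.combination == "formula":
        return score_formula_model(patient, spec)
    return score_hfa_icos(patient, spec, include_biomarkers=include_biomarkers)


def attach_predicted_risk(
    assignment: RiskAssignment, spec: RiskModelSpec
) -> RiskAssignment:
    """Populate ``predicted_risk`` from the model configuration.

    Formula models with a fitted score->risk curve evaluate it at the
    raw score; other models look the category up in the configured
    per-category risks.  Unscorable assignments pass through unchanged.
    """
    if not assignment.scorable:
        return assignment
    if spec.risk_function is not None and isinstance(assignment.raw_score, (int, float)):
        return replace(
            assignment, predicted_risk=float(spec.risk_function(assignment.raw_score))
        )
    if assignment.category not in spec.predicted_risk:
        raise UnscorableError(
            f"{spec.model_id}: no predicted risk configured for category "
            f"{assignment.category!r}"
        )
    return replace(assignment, predicted_risk=spec.predicted_risk[assignment.category])


# ---------------------------------------------------------------------------
# Quantile stratification

def stratify_by_quantiles(scores, k: int) -> tuple[np.ndarray, list[float], bool]:
    """Split scores into ``k`` ordered groups at empirical quantile
    cutpoints (inverted-CDF order statistics at j/k).

    A score equal to a cutpoint goes to the LOWER group, matching the
    "score <= cutpoint" labelling of published tertiles.  Returns
    (group index per score, cutpoints, degenerate flag); all-identical
    scores collapse to a single flagged group.
    """
    scores = np.asarray(scores, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    if np.all(scores == scores[0]):
        return np.zeros(scores.size, dtype=int), [], True
    srt = np.sort(scores)
    n = scores.size
    cutpoints = []
    for j in range(1, k):
        idx = max(int(math.ceil(n * j / k)) - 1, 0)
        cutpoints.append(float(srt[idx]))
    labels = np.zeros(n, dtype=int)
    for cp in cutpoints:
        labels += scores > cp
    return labels, cutpoints, False
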