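"""Published incidence-by-category tables from the external validation
study this toolkit is built around (629 trastuzumab-treated women with
stage I-III HER2+ breast cancer; CTRCD adjudicated under the CREC
definition unless noted).

These counts are fixed reference inputs: they let the between-category
statistics the study reports (chi-square p-values, relative risks) be
recomputed exactly without access to the private patient-level data.
"""

from __future__ import annotations

from .stats import ContingencySummary

__all__ = ["REPORTED_TABLES", "reported_table", "COHORT_SIZE",
           "CREC_EVENTS", "ESC_EVENTS", "ASE_EVENTS"]

COHORT_SIZE = 629
CREC_EVENTS = 151   # 24% of the cohort
ESC_EVENTS = 35     # 5.6%
ASE_EVENTS = 102    # 16.2%

_RAW: dict[str, dict] = {
    # full cohort, CREC definition
    "ezaz_crec": {
        "categories": ["low", "medium", "high"],
        "n_total": [577, 45, 7],
        "n_events": [141, 9, 1],
    },
    "nsabp_tertiles_crec": {
        "categories": ["low", "medium", "high"],   # CRS <=50 / 51-64 / >=65
        "n_total": [223, 204, 202],
        "n_events": [40, 50, 61],
    },
    "hfa_icos_crec": {
        "categories": ["low", "medium", "high", "very_high"],
        "n_total": [193, 404, 27, 5],
        "n_events": [30, 109, 10, 2],
    },
    # sensitivity analyses
    "nsabp_anthracycline_only": {
        "categories": ["low", "medium", "high"],
        "n_total": [201, 184, 183],
        "n_events": [38, 47, 53],
    },
    "hfa_icos_biomarkers": {
        "categories": ["low", "medium", "high"],   # no very-high patients
        "n_total": [40, 140, 4],
        "n_events": [10, 46, 1],
    },
    "ezaz_age_ge_67": {
        "categories": ["low", "medium", "high"],
        "n_total": [45, 15, 4],
        "n_events": [15, 4, 1],
    },
}

REPORTED_TABLES = tuple(_RAW)


def reported_table(name: str) -> ContingencySummary:
    """One of the published tables as a :class:`ContingencySummary`."""
    if name not in _RAW:
        raise KeyError(f"unknown table {name!r}; choose from {REPORTED_TABLES}")
    d = _RAW[name]
    return ContingencySummary(
        categories=list(d["categories"]),
        n_total=list(d["n_total"]),
        n_events=list(d["n_events"]),
    )
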