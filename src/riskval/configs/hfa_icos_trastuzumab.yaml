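# HFA-ICOS trastuzumab proforma: expert-consensus risk factors at
# medium / high / very_high levels, combined into a final category
# low / medium / high / very_high.
#
# VERIFY AGAINST THE ORIGINAL CONSENSUS DOCUMENT: the factor-to-level
# assignments below follow its structure but were assembled for this
# toolkit; the combination rule is this package's default (any very_high
# factor -> very_high; any high factor or >=5 medium factors -> high;
# 2-4 medium factors -> medium; else low) because the consensus document
# describes combining levels without a fully explicit algorithm.
#
# Biomarker factors (flagged biomarker: true) fire only when biomarker
# inclusion is requested and the measurement is present; thresholds
# hsTnI > 16 ng/L and BNP > 100 pg/mL are institutional upper normals.
model_id: hfa_icos
combination: level_combination
metadata: >
  Level-combination proforma for trastuzumab-treated patients. Factor
  levels follow the consensus structure; combination rule and predicted
  per-category risks are config-overridable defaults.
categories: [low, medium, high, very_high]
combination_rule:
  medium_for_medium_count: 2
  high_for_medium_count: 5
factors:
  - {field: heart_failure_history, op: is_true, level: very_high}
  - {field: baseline_lvef, op: lt, value: 50, level: high}
  - {field: baseline_lvef, op: between, value: [50, 54], level: medium}
  - {field: age, op: ge, value: 80, level: high}
  - {field: age, op: between, value: [65, 79], level: medium}
  - {field: hypertension, op: is_true, level: medium}
  - {field: diabetes, op: is_true, level: medium}
  - {field: atrial_fibrillation, op: is_true, level: medium}
  - {field: coronary_artery_disease, op: is_true, level: high}
  - {field: anthracycline_received, op: is_true, level: medium}
  - {field: current_smoker, op: is_true, level: medium}
  - {field: dyslipidemia, op: is_true, level: medium}
  - {field: troponin, op: gt, value: 16, level: medium, biomarker: true}
  - {field: bnp, op: gt, value: 100, level: medium, biomarker: true}
# Predicted risks for calibration: representative values of the published
# bands (low <2%, medium 2-9%, high 10-19%, very high >20%, taken as 30%).
predicted_risk:
  low: 0.01
  medium: 0.055
  high: 0.145
  very_high: 0.30
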