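# Points-based heart-failure/cardiomyopathy risk model for older women with
# HER2+ breast cancer on adjuvant trastuzumab (points 0-12; categories
# 0-3 low, 4-5 medium, 6-9 high).
#
# PLACEHOLDER NUMBERS: the exact point allocation lives in the original
# derivation publication and must be transcribed from it before clinical
# use.  The factor structure and the category cutpoints below are the
# published ones; the per-factor points and per-category source
# incidences are illustrative stand-ins.  Edit freely.
model_id: ezaz
combination: points_sum
metadata: >
  Points-sum model over baseline cardiovascular comorbidity and treatment
  covariates. Point values are placeholders pending transcription from the
  source publication; category boundaries (0-3/4-5/6-9) are as published.
factors:
  - {field: anthracycline_received, op: is_true, points: 2}
  - {field: coronary_artery_disease, op: is_true, points: 2}
  - {field: atrial_fibrillation, op: is_true, points: 2}
  - {field: diabetes, op: is_true, points: 2}
  - {field: hypertension, op: is_true, points: 1}
  - {field: age, op: between, value: [75, 79], points: 1}
  - {field: age, op: ge, value: 80, points: 2}
category_rule:
  - {category: low, max: 3}
  - {category: medium, max: 5}
  - {category: high, max: null}
# Predicted risks for calibration: the source publication's per-category
# 3-year incidences. PLACEHOLDER values pending transcription.
predicted_risk:
  low: 0.10
  medium: 0.19
  high: 0.32
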