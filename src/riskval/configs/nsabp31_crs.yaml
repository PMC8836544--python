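# NSABP B-31 cardiac risk score (CRS): a closed-form score of age and
# baseline LVEF for women treated with anthracyclines followed by
# trastuzumab.
#
# PLACEHOLDER FORMULA: the exact CRS expression lives in the original
# trial publication's appendix; the expression below has the published
# structure (increasing in age, decreasing in baseline LVEF, on a scale
# where the validation-cohort tertile boundaries fall at 50 and 64) and
# must be replaced by the transcribed formula before clinical use.
#
# The risk_function anchors approximate the score -> cardiac-event-risk
# curve that the source publication shows only graphically (its authors
# did not publish the cumulative incidence function).  The anchor values
# below are PLACEHOLDERS requiring transcription from that figure; a
# restricted cubic spline is fitted through them at load time.
model_id: nsabp31_crs
combination: formula
metadata: >
  Formula model of age and baseline LVEF. Formula and risk-curve anchors
  are placeholders pending transcription from the source publication;
  the tertile cutpoints (<=50 / 51-64 / >=65) are the published
  validation-cohort boundaries.
formula: "age + (70 - baseline_lvef)"
formula_fields: [age, baseline_lvef]
category_rule:
  - {category: low, max: 50}
  - {category: medium, max: 64}
  - {category: high, max: null}
risk_function:
  anchors:
    - [30, 0.005]
    - [40, 0.010]
    - [50, 0.020]
    - [60, 0.040]
    - [70, 0.070]
    - [80, 0.120]
    - [90, 0.180]
  knots: [40, 55, 70, 85]
predicted_risk: {}
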