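# Versioned bin/point tables for the comparator remission scores.
#
# Rules for a numeric variable are evaluated in order; a rule matches when
# value < max (or value <= max with inclusive: true); the terminal rule
# (no max) catches everything else. Flag variables contribute flag_points
# when true.
#
# ABCD: transcribed from the original publication (Lee et al., 2013).
# DiaRem: transcribed from the original publication (Still et al., 2014);
#   any non-insulin antidiabetic drug use contributes the 3-point item.
# IMS: the published nomogram's exact point values are not reprinted in an
#   extractable table; the point assignments below are an approximate
#   reconstruction that preserves the published variable set, the monotone
#   ordering of severity, and the mild <=25 / moderate (25, 95) /
#   severe >=95 banding. Treat them as configurable data, not ground truth.
version: 1
abcd:
  total_range: [0, 10]
  bands:
    "0-2": [0, 2]
    "3-4": [3, 4]
    "5-6": [5, 6]
    "7-8": [7, 8]
    "9-10": [9, 10]
  variables:
    age:
      rules:
        - {max: 40, points: 1}
        - {points: 0}
    bmi:
      rules:
        - {max: 27, points: 0}
        - {max: 35, points: 1}
        - {max: 42, points: 2}
        - {points: 3}
    fcp:
      rules:
        - {max: 2, points: 0}
        - {max: 3, points: 1}
        - {max: 5, points: 2}
        - {points: 3}
    duration:
      rules:
        - {max: 1, points: 3}
        - {max: 4, points: 2}
        - {max: 8, inclusive: true, points: 1}
        - {points: 0}
diarem:
  total_range: [0, 22]
  bands:
    "0-2": [0, 2]
    "3-7": [3, 7]
    "8-12": [8, 12]
    "13-17": [13, 17]
    "18-22": [18, 22]
  variables:
    age:
      rules:
        - {max: 40, points: 0}
        - {max: 50, points: 1}
        - {max: 60, points: 2}
        - {points: 3}
    hba1c:
      rules:
        - {max: 6.5, points: 0}
        - {max: 7.0, points: 2}
        - {max: 9.0, points: 4}
        - {points: 6}
    other_antidiabetic_drug_use:
      flag_points: 3
    insulin_use:
      flag_points: 10
ims:
  # banding: mild <= mild_max; severe >= severe_min; moderate in between
  bands:
    mild_max: 25
    severe_min: 95
  variables:
    n_diabetes_medications:
      rules:
        - {max: 2, points: 0}
        - {points: 28.5}
    insulin_use:
      flag_points: 25
    duration:
      rules:
        - {max: 1, points: 0}
        - {max: 4, points: 10}
        - {max: 8, inclusive: true, points: 25}
        - {points: 45}
    hba1c:
      rules:
        - {max: 7.0, points: 0}
        - {max: 9.0, points: 20}
        - {points: 36.5}
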