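# Default risk-factor registries for the three scales.
#
# Every printed cutoff, inequality direction and weight lives here as data so
# a different cohort (different questionnaires, added LIBRA components) can
# supply its own registry file without touching code.
#
# Operators: ge / gt / le / lt  — numeric comparison against `cutoff`;
#            eq                 — equality against `cutoff` (categorical);
#            flag               — boolean field is true;
#            any_of             — at least one of the listed `terms` holds;
#            count_ge           — at least `cutoff` of the boolean `fields`;
#            age_sex_band       — male/female point lookup in `bands`;
#            band               — point lookup in `bands` on one field.

libra:
  high_risk_cutoff: 4.2
  factors:
    - name: age_by_sex
      op: age_sex_band
      field: age
      sex_field: sex
      bands:   # [min, max) in years; points male / female
        - {min: 0,  max: 65,   male: 0.0,  female: 0.0}
        - {min: 65, max: 70,   male: 0.4,  female: 2.1}
        - {min: 70, max: 75,   male: 5.2,  female: 6.2}
        - {min: 75, max: 80,   male: 6.8,  female: 9.2}
        - {min: 80, max: 85,   male: 11.2, female: 12.4}
        - {min: 85, max: 90,   male: 14.1, female: 15.3}
        - {min: 90, max: .inf, male: 16.4, female: 17.6}
    - name: education_level
      op: band
      field: education
      bands:   # high >= 13 y: 0; medium 8-12 y: 1.4; low <= 7 y: 2.7
        - {min: 13, max: .inf, points: 0.0}
        - {min: 8,  max: 13,   points: 1.4}
        - {min: 0,  max: 8,    points: 2.7}
    - {name: depression,           field: gds15, op: ge, cutoff: 5,  points: 2.1}
    - {name: obesity,              field: bmi,   op: ge, cutoff: 30, points: 1.6}
    - {name: physical_inactivity,  field: pase,  op: le, cutoff: 90, points: 1.1}
    - {name: hypertension,         field: hypertension,            op: flag, points: 1.6}
    - {name: hypercholesterolemia, field: hypercholesterolemia,    op: flag, points: 1.4}
    - {name: diabetes,             field: diabetes,                op: flag, points: 1.3}
    - {name: coronary_heart_disease, field: coronary_artery_disease, op: flag, points: 1.0}

mopards:
  high_risk_cutoff: 4
  factors:
    - {name: older_age,            field: age,  op: ge, cutoff: 70, points: 1}
    - {name: male_sex,             field: sex,  op: eq, cutoff: male, points: 1}
    - {name: cognitive_impairment, field: moca, op: lt, cutoff: 26, points: 1}
    - {name: orthostatic_hypotension, field: orthostatic_sbp_drop, op: gt, cutoff: 10, points: 1}
    - {name: bilateral_onset,      field: bilateral_onset, op: flag, points: 1}
    - name: falls_freezing
      op: any_of
      points: 1
      terms:
        - {field: updrs2_12_walking,  op: gt, cutoff: 1}
        - {field: updrs2_13_freezing, op: gt, cutoff: 0}
    - {name: rbd,            field: rbdsq,                   op: gt, cutoff: 5, points: 1}
    - {name: hallucinations, field: updrs1_2_hallucinations, op: gt, cutoff: 0, points: 1}

ppredict:
  high_risk_cutoff: 4
  factors:
    - {name: older_age,         field: age,              op: ge, cutoff: 65, points: 1}
    - {name: male_sex,          field: sex,              op: eq, cutoff: male, points: 1}
    - {name: nonwhite_hispanic, field: race_ethnicity,   op: eq, cutoff: nonwhite_or_hispanic, points: 1}
    - {name: lower_education,   field: education,        op: le, cutoff: 12, points: 1}
    - {name: lower_moca,        field: moca,             op: lt, cutoff: 26, points: 1}
    - {name: longer_disease_duration, field: disease_duration, op: ge, cutoff: 5, points: 1}
    - {name: rbd,               field: rbdsq,            op: ge, cutoff: 5, points: 1}
    - {name: moderate_severe_motor, field: updrs3_total, op: ge, cutoff: 32, points: 1}
    - {name: depression,        field: gds15,            op: ge, cutoff: 8, points: 1}
    - {name: anxiety,           field: stai_state,       op: ge, cutoff: 54, points: 1}
    - {name: excessive_daytime_sleepiness, field: ess,   op: ge, cutoff: 11, points: 1}
    - {name: obesity,           field: bmi,              op: ge, cutoff: 25, points: 1}
    - {name: low_physical_activity, field: pase,         op: le, cutoff: 90, points: 1}
    - name: vascular_risk
      op: count_ge
      cutoff: 2
      points: 1
      fields:
        - coronary_artery_disease
        - ischemic_stroke_tia
        - hypercholesterolemia
        - hypertension
        - diabetes
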