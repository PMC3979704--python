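cohort_size: 10000.0
combined_performance_by_cutoff:
  '150':
    detection_rate: 0.85
    false_positive_rate: 0.025
    sample_failure_rate: 0.0
    procedure_miscarriage_rate: 0.0
  '500':
    detection_rate: 0.94
    false_positive_rate: 0.07
    sample_failure_rate: 0.0
    procedure_miscarriage_rate: 0.0
  '1000':
    detection_rate: 0.96
    false_positive_rate: 0.12
    sample_failure_rate: 0.0
    procedure_miscarriage_rate: 0.0
  '2000':
    detection_rate: 0.98
    false_positive_rate: 0.19
    sample_failure_rate: 0.0
    procedure_miscarriage_rate: 0.0
quadruple_performance:
  detection_rate: 0.805
  false_positive_rate: 0.04
  sample_failure_rate: 0.0
  procedure_miscarriage_rate: 0.0
invasive_cvs:
  detection_rate: 1.0
  false_positive_rate: 0.0
  sample_failure_rate: 0.013
  procedure_miscarriage_rate: 0.005
invasive_amnio:
  detection_rate: 1.0
  false_positive_rate: 0.0
  sample_failure_rate: 0.008
  procedure_miscarriage_rate: 0.005
nipt:
  detection_rate: 0.99
  false_positive_rate: 0.01
  sample_failure_rate: 0.05
  procedure_miscarriage_rate: 0.0
nt_failure_week11: 0.14
nt_failure_week14: 0.19
vaginal_birth_fraction: 0.752
caesarean_birth_fraction: 0.248
loss_rates:
  unaffected_weeks_10_25: 0.0012
  unaffected_weeks_26_40: 0.00034
  affected_weeks_10_15: 0.07067
  affected_weeks_16_40: 0.0051
  unaffected_by_age: null
uptakes:
  screening_uptake: 0.69
  late_arrival_fraction: 0.15
  invasive_uptake_unaffected: 0.8
  invasive_uptake_affected: 0.9
  nipt_uptake_unaffected: 0.8
  nipt_uptake_affected: 0.9
  nipt_firstline_uptake: 0.69
  top_uptake: 0.921
costs:
  combined_test: 27.0
  quadruple_test: 35.0
  invasive_test: 479.0
  fetal_loss: 511.0
  top_first_trimester: 697.0
  top_second_trimester: 882.0
  vaginal_birth: 1341.0
  caesarean_birth: 2436.0
  nipt_unit_cost: 500.0
  blood_draw: 3.0
  repeat_nt: 6.5
timing:
  combined_screen_week: 12
  cvs_week: 13
  quadruple_screen_week: 16
  amnio_week: 17
  contingent_nipt_week_t1: 13
  contingent_invasive_week_t1: 14
  contingent_nipt_week_t2: 17
  contingent_invasive_week_t2: 18
  firstline_nipt_week: 11
  firstline_invasive_week: 12
  term_week: 40
  first_trimester_top_last_week: 14
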