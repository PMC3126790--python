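# Base-case parameter set for the Spanish OAB antimuscarinic cost-effectiveness model.
# Probability-like quantities are written as percentages with the source's two-decimal
# precision; the loader converts them to fractions. Monetary values are 2010 euros.

efficacy:
  placebo:
    start_dose: std
    doses:
      std:
        response_w2: 20.99
        response_w8: 34.66
        response_w12: 27.84
        cond_w12_given_w8resp: 80.33
        cond_w12_given_w8nonresp: 14.16
        nocturia_resolution_w12: 54.34
        constipation_rate: 1.99
  fesoterodine:
    start_dose: 4mg
    high_dose: 8mg
    doses:
      4mg:
        response_w2: 30.41
        response_w8: 50.00
        response_w12: 43.67
        cond_w12_given_w8resp: 87.34
        cond_w12_given_w8nonresp: 21.05
        nocturia_resolution_w12: 55.56
        constipation_rate: 4.15
      8mg:
        response_w2: 40.59
        response_w8: 55.38
        response_w12: 50.21
        cond_w12_given_w8resp: 90.65
        cond_w12_given_w8nonresp: 24.20
        nocturia_resolution_w12: 55.90
        constipation_rate: 6.01
  tolterodine:
    start_dose: 4mg
    doses:
      4mg:
        response_w2: 29.23
        response_w8: 49.47
        response_w12: 38.18
        cond_w12_given_w8resp: 77.17
        cond_w12_given_w8nonresp: 13.04
        nocturia_resolution_w12: 57.69
        constipation_rate: 2.76
  solifenacin:
    start_dose: 5mg
    high_dose: 10mg
    doses:
      5mg:
        # derived from the placebo row with a relative risk of 1.50;
        # the week-12-given-week-8 conditional is taken equal to placebo
        response_w2: 31.49
        response_w8: 51.99
        response_w12: 41.76
        cond_w12_given_w8resp: 80.33
        cond_w12_given_w8nonresp: 21.24
        nocturia_resolution_w12: 54.34
        constipation_rate: 3.53
      10mg:
        # source prints these cells directly (stated relative risk 1.53)
        response_w2: 32.11
        response_w8: 53.01
        response_w12: 42.58
        cond_w12_given_w8resp: 80.33
        cond_w12_given_w8nonresp: 21.66
        nocturia_resolution_w12: 88.72
        constipation_rate: 7.72

# fraction of starters still on therapy (percent); per-arm values to week 8,
# shared placebo curve from week 12 onwards
persistence:
  placebo: {2: 100.0, 8: 92.84}
  fesoterodine: {2: 100.0, 8: 92.67}
  tolterodine: {2: 100.0, 8: 95.76}
  solifenacin: {2: 100.0, 8: 94.06}
shared_persistence: {12: 90.64, 24: 79.32, 52: 59.27}

# week-4 dose-escalation policy (percent of each week-8-proxy response group
# that moves to the high dose); zero for single-dose arms
titration:
  placebo: {frac_responders_titrate: 0.0, frac_nonresponders_titrate: 0.0}
  fesoterodine: {frac_responders_titrate: 50.0, frac_nonresponders_titrate: 50.0}
  tolterodine: {frac_responders_titrate: 0.0, frac_nonresponders_titrate: 0.0}
  solifenacin: {frac_responders_titrate: 50.0, frac_nonresponders_titrate: 50.0}

unit_costs:
  pad: 0.58
  gp_visit: 26.78
  specialist_visit: 58.60
  lab_test: 2.56
  constipation_per_day: 0.16
  fracture_event: 5742.8
  skin_infection_episode: 53.1
  uti_episode: 53.1
  depression_per_patient_year: 2699.0
  nursing_home: 14831.4
  drug_per_day:
    placebo: {std: 0.0}
    fesoterodine: {4mg: 1.70, 8mg: 2.72}
    tolterodine: {4mg: 1.70}
    solifenacin: {5mg: 1.67, 10mg: 2.67}

# status-conditional utilization (percent for pad use; counts otherwise)
resource_use:
  controlled:
    frac_using_pads: 0.0
    pads_per_day: 0.0
    gp_visits_per_month: 0.133
    specialist_visits_per_month: 0.117
    lab_tests_per_month: 0.033
  uncontrolled_on_rx:
    frac_using_pads: 67.0
    pads_per_day: 4.23
    gp_visits_per_month: 0.2
    specialist_visits_per_month: 0.15
    lab_tests_per_month: 0.078
  untreated:
    frac_using_pads: 67.0
    pads_per_day: 4.23
    gp_visits_per_month: 0.2
    specialist_visits_per_month: 0.15
    lab_tests_per_month: 0.078

# probabilities over a 6-month window unless stated otherwise (percent);
# skin/UTI expected events per person over the same window
comorbidity:
  controlled:
    fracture_prob_6mo: 2.5
    skin_prob_6mo: 10.7
    skin_events_per_person: 0.3
    uti_prob_6mo: 19.0
    uti_events_per_person: 0.3
    depression_prob_annual: 8.08
    nursing_home_admissions_per_1000py: 29.5
  uncontrolled_on_rx:
    fracture_prob_6mo: 5.3
    skin_prob_6mo: 9.3
    skin_events_per_person: 0.6
    uti_prob_6mo: 30.7
    uti_events_per_person: 0.7
    depression_prob_annual: 18.84
    nursing_home_admissions_per_1000py: 78.3
  untreated:
    fracture_prob_6mo: 5.3
    skin_prob_6mo: 9.3
    skin_events_per_person: 0.6
    uti_prob_6mo: 30.7
    uti_events_per_person: 0.7
    depression_prob_annual: 18.84
    nursing_home_admissions_per_1000py: 78.3
depression_by_sex:
  frac_female: 80.87
  controlled: {women: 9.10, men: 4.30}
  uncontrolled: {women: 18.90, men: 18.60}
nursing_home_by_sex:
  frac_female: 80.87
  controlled: {women: 31.0, men: 24.0}
  uncontrolled: {women: 73.0, men: 98.0}
# percent decrease in state utility while the condition is present;
# the nursing-home decrement is asterisked but never given a value in the source
utility_decrements:
  fracture: 4.0
  depression: 48.0
  nursing_home: null

# preference-based state utilities (dimensionless)
utilities:
  continent: 0.9569
  incontinent_on_rx: 0.9412
  untreated: 0.9332

productivity:
  wage_per_hour: 13.51
  hours_per_week: 40.0
  frac_employed: 59.83
  incontinence_hours_reduction: 21.1
  hours_reduction_female: 8.0
  hours_reduction_male: 21.0
  frac_female: 80.87
  hours_reduction_mode: sex_weighted
  nocturia_impairment: 9.2
  baseline_nocturia_prevalence: 48.58

settings:
  horizon_weeks: 52
  perspective: societal
  decrements_enabled: false
  annualization_factor: 2.0
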