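# Baseline calibration of the cardiothoracic-department flow model.
#
# Durations are hours, probabilities are per patient, costs are USD
# (Omani Rial * 2.56).  Week starts on Sunday: or_days 0-3 = Sun-Wed.
#
# Parameter-order conventions (the source calibration table prints bare
# number lists; the readings below are a deliberate choice, overridable
# per spec):
#   beta_scaled:              (shape1, shape2, min, max)
#   weibull_shifted / gamma_shifted: (offset, shape, scale)
#     -- 121 h appears as the common lower bound of all four postoperative
#        LOS rows, hence the leading value is read as an offset.
#   "Arrival of non-surgical patients admitted to CICU: 55, Poisson" is
#     read as a Poisson process with mean inter-arrival 55 h (parallel to
#     the referral inter-arrival row); this reproduces the published
#     baseline CICU and overall bed-turnover figures, which the
#     arrivals-per-year reading cannot.
cicu_beds: 5
ward_beds: 18
or_days: [0, 1, 2, 3]
or_session_start: 8.0
or_session_end: 14.5
electives_per_day: 1
one_surgery_per_day: true
referral_interarrival: {family: exponential_interarrival, params: [33.0]}
nonsurgical_cicu_interarrival: {family: exponential_interarrival, params: [55.0]}
# Elective / non-elective referral split is not published; 0.15 is a
# calibration knob.
nonelective_share: 0.15
# Fraction of referrals accepted onto the surgical pathway (the rest
# decline, are found unfit, or are referred on before admission).  A
# calibration knob: the printed 33 h referral gap (~265/year) cannot be
# reconciled with the department's yearly surgical volume without
# pre-admission attrition.
referral_acceptance: 0.78
pct_admitted_not_operated: 0.10
reoperation_prob: 0.04
# Elective patients wait at home and are admitted a few days before
# surgery; at most this many occupy preoperative ward beds at once.
preop_admission_buffer: 5
complication_any_prob: 0.48
cicu_location_share: 0.40
allow_multiple_complications: false
negative_excess_as_zero: true
preop_los: {family: beta_scaled, params: [1.61, 1.3, 75.0, 152.0]}
cicu_los: {family: beta_scaled, params: [1.04, 1.6, 48.0, 111.0]}
# Non-surgical CICU admissions (follow-up / monitoring) are short
# observation stays; no LOS was published for them.
nonsurgical_cicu_los: {family: triangular, params: [12.0, 24.0, 48.0]}
surgery_duration: {family: triangular, params: [2.5, 2.8, 6.0]}
postop_los_by_surgery_type:
  isolated_cabg: {family: beta_scaled, params: [0.87, 1.65, 121.0, 577.0]}
  isolated_valve: {family: beta_scaled, params: [1.0, 2.21, 121.0, 685.0]}
  cabg_valve: {family: weibull_shifted, params: [121.0, 1.48, 199.0]}
  other: {family: gamma_shifted, params: [121.0, 1.56, 90.0]}
# Surgery-type mix is not published; affects only which postoperative LOS
# distribution is drawn.
surgery_type_mix:
  isolated_cabg: 0.60
  isolated_valve: 0.20
  cabg_valve: 0.10
  other: 0.10
min_cicu_hours: 48.0
ward_postop_scale: 1.0
# Patients fit for transfer leave the CICU at the daily 07:00 discharge
# round (beds free up before the theatre's 08:00 CICU check).
transfer_round_hour: 7.0
# A cancelled elective case is rescheduled a few days later rather than
# re-attempted every morning.
cancellation_reschedule_days: 10.0
# Staffed nursing capacity (patients per shift); units staff below bed
# count, so nurse utilisation runs above bed occupancy.
cicu_nursing_capacity: 4
ward_nursing_capacity: 13
currency_factor: 2.56
lost_days_divisor: 23
mortality_enabled: false
mortality_prob: 0.04
# Complication table: prevalence (fraction of all patients), excess LOS
# (marginal effect on postoperative LOS, days) and marginal charge (USD).
# Prevalences marked "unpublished" are defaults chosen so that the
# pulmonary / infection / neurological category rates land near 17 / 16 /
# 9.5 % and "other pulmonary" is ~4.5 % of all complication events; the
# published individual cardiac prevalences already exceed the published
# 26 % category rate, so the cardiac category is over by construction.
complications:
  - {name: "Ventricular arrhythmia", category: cardiac, prevalence: 0.16,
     excess_los_days: 0.9, marginal_cost_usd: 170.01, cicu_only: false, significant: true}
  - {name: "Cardiac arrest", category: cardiac, prevalence: 0.015,  # unpublished
     excess_los_days: -1.59, marginal_cost_usd: 950.91, cicu_only: false, significant: true}
  - {name: "New atrial arrhythmia", category: cardiac, prevalence: 0.155,
     excess_los_days: 0.27, marginal_cost_usd: 70.07, cicu_only: false, significant: false}
  - {name: "Other cardiac complications", category: cardiac, prevalence: 0.02,  # unpublished
     excess_los_days: 2.28, marginal_cost_usd: 1054.62, cicu_only: false, significant: true}
  - {name: "Stroke permanent", category: neurological, prevalence: 0.06,
     excess_los_days: 22.96, marginal_cost_usd: 3210.55, cicu_only: false, significant: true}
  - {name: "Neuro psychiatry", category: neurological, prevalence: 0.018,  # unpublished
     excess_los_days: -0.59, marginal_cost_usd: 204.34, cicu_only: false, significant: false}
  - {name: "Other neurological complications", category: neurological, prevalence: 0.02,  # unpublished
     excess_los_days: 2.94, marginal_cost_usd: 709.91, cicu_only: false, significant: true}
  - {name: "Prolonged ventilation >24 h", category: pulmonary, prevalence: 0.125,
     excess_los_days: 4.70, marginal_cost_usd: 1057.48, cicu_only: true, significant: true}
  - {name: "Pneumonia", category: pulmonary, prevalence: 0.022,  # unpublished
     excess_los_days: 6.33, marginal_cost_usd: 733.85, cicu_only: false, significant: true}
  - {name: "Other pulmonary complications", category: pulmonary, prevalence: 0.036,  # unpublished
     excess_los_days: 11.34, marginal_cost_usd: 2452.22, cicu_only: false, significant: true}
  - {name: "Sternal deep", category: infection, prevalence: 0.04,  # unpublished
     excess_los_days: 4.30, marginal_cost_usd: 516.02, cicu_only: false, significant: true}
  - {name: "Septicaemia", category: infection, prevalence: 0.02,  # unpublished
     excess_los_days: 22.90, marginal_cost_usd: 2456.99, cicu_only: false, significant: true}
  - {name: "Leg wound", category: infection, prevalence: 0.03,  # unpublished
     excess_los_days: 3.09, marginal_cost_usd: 598.71, cicu_only: false, significant: true}
  - {name: "Sternal superficial", category: infection, prevalence: 0.035,  # unpublished
     excess_los_days: 4.11, marginal_cost_usd: 169.24, cicu_only: false, significant: true}
  - {name: "Other infection", category: infection, prevalence: 0.045,  # unpublished
     excess_los_days: 5.19, marginal_cost_usd: 224.92, cicu_only: false, significant: true}
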