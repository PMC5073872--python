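# Methods

## The system being modelled

A cardiothoracic surgical department with one dedicated operating theatre,
a 5-bed cardiac intensive care unit (CICU) and an 18-bed ward. Elective
sessions run Sunday–Wednesday 08:00–14:30 with a single case per day;
in-call staff operate emergencies on any day, one surgery per calendar day
in total, with emergencies taking priority and being operated the day
after they become ready. No surgery may start unless a CICU bed is free;
postoperative patients stay in the CICU at least 48 h, then transfer to
the ward, blocking their CICU bed whenever the ward is full. Non-surgical
patients compete for CICU beds. Time is continuous, in hours, with
simulation time 0 at a Sunday midnight.

Complications enter as *excess length of stay*: an operated patient
becomes "complicated" with probability 0.48; a complicated patient draws
one complication type with probability proportional to its per-patient
prevalence; the type's marginal effect (days × 24 h) is appended to the
end of the stay at its assigned location — CICU with probability 0.40,
ward otherwise, except prolonged ventilation, which is always CICU. The
excess time is what blocks beds and, through the CICU gate, cancels and
delays surgeries.

### One complication per patient

The published prevalence table cannot be realised as independent
per-patient indicators together with an any-complication rate of 48 % (the
individual rates alone imply ~57 % under independence, and the individual
cardiac prevalences of 16 % + 15.5 % already exceed the 26 % cardiac
category rate). The flow model therefore assigns at most one complication
per operated patient — the gate (48 %) times a type draw proportional to
prevalence — which reproduces the any-complication rate exactly and is
how single-profile entity attributes behave in classical DES packages. A
config flag (`allow_multiple_complications`) switches to gated independent
flags for sensitivity analysis. Note the synthetic *cohort* generator, by
contrast, uses independent flags (see below): the regression stage needs
per-type marginal variation, the flow stage needs the correct total
burden.

## Input parameters

All durations in hours; probabilities per patient; costs in USD (fixed
conversion factor 2.56 from the local currency).

| Parameter | Default | Source/why |
|---|---|---|
| Referral inter-arrival | exponential, mean 33 | published calibration table |
| Non-surgical CICU inter-arrival | exponential, mean 55 | published "55, Poisson", read as inter-arrival hours: this reproduces the published CICU bed turnover (≈60.8 ≙ ~300 CICU departures/yr) and overall turnover (15.66 ≙ ~360 discharges/yr); an arrivals-per-year reading gives turnover ≈46 and cannot |
| Preoperative LOS | Beta(1.61, 1.3) scaled to [75, 152] | published; mean ≈ 4.9 d, matching the department's ~5-day preoperative stays |
| CICU LOS (postoperative) | Beta(1.04, 1.6) scaled to [48, 111] | published; min stay 48 h enforced |
| Postoperative LOS by surgery type | Beta/Weibull/Gamma per type | published; the Weibull "121, 1.48, 199" and Gamma "121, 1.56, 90" rows are read as (offset, shape, scale) because 121 h is the common lower bound of all four rows |
| Surgery duration | Triangular(2.5, 2.8, 6) | published |
| Reoperation probability | 0.04 | published; reoperations occur within 24 h, outrank electives, keep the CICU bed, and redraw the CICU stay |
| Admitted but never operated | 0.10 | published |
| Complication prevalences/effects/costs | 15-type table | published where printed; unpublished prevalences chosen so pulmonary/infection/neurological category rates land near 17/16/9.5 % and "other pulmonary" ≈ 4.5 % of complication events |
| Non-elective referral share | 0.15 | not published; calibration knob |
| Referral acceptance | 0.78 | not published; see calibration below |
| Preop admission buffer | 5 patients | structural, see below |
| Cancelled-case rebooking delay | 10 d | structural, see below |
| Non-surgical CICU LOS | Triangular(12, 24, 48) | not published; observation stays |
| Nursing capacity (CICU/ward) | 4 / 13 patients per shift | staffing levels below bed count; see "interpretation choices" |

## Structural choices the published description does not fix

* **Pull-based elective admission.** Elective patients wait at home and
  are admitted a few days before surgery. Mechanically, at most
  `preop_admission_buffer` electives occupy preoperative ward beds at any
  time; the next admission is pulled when one leaves. Admitting every
  referral on arrival is not a viable alternative: the ward fills with
  waiting patients, CICU transfers block, and the ward–CICU loop
  deadlocks the whole department.
* **Referral acceptance (0.78).** The published referral gap (33 h ≈ 265
  referrals/yr) exceeds any plausible yearly surgical volume of this
  department (~174 simulated, 164 historical completed surgeries plus 10 %
  admitted-not-operated). Without pre-admission attrition the waiting
  list grows without bound (~60 patients/yr). The acceptance fraction
  models referrals that decline, are found unfit, or are referred on
  before admission.
* **Morning discharge round.** CICU patients fit for transfer leave at a
  daily 07:00 round, so beds free up before the theatre's 08:00 CICU
  check — standard ICU practice, and necessary to keep the
  cancellation count near the published level.
* **Rebooking after cancellation.** A cancelled elective case is
  rescheduled ~10 days later (with precedence when it returns) rather
  than re-attempted every morning.
* **Cancellation accounting.** A cancellation is recorded when a selected
  patient stays blocked behind a full CICU for a whole in-hours session.
  The cause is `complication` when a CICU occupant is serving
  complication-attributable excess time at session close, `no_cicu_bed`
  otherwise. The published "surgery cancellations" figure is mapped to
  the complication-caused count: the published four-condition rule
  requires a complicated CICU occupant, and the published
  no-complication scenario reports exactly zero cancellations, which only
  that reading reproduces.
* **Waiting time** runs from ready-for-surgery (end of preoperative
  assessment) to theatre entry, over elective cases: emergencies are
  operated next-day by rule and are not "scheduled" cases. The waiting
  *list* counts all surgical patients from referral to theatre.
* **Nurse utilisation** is the time-average patient census divided by the
  staffed nursing capacity (CICU 4, ward 13 patients per shift), not by
  bed count. The published ~83 % CICU "utilisation" is irreconcilable
  with the published turnover and single-digit yearly cancellations if
  read as bed occupancy (a 5-bed unit at 83 % occupancy is full at the
  morning check roughly every third day); as census over a 4-patient
  nursing roster the same published value emerges from the model's ~3.2
  average census.

### Calibration

The free knobs above (acceptance fraction, non-elective share,
buffer, rebooking delay, non-surgical LOS) were calibrated once against
the published baseline operating point — throughput ≈ 174/yr,
cancellations ≈ 9/yr, surgery waiting ≈ 5 d, waiting list ≈ 23, CICU bed
turnover ≈ 60.8, overall ≈ 15.7 — and then frozen in
`src/cardioflow/data/default_config.yaml`. Everything printed in the
source tables (capacities, schedules, LOS distributions, prevalences,
marginal effects, costs) is transcribed, not calibrated.

## Attribution stage

`fit_count_model` fits the log-link Poisson model by standard IRLS
(deviance tolerance 1e-8, ≤100 iterations, via statsmodels GLM); standard
errors come from the observed information matrix (no robust/sandwich
option — the original analysis does not state which it used). Marginal
effects at the means evaluate `exp(η)` at the two settings of one binary
covariate with all others at their sample means. Two-sided Wald p-values;
effects with `p ≥ 0.05` are exported to the flow model as zero excess
(the published table's two non-significant complications — new atrial
arrhythmia and neuro-psychiatry — ship that way). A covariate with no
variation is reported *not estimable*, never zero. The published negative
effect for cardiac arrest (−1.59 d) is also applied as zero excess in the
flow model: a negative bed-time credit has no physical meaning there
(`negative_excess_as_zero` restores it for the regression only).

## Synthetic cohort

The generator emulates the 600-patient cohort the attribution analysis
was derived from: independent complication indicators, Poisson LOS counts
around `exp(1.78 + Σ β_k x_k)` with the published coefficients, charges
as a base fee plus published marginal costs plus Gaussian noise.
Because independence of the published individual prevalences would imply
~57 % of patients with at least one complication, the *unpublished*
prevalences are shrunk by a common factor (solved by bisection at truth
construction) until the any-complication rate is exactly 0.48; the
published individual prevalences are kept exact. Demographic covariates
(age ≈ rounded N(60, 10²), sex Bernoulli 0.7, comorbidities
Bernoulli 0.3) are plumbing with zero generating coefficients.

What the cohort does *not* emulate, and hence what passing tests do not
show about real data: complication co-occurrence (real patients have
correlated adverse events), confounding between risk factors and
complications (zero adjuster coefficients by construction), over-dispersion
(a negative-binomial knob exists but defaults off), and the registry's
real covariate distributions. Parameter-recovery results therefore
certify the estimator, not the epidemiology.

## Output analysis

30 replications; statistics collected over one simulated year after a
fixed 6-month warm-up (the original study chose its warm-up by visual
inspection of a waiting-time series, which is not faithfully automatable;
an MSER helper is provided for inspection but never applied silently).
Per-KPI summaries are replicate means with 95 % Student-t intervals
(n−1 df). Replicate *i* of every scenario derives its named random
substreams (arrivals, per-patient attributes, …) from the same
`(master seed, i)` pair, giving common random numbers across scenarios;
every patient's full set of draws is made at arrival in a fixed order, so
a scenario change never desynchronises the streams. Excess stay
straddling the measurement boundary is pro-rated. Event-calendar ties
break by global insertion order, making runs bit-reproducible for a given
seed on any platform.

Degenerate inputs are defined rather than accidental: zero discharges give
turnover 0; utilisation ratio raises on u ≥ 1; an empty operated-patient
set reports waiting time as not-available (NaN); a complication that
never occurs in a cohort is not estimable; `n = 0` cohorts are empty, not
errors.

## Known limitations and discrepancies

* With the published inputs (prevalences × marginal effects), the
  expected complication-attributable excess is ≈ 2.3 bed-days per operated
  patient, i.e. ≈ 410–440 lost bed-days per year at the baseline volume —
  about a third above the ≈ 310 the original study reports (whose own
  figures are loose here: 310 total vs "15 days per bed" × 23 beds =
  345). No prevalence choice consistent with the published individual
  and category rates brings the expectation below ≈ 350. The package
  reports what it computes.
* The published no-complication scenario reports waiting times of
  ≈ 1.36 d and ≈ 23 extra surgeries. In this model the elective gap from
  readiness to the next Sunday–Wednesday session alone averages ≈ 1.8 d,
  and with a demand-limited baseline the recoverable throughput is a few
  surgeries, not 23; the corresponding waiting-time reduction is ≈ −20 %
  rather than ≈ −73 %. Reproducing those published values would require a
  capacity-limited baseline, which contradicts the published baseline
  waiting time and list size under the published arrival process.
* The published utilisation-ratio example (0.82/(1−0.82) printed as 5.55)
  is arithmetically inconsistent with its own formula (= 4.556); the
  implementation follows the formula.
* Mortality is disabled by default (the original study found a negligible
  resource-utilisation impact); a flag removes patients at CICU exit when
  enabled. The urgent tier between elective and emergency, the
  catheterisation laboratory, staff rosters and itemised billing are out
  of scope.
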