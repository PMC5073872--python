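# cardioflow

Discrete-event simulation of patient flow through a cardiothoracic
surgical department in which postoperative complications inflate length of
stay (LOS) and thereby degrade operational performance — surgery
cancellations, waiting times, bed turnover, throughput and cost — together
with the Poisson marginal-effects analysis that supplies the
complication-attributable excess-LOS and cost inputs.

The package is for health-services and operations researchers who want to
quantify how adverse events propagate through a capacity-constrained
surgical pathway: a single operating theatre (elective sessions
Sunday–Wednesday 08:00–14:30, one case per day), a 5-bed cardiac intensive
care unit (CICU) whose free bed is a precondition for starting any
surgery, and an 18-bed ward. Complication-attributable excess stay blocks
beds, the blocked beds gate the theatre, and the model measures the
downstream damage.

## The model

**Attribution stage.** Postoperative LOS (a day count, heavily skewed) is
modelled by Poisson regression with log link,

    log E[LOS_i] = β₀ + Σ_k β_k x_ik,

where the `x_ik` are binary complication indicators plus demographic,
comorbidity and surgery-type adjusters. The excess stay attributable to a
complication is its *marginal effect at the means* (MEM): for a binary
covariate `x_k`,

    MEM_k = exp(η | x_k = 1) − exp(η | x_k = 0),

with every other covariate held at its sample mean. Effects with
two-sided Wald `p ≥ 0.05` are treated as zero excess. The same machinery
applied to hospital charges yields marginal costs. Because the clinical
registry behind the original analysis is not public, a synthetic-cohort
generator (`cardioflow.cohort`) reproduces its statistical structure
(600 patients, 48 % with at least one complication, the published
prevalences and log-scale coefficients) so the attribution stage is fully
testable.

**Flow stage.** A deterministic event-calendar kernel
(`cardioflow.engine`) drives the department model (`cardioflow.hospital`):
Poisson referral arrivals (mean gap 33 h), preoperative ward stay,
priority rules (emergencies > reoperations > electives), the CICU gate
with the four-condition cancellation rule, a 48 h minimum CICU stay,
surgery-type-specific postoperative LOS, and complication assignment
(48 % of operated patients; type drawn in proportion to prevalence; the
excess stay `24 × MEM_k` hours appended in the CICU with probability 0.40,
else in the ward). Key outcome formulas:

    bed turnover      = discharges (incl. deaths) / average bed count
    utilisation ratio = u / (1 − u)
    lost bed days     = Σ complication-attributable excess stay (days)

Experiments (`cardioflow.experiments`) run 30 replications of one
simulated year after a 6-month warm-up and compare scenarios (eliminating
all complications, infections only, or the high-cost subset; an extra
theatre day; an extra CICU bed; 40 % shorter ward stays; halving
septicaemia) under common random numbers.

## Worked example

```python
from cardioflow import default_config, apply_scenario, run_replications

base = run_replications(default_config(), n_reps=30, seed=42)
none = run_replications(apply_scenario(default_config(), "no_complications"),
                        n_reps=30, seed=42)
for kpi in ("throughput", "mean_surgery_waiting_time_days",
            "cancellations_complication", "lost_bed_days"):
    lo, hi = base.ci95(kpi)
    print(f"{kpi:32s} {base.mean(kpi):8.2f} (95% CI {lo:.2f}-{hi:.2f})"
          f"   -> without complications {none.mean(kpi):8.2f}")
```

prints (seed 42):

```
throughput                         183.73 (95% CI 178.53-188.94)   -> without complications   184.47
mean_surgery_waiting_time_days       4.12 (95% CI 3.81-4.43)   -> without complications     3.44
cancellations_complication           8.30 (95% CI 6.69-9.91)   -> without complications     0.00
lost_bed_days                      411.37 (95% CI 384.50-438.25)   -> without complications     0.00
```

Read: under the baseline calibration the department completes ~184
surgeries a year while complications cancel ~8 scheduled cases, hold
scheduled patients ~4 days from readiness to theatre, and consume ~410
bed-days of capacity; eliminating complications removes the cancellations
and the lost bed-days entirely.

The same analyses are packaged as narrative drivers under `analysis/`
(`01_fit_excess_los.py` → attribution tables, `02_baseline_simulation.py`
→ baseline KPIs, `03_scenario_experiments.py` → scenario comparisons,
`04_validation.py` → t-tests against historical indicators), each writing
its tables under `results/`. A CLI is also available:
`cardioflow --scenario all --reps 30 --seed 42 --out out/`.

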