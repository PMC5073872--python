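"""Replicated scenario experiments over the department model.

The experiment protocol: each configuration is replicated (30 runs by
default) over a 6-month warm-up plus 1 simulated year of measurement, and
each KPI is summarised by its replicate mean with a 95 % t-interval.
Scenario variants reuse the same replicate seeds, and the model draws all
of a patient's randomness from per-patient substreams, so comparisons run
under common random numbers.

Scenarios (the capacity-planning questions the model answers):

``no_complications``   every complication eliminated — bounds the burden
``no_infections``      infection-category complications eliminated
``no_high_cost``       complications with marginal charge at or above the
                       75th-percentile cut-off (1057.48 USD) eliminated:
                       permanent stroke, prolonged ventilation >24 h,
                       other pulmonary complications, septicaemia
``more_or_days``       one extra elective theatre day per week (Sun–Thu)
``extra_cicu_bed``     CICU capacity 5 → 6
``shorter_ward_los``   ward postoperative stay reduced by 40 %
``septicaemia_half``   septicaemia prevalence halved

Eliminating a complication type removes exactly that type's probability
mass: the per-patient assignment chance of every surviving type is
unchanged (the any-complication gate is rescaled accordingly), so the
overall complication rate falls by the removed share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ComplicationSpec, SystemConfig
from .hospital import run_single
from .kpis import compute_kpis

__all__ = [
    "SCENARIO_IDS",
    "HIGH_COST_NAMES",
    "ReplicationSummary",
    "ValidationResult",
    "apply_scenario",
    "run_replications",
    "compare_scenarios",
    "validate_against_history",
    "mser_warmup",
    "DEFAULT_WARMUP_HOURS",
    "DEFAULT_HORIZON_HOURS",
]

DEFAULT_WARMUP_HOURS = 6 * 730.0  # six months
DEFAULT_MEASURE_HOURS = 8760.0  # one year
DEFAULT_HORIZON_HOURS = DEFAULT_WARMUP_HOURS + DEFAULT_MEASURE_HOURS

HIGH_COST_NAMES = frozenset({
    "Stroke permanent",
    "Prolonged ventilation >24 h",
    "Other pulmonary complications",
    "Septicaemia",
})

SCENARIO_IDS = (
    "baseline", "no_complications", "no_infections", "no_high_cost",
    "more_or_days", "extra_cicu_bed", "shorter_ward_los", "septicaemia_half",
)


def _scale_prevalences(config: SystemConfig, factor_for) -> SystemConfig:
    """Scale selected complication prevalences and rescale the
    any-complication gate so untouched types keep their absolute
    per-patient assignment probability."""
    old_total = sum(c.prevalence for c in config.complications)
    new_comps = []
    for c in config.complications:
        f = factor_for(c)
        new_comps.append(c if f == 1.0 else
                         ComplicationSpec(**{**c.to_dict(), "prevalence": c.prevalence * f}))
    new_total = sum(c.prevalence for c in new_comps)
    any_prob = (config.complication_any_prob * new_total / old_total
                if old_total > 0 else 0.0)
    return config.with_updates(complications=tuple(new_comps),
                               complication_any_prob=any_prob)


def apply_scenario(base: SystemConfig, scenario_id: str) -> SystemConfig:
    if scenario_id == "baseline":
        return base
    if scenario_id == "no_complications":
        return _scale_prevalences(base, lambda c: 0.0)
    if scenario_id == "no_infections":
        return _scale_prevalences(base, lambda c: 0.0 if c.category == "infection" else 1.0)
    if scenario_id == "no_high_cost":
        return _scale_prevalences(base, lambda c: 0.0 if c.name in HIGH_COST_NAMES else 1.0)
    if scenario_id == "more_or_days":
        return base.with_updates(or_days=tuple(sorted(set(base.or_days) | {4})))
    if scenario_id == "extra_cicu_bed":
        return base.with_updates(cicu_beds=base.cicu_beds + 1)
    if scenario_id == "shorter_ward_los":
        return base.with_updates(ward_postop_scale=base.ward_postop_scale * 0.6)
    if scenario_id == "septicaemia_half":
        return _scale_prevalences(base, lambda c: 0.5 if c.name == "Septicaemia" else 1.0)
    raise ValueError(f"unknown scenario {scenario_id!r}; expected one of {SCENARIO_IDS}")


# ---------------------------------------------------------------------------
@dataclass
class ReplicationSummary:
    """Across-replication statistics: per-KPI mean, sd and 95 % t-interval."""

    per_replication: pd.DataFrame  # one row per replication
    n_replications: int

    def mean(self, kpi: str) -> float:
        return float(self.per_replication[kpi].mean())

    def sd(self, kpi: str) -> float:
        return float(self.per_replication[kpi].std(ddof=1))

    def ci95(self, kpi: str) -> tuple[float, float]:
        n = self.n_replications
        m, s = self.mean(kpi), self.sd(kpi)
        half = stats.t.ppf(0.975, n - 1) * s / math.sqrt(n)
        return (m - half, m + half)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for kpi in self.per_replication.columns:
            lo, hi = self.ci95(kpi)
            rows.append({"kpi": kpi, "mean": self.mean(kpi), "sd": self.sd(kpi),
                         "lo95": lo, "hi95": hi, "n": self.n_replications})
        return pd.DataFrame(rows).set_index("kpi")


def replicate_seed(master_seed: int, rep: int) -> int:
    return (int(master_seed) * 1_000_003 + rep) % (2**31)


def run_replications(config: SystemConfig, n_reps: int = 30,
                     warmup_hours: float = DEFAULT_WARMUP_HOURS,
                     horizon_hours: float = DEFAULT_HORIZON_HOURS,
                     seed: int = 0) -> ReplicationSummary:
    """Independent replications with statistics collected after warm-up.

    Replicate ``i`` of every scenario derives its streams from
    ``replicate_seed(seed, i)``, giving common random numbers across
    scenario variants.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replications for a t-interval")
    if horizon_hours <= warmup_hours:
        raise ValueError("horizon must exceed the warm-up period")
    rows = []
    for rep in range(n_reps):
        model = run_single(config, replicate_seed(seed, rep), horizon_hours)
        report = compute_kpis(model, warmup_hours, horizon_hours)
        rows.append(report.to_dict())
    return ReplicationSummary(per_replication=pd.DataFrame(rows), n_replications=n_reps)


def compare_scenarios(summary_a: ReplicationSummary,
                      summary_b: ReplicationSummary) -> pd.DataFrame:
    """Per-KPI percentage change of b's replicate mean relative to a's
    (negative = reduction); NaN where a's mean is zero."""
    kpis = summary_a.per_replication.columns
    if list(kpis) != list(summary_b.per_replication.columns):
        raise ValueError("summaries cover different KPI sets")
    rows = []
    for kpi in kpis:
        a, b = summary_a.mean(kpi), summary_b.mean(kpi)
        change = (b - a) / a * 100.0 if a != 0 else math.nan
        rows.append({"kpi": kpi, "mean_a": a, "mean_b": b, "pct_change": change})
    return pd.DataFrame(rows).set_index("kpi")


# ---------------------------------------------------------------------------
@dataclass
class ValidationResult:
    indicator: str
    observed: float
    simulated_mean: float
    t_statistic: float
    p_value: float
    variance_pct: float
    decision: str  # accept | reject (two-tailed t-test at alpha = 0.05)


def validate_against_history(indicator: str, observed: float,
                             samples, alpha: float = 0.05) -> ValidationResult:
    """One-sample two-tailed t-test of replicate mean vs a historical value.

    ``variance_pct`` is the relative discrepancy (sim − obs)/obs × 100.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicate samples")
    mean = float(x.mean())
    if x.std(ddof=1) == 0.0:
        if mean == observed:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.inf, 0.0
    else:
        t_stat, p = stats.ttest_1samp(x, observed)
        t_stat, p = float(t_stat), float(p)
    variance_pct = (mean - observed) / observed * 100.0
    return ValidationResult(
        indicator=indicator, observed=observed, simulated_mean=mean,
        t_statistic=t_stat, p_value=p, variance_pct=variance_pct,
        decision="accept" if p >= alpha else "reject",
    )


def mser_warmup(series, batch: int = 5) -> int:
    """MSER truncation point of a time series (index into *series*).

    An inspection aid for choosing the warm-up period; the experiment
    protocol uses the fixed 6-month warm-up and never applies this
    automatically.
    """
    x = np.asarray(series, dtype=float)
    nb = len(x) // batch
    if nb < 3:
        return 0
    means = x[: nb * batch].reshape(nb, batch).mean(axis=1)
    best, best_d = math.inf, 0
    for d in range(nb - 2):
        tail = means[d:]
        se = tail.std(ddof=0) / math.sqrt(len(tail))
        if se < best:
            best, best_d = se, d
    return best_d * batch
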