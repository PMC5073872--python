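"""Operational outcome measures computed from a finished replication.

Every measure is evaluated over a measurement window ``[t0, t1]`` (hours),
which in replicated experiments excludes the warm-up period.  Conventions:

* **Bed turnover** = departures (including deaths) during the window
  divided by the average bed count — the classical productivity ratio.
* **Lost bed days** = complication-attributable excess stay, in bed-days,
  served inside the window (excess sits at the end of each location stay
  and is pro-rated at the window boundaries).
* **Waiting time** for surgery runs from ready-for-surgery (end of the
  preoperative assessment) to theatre entry; the waiting-list size is the
  time-average number of referred surgical patients not yet operated.
* **Nurse utilisation** equals the time-average patient census divided by
  the staffed nursing capacity (patients per shift the roster can carry;
  units routinely staff below bed count, so this runs above bed
  occupancy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import SystemConfig

__all__ = [
    "KPIReport",
    "bed_turnover",
    "utilisation_ratio",
    "lost_bed_days",
    "waiting_metrics",
    "complication_cost",
    "time_average",
    "compute_kpis",
]


@dataclass
class KPIReport:
    mean_surgery_waiting_time_days: float
    time_avg_waiting_list_size: float
    throughput: int
    cancellations_complication: int
    cancellations_no_cicu_bed: int
    cancellations_no_or_session: int
    bed_turnover_cicu: float
    bed_turnover_overall: float
    lost_bed_days: float
    lost_days_per_bed: float
    cicu_nurse_utilisation: float
    ward_nurse_utilisation: float
    cicu_blocked_hours: float
    complication_cost_usd: float

    @property
    def cancellations_total(self) -> int:
        return (self.cancellations_complication + self.cancellations_no_cicu_bed
                + self.cancellations_no_or_session)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["cancellations_total"] = self.cancellations_total
        return d


# ---------------------------------------------------------------------------
def bed_turnover(discharges: int, average_bed_count: float) -> float:
    """Patients treated per bed over a period: discharges (including
    deaths) divided by the average bed count."""
    if average_bed_count <= 0:
        raise ZeroDivisionError("average_bed_count must be positive")
    return discharges / average_bed_count


def utilisation_ratio(u: float) -> float:
    """The queueing pressure ratio u/(1−u); diverges as utilisation → 1."""
    if not 0.0 <= u < 1.0:
        raise ValueError(f"utilisation must be in [0, 1), got {u}")
    return u / (1.0 - u)


def _interval_overlap(lo: float, hi: float, t0: float, t1: float) -> float:
    if math.isnan(lo) or math.isnan(hi):
        return 0.0
    return max(0.0, min(hi, t1) - max(lo, t0))


def lost_bed_days(table: pd.DataFrame, t0: float, t1: float) -> float:
    """Complication-attributable excess bed time served in [t0, t1], days.

    CICU excess occupies the tail of the CICU stay (ending at the moment
    the patient is fit for transfer); ward excess occupies the tail of the
    ward stay (ending at the planned discharge).  Partial overlap with the
    window is pro-rated.
    """
    if table.empty:
        return 0.0
    total_hours = 0.0
    for row in table.itertuples():
        if row.excess_cicu_hours > 0:
            hi = row.t_cicu_ready_exit
            total_hours += _interval_overlap(hi - row.excess_cicu_hours, hi, t0, t1)
        if row.excess_ward_hours > 0:
            hi = row.t_discharge_planned
            total_hours += _interval_overlap(hi - row.excess_ward_hours, hi, t0, t1)
    return total_hours / 24.0


def time_average(history: list[tuple[float, int]], t0: float, t1: float) -> float:
    """Time average of a right-continuous step function given as
    (time, level) change points."""
    if t1 <= t0:
        raise ValueError("empty averaging window")
    total = 0.0
    for i, (t, level) in enumerate(history):
        t_next = history[i + 1][0] if i + 1 < len(history) else t1
        lo, hi = max(t, t0), min(t_next, t1)
        if hi > lo:
            total += level * (hi - lo)
    return total / (t1 - t0)


def waiting_metrics(table: pd.DataFrame, waitlist_history: list[tuple[float, int]],
                    t0: float, t1: float) -> tuple[float, float]:
    """(mean surgery waiting time in days, time-average waiting-list size).

    Waiting time averages over patients operated inside the window; with no
    operated patients it is reported as NaN (not available).
    """
    avg_list = time_average(waitlist_history, t0, t1)
    if table.empty:
        return (math.nan, avg_list)
    started = table[(table["t_surgery_start"] >= t0) & (table["t_surgery_start"] < t1)]
    # waiting time covers *scheduled* surgery: elective cases (emergencies
    # are operated the next day by rule, not placed on the schedule)
    if "klass" in started.columns and (started["klass"] == "elective_surgical").any():
        started = started[started["klass"] == "elective_surgical"]
    if started.empty:
        return (math.nan, avg_list)
    waits = (started["t_surgery_start"] - started["t_ready"]) / 24.0
    return (float(waits.mean()), avg_list)


def complication_cost(table: pd.DataFrame, t0: float, t1: float) -> float:
    """Summed marginal charges (USD) of complications occurring in the
    window (a complication is dated to its patient's surgery completion)."""
    if table.empty:
        return 0.0
    sel = table[(table["t_surgery_end"] >= t0) & (table["t_surgery_end"] < t1)]
    return float(sel["complication_cost_usd"].sum())


# ---------------------------------------------------------------------------
def compute_kpis(model, t0: float, t1: float) -> KPIReport:
    """All outcome measures of one replication over window [t0, t1]."""
    cfg: SystemConfig = model.config
    table = model.patient_table()

    wait_days, wl_size = waiting_metrics(table, model.waitlist_history, t0, t1)

    if table.empty:
        throughput = 0
        cicu_departures = 0
        discharges = 0
        cost = 0.0
        lost = 0.0
        blocked = 0.0
    else:
        throughput = int(((table["t_surgery_end"] >= t0) & (table["t_surgery_end"] < t1)).sum())
        cicu_departures = int(((table["t_cicu_out"] >= t0) & (table["t_cicu_out"] < t1)).sum())
        discharges = int(((table["t_discharge"] >= t0) & (table["t_discharge"] < t1)).sum())
        cost = complication_cost(table, t0, t1)
        lost = lost_bed_days(table, t0, t1)
        transfers = table.dropna(subset=["t_cicu_out", "t_ward_requested"])
        transfers = transfers[(transfers["t_cicu_out"] >= t0) & (transfers["t_cicu_out"] < t1)]
        blocked = float((transfers["t_cicu_out"] - transfers["t_ward_requested"]).clip(lower=0).sum())

    cancellations = {"complication": 0, "no_cicu_bed": 0, "no_or_session": 0}
    for (time, cause, _pid) in model.cancellation_events:
        if t0 <= time < t1:
            cancellations[cause] += 1

    total_beds = cfg.cicu_beds + cfg.ward_beds
    return KPIReport(
        mean_surgery_waiting_time_days=wait_days,
        time_avg_waiting_list_size=wl_size,
        throughput=throughput,
        cancellations_complication=cancellations["complication"],
        cancellations_no_cicu_bed=cancellations["no_cicu_bed"],
        cancellations_no_or_session=cancellations["no_or_session"],
        bed_turnover_cicu=bed_turnover(cicu_departures, cfg.cicu_beds),
        bed_turnover_overall=bed_turnover(discharges, total_beds),
        lost_bed_days=lost,
        lost_days_per_bed=lost / cfg.lost_days_divisor,
        cicu_nurse_utilisation=model.cicu.mean_occupancy(t0, t1) / cfg.cicu_nursing_capacity,
        ward_nurse_utilisation=model.ward.mean_occupancy(t0, t1) / cfg.ward_nursing_capacity,
        cicu_blocked_hours=blocked,
        complication_cost_usd=cost,
    )
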