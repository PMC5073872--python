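"""Patient-flow logic of the cardiothoracic surgical department.

The modelled system: referrals arrive as a Poisson process and are admitted
to an 18-bed ward for a preoperative stay; a single operating theatre runs
one case per day (elective sessions Sunday–Wednesday 08:00–14:30,
non-elective cases any day, operated the day after becoming ready, with
priority); a theatre start requires a free bed in the 5-bed cardiac
intensive care unit (CICU); after at least 48 h in the CICU patients
transfer to the ward — if the ward is full the CICU bed stays blocked —
and are discharged at the end of a surgery-type-specific postoperative
stay.  Non-surgical patients also compete for CICU beds.

Postoperative complications are drawn at surgery completion.  A patient is
assigned at most one complication type by default (probability 0.48 of any,
type proportional to per-patient prevalence); each complication adds its
excess LOS (marginal effect × 24 h) to the end of the stay at its assigned
location (CICU with probability 0.40, ward otherwise; prolonged
ventilation is CICU-only).  Excess stay is what clogs the beds and drives
every downstream performance measure.

Surgery cancellations are recorded when a ready patient cannot be operated
at an in-hours theatre opportunity because every CICU bed is occupied; the
cause is ``complication`` when at least one CICU occupant is in a
complication state, otherwise ``no_cicu_bed``.  Cancelled patients keep
their place and take precedence at the next opportunity.

All random draws a patient will ever need are made from a per-patient
substream at arrival, in a fixed order, so that scenario variants run under
common random numbers: the same patient faces the same stay lengths and
the same complication fate (unless the scenario removes it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .config import SURGERY_TYPES, SystemConfig
from .distributions import sample_duration
from .engine import ResourcePool, RngStreams, Simulator

__all__ = ["Patient", "CardiacUnitModel", "run_single"]

HOURS_PER_DAY = 24.0
HOURS_PER_YEAR = 8760.0

# ward-queue priorities (lower = served first)
PRIO_NONELECTIVE = 0.2
PRIO_TRANSFER = 0.5
PRIO_ELECTIVE = 1.0


def weekday(t: float) -> int:
    """0 = Sunday; simulation time 0 is Sunday 00:00."""
    return int(t // HOURS_PER_DAY) % 7


def day_index(t: float) -> int:
    return int(t // HOURS_PER_DAY)


@dataclass
class Patient:
    pid: str
    klass: str  # elective_surgical | nonelective_surgical | nonsurgical_ward | nonsurgical_cicu
    surgery_type: str | None = None
    # pre-drawn stochastic attributes (hours unless noted)
    preop_los: float = 0.0
    surgery_dur: float = 0.0
    cicu_base: float = 0.0
    postop_total: float = 0.0
    u_complication: float = 1.0
    u_locations: tuple[float, ...] = ()
    u_flags: tuple[float, ...] = ()
    u_reop: float = 1.0
    reop_delay: float = 0.0
    reop_dur: float = 0.0
    cicu_base_after_reop: float = 0.0
    u_death: float = 1.0
    # realised path
    t_referral: float = math.nan
    t_admission: float = math.nan
    t_ready: float = math.nan
    t_surgery_start: float = math.nan
    t_surgery_end: float = math.nan
    t_cicu_in: float = math.nan
    t_cicu_ready_exit: float = math.nan  # fit for transfer (incl. excess)
    t_cicu_out: float = math.nan
    t_ward_requested: float = math.nan
    t_ward_in: float = math.nan
    t_discharge: float = math.nan
    t_discharge_planned: float = math.nan
    complications: list = field(default_factory=list)  # (ComplicationSpec, location)
    excess_cicu_hours: float = 0.0
    excess_ward_hours: float = 0.0
    reoperation: bool = False
    died: bool = False
    cancellations: dict = field(default_factory=lambda: {
        "complication": 0, "no_cicu_bed": 0, "no_or_session": 0})
    eligible_at: float = math.inf  # earliest permissible surgery start
    exit_epoch: int = 0  # invalidates stale CICU-exit events after reoperation
    waiting_ward: bool = False

    @property
    def excess_los_hours(self) -> float:
        return self.excess_cicu_hours + self.excess_ward_hours

    @property
    def surgical(self) -> bool:
        return self.klass in ("elective_surgical", "nonelective_surgical")

    @property
    def cancellations_total(self) -> int:
        return sum(self.cancellations.values())

    def in_complication_state(self, now: float) -> bool:
        """Is the patient currently serving complication-attributable excess
        time in the CICU?  (Excess sits at the end of the CICU stay.)"""
        if self.excess_cicu_hours <= 0 or math.isnan(self.t_cicu_ready_exit):
            return False
        return now >= self.t_cicu_ready_exit - self.excess_cicu_hours

    def has_complication(self) -> bool:
        return bool(self.complications)


class CardiacUnitModel:
    """One replication of the department, run on the event kernel."""

    def __init__(self, config: SystemConfig, seed: int) -> None:
        self.config = config
        self.sim = Simulator()
        self.rng = RngStreams(seed)
        self.cicu = ResourcePool(self.sim, "cicu", config.cicu_beds)
        self.ward = ResourcePool(self.sim, "ward", config.ward_beds)
        self.theatre = ResourcePool(self.sim, "theatre", 1)

        self.patients: list[Patient] = []
        self.waiting_surgical: list[Patient] = []
        self.waiting_nonsurgical_cicu: list[Patient] = []
        self.cicu_occupants: list[Patient] = []
        self.cancellation_events: list[tuple[float, str, str]] = []  # (time, cause, pid)
        self.waitlist_history: list[tuple[float, int]] = [(0.0, 0)]
        self._waitlist_size = 0

        self.admission_queue: list[Patient] = []
        self._preop_count = 0
        self._referral_count = 0
        self._nonsurgical_count = 0
        self._surgeries_started_by_day: dict[int, int] = {}
        self._elective_quota_today = 0
        self._blocked_today: set[str] = set()

        # assignment intervals for the single-complication draw
        self._comp_cum = self._assignment_intervals()

    # ------------------------------------------------------------------
    def _assignment_intervals(self) -> list[tuple[float, object]]:
        """Cumulative thresholds on the unit interval: patient draws one
        uniform; each complication type owns a slice proportional to its
        prevalence, scaled so the slices together cover
        ``complication_any_prob`` of the interval."""
        cfg = self.config
        total = sum(c.prevalence for c in cfg.complications)
        cum: list[tuple[float, object]] = []
        if total <= 0:
            return cum
        scale = cfg.complication_any_prob / total
        acc = 0.0
        for c in cfg.complications:
            acc += c.prevalence * scale
            cum.append((acc, c))
        return cum

    # -- patient creation ----------------------------------------------
    def _draw_patient(self, kind: str, index: int) -> Patient:
        """All stochastic attributes are drawn here, in a fixed order, from
        a per-patient substream — the common-random-numbers backbone."""
        cfg = self.config
        rng = self.rng.stream(f"patient.{kind}.{index}")
        pid = f"{kind[:2]}{index}"
        if kind == "nonsurgical_cicu":
            p = Patient(pid=pid, klass="nonsurgical_cicu")
            p.cicu_base = sample_duration(cfg.nonsurgical_cicu_los, rng)
            return p

        u_accept = rng.random()
        u_nonelective = rng.random()
        u_not_operated = rng.random()
        u_type = rng.random()
        preop = sample_duration(cfg.preop_los, rng)
        sdur = sample_duration(cfg.surgery_duration, rng)
        cicu_base = sample_duration(cfg.cicu_los, rng)
        # postop LOS depends on surgery type: pick the type first
        acc, stype = 0.0, SURGERY_TYPES[-1]
        for name in SURGERY_TYPES:
            acc += cfg.surgery_type_mix[name]
            if u_type < acc:
                stype = name
                break
        postop = sample_duration(cfg.postop_los_by_surgery_type[stype], rng)
        u_comp = rng.random()
        n = len(cfg.complications)
        u_locs = tuple(rng.random(n))
        u_flags = tuple(rng.random(n))
        u_reop = rng.random()
        reop_delay = rng.random() * HOURS_PER_DAY  # within 24 h of surgery
        reop_dur = sample_duration(cfg.surgery_duration, rng)
        cicu_after_reop = sample_duration(cfg.cicu_los, rng)
        u_death = rng.random()

        if u_accept >= cfg.referral_acceptance:
            klass = "declined"
        elif u_not_operated < cfg.pct_admitted_not_operated:
            klass = "nonsurgical_ward"
        elif u_nonelective < cfg.nonelective_share:
            klass = "nonelective_surgical"
        else:
            klass = "elective_surgical"
        return Patient(
            pid=pid, klass=klass, surgery_type=stype,
            preop_los=preop, surgery_dur=sdur, cicu_base=cicu_base,
            postop_total=postop, u_complication=u_comp, u_locations=u_locs,
            u_flags=u_flags, u_reop=u_reop, reop_delay=reop_delay,
            reop_dur=reop_dur, cicu_base_after_reop=cicu_after_reop,
            u_death=u_death,
        )

    # -- arrivals -------------------------------------------------------
    def _schedule_next_referral(self) -> None:
        gap = sample_duration(self.config.referral_interarrival, self.rng.stream("arrivals.referral"))
        self.sim.schedule_in(gap, self._referral_arrives)

    def _referral_arrives(self) -> None:
        self._schedule_next_referral()
        p = self._draw_patient("referral", self._referral_count)
        self._referral_count += 1
        p.t_referral = self.sim.now
        self.patients.append(p)
        if p.klass == "declined":
            return  # never enters the department
        if p.surgical:
            self._set_waitlist(+1)
        if p.klass == "nonelective_surgical":
            # emergencies are admitted at once, bypassing the admission buffer
            self.ward.acquire(p.pid, lambda pat=p: self._admit(pat),
                              priority=PRIO_NONELECTIVE)
        else:
            self.admission_queue.append(p)
            self._pull_admissions()

    def _pull_admissions(self) -> None:
        """Elective admissions are pulled by the surgery schedule: patients
        wait at home until a preoperative ward place opens up."""
        while self.admission_queue and self._preop_count < self.config.preop_admission_buffer:
            p = self.admission_queue.pop(0)
            self._preop_count += 1
            self.ward.acquire(p.pid, lambda pat=p: self._admit(pat),
                              priority=PRIO_ELECTIVE)

    def _leave_preop(self, p: Patient) -> None:
        if p.klass != "nonelective_surgical":
            self._preop_count -= 1
            self._pull_admissions()

    def _schedule_next_nonsurgical(self) -> None:
        gap = sample_duration(self.config.nonsurgical_cicu_interarrival,
                              self.rng.stream("arrivals.nonsurgical"))
        self.sim.schedule_in(gap, self._nonsurgical_arrives)

    def _nonsurgical_arrives(self) -> None:
        self._schedule_next_nonsurgical()
        p = self._draw_patient("nonsurgical_cicu", self._nonsurgical_count)
        self._nonsurgical_count += 1
        p.t_referral = self.sim.now
        self.patients.append(p)
        self.waiting_nonsurgical_cicu.append(p)
        self._admit_nonsurgical_cicu()

    def _admit_nonsurgical_cicu(self) -> None:
        """Surgical demand outranks non-surgical CICU admissions: this is
        only called after surgery starts have had their chance at the bed."""
        while self.waiting_nonsurgical_cicu and self.cicu.in_use < self.cicu.capacity:
            p = self.waiting_nonsurgical_cicu.pop(0)
            p.t_admission = p.t_cicu_in = self.sim.now
            self.cicu.acquire(p.pid, lambda: None)
            self.cicu_occupants.append(p)
            self.sim.schedule_in(p.cicu_base, lambda pat=p: self._nonsurgical_leaves(pat))

    def _nonsurgical_leaves(self, p: Patient) -> None:
        self.cicu.release(p.pid)
        self.cicu_occupants.remove(p)
        p.t_cicu_out = p.t_discharge = self.sim.now
        self._on_cicu_release()

    # -- admission and preparation --------------------------------------
    def _admit(self, p: Patient) -> None:
        p.t_admission = self.sim.now
        self.sim.schedule_in(p.preop_los, lambda: self._preop_complete(p))

    def _preop_complete(self, p: Patient) -> None:
        if p.klass == "nonsurgical_ward":
            self.ward.release(p.pid)
            p.t_discharge = self.sim.now
            self._leave_preop(p)
            return
        p.t_ready = self.sim.now
        if p.klass == "nonelective_surgical":
            # operated the day after becoming ready, any day of the week
            p.eligible_at = (day_index(self.sim.now) + 1) * HOURS_PER_DAY + self.config.or_session_start
            self.sim.schedule(p.eligible_at, self._try_start_surgeries)
        else:
            p.eligible_at = self.sim.now
        self.waiting_surgical.append(p)
        self._try_start_surgeries()

    # -- waiting list ----------------------------------------------------
    def _set_waitlist(self, delta: int) -> None:
        self._waitlist_size += delta
        self.waitlist_history.append((self.sim.now, self._waitlist_size))

    def _klass_rank(self, p: Patient) -> int:
        return 0 if p.klass == "nonelective_surgical" else 1

    def _select_next_surgery(self, now: float) -> Patient | None:
        """Priority: non-elective > elective; previously cancelled patients
        take precedence within their class; FIFO otherwise.  Electives are
        only eligible inside an elective session with quota remaining."""
        in_session = (weekday(now) in self.config.or_days
                      and self.config.or_session_start <= (now % HOURS_PER_DAY) < self.config.or_session_end)
        candidates = []
        for p in self.waiting_surgical:
            if now < p.eligible_at:
                continue
            if p.klass == "elective_surgical" and not (in_session and self._elective_quota_today > 0):
                continue
            candidates.append(p)
        if not candidates:
            return None
        return min(candidates, key=lambda p: (
            self._klass_rank(p), -p.cancellations_total, p.t_ready, p.pid))

    # -- theatre ---------------------------------------------------------
    def _day_opens(self) -> None:
        now = self.sim.now
        self._elective_quota_today = (
            self.config.electives_per_day if weekday(now) in self.config.or_days else 0)
        self._blocked_today.clear()
        close_in = self.config.or_session_end - self.config.or_session_start
        self.sim.schedule_in(close_in, self._session_closes)
        self.sim.schedule_in(HOURS_PER_DAY, self._day_opens)
        self._try_start_surgeries()

    def _session_closes(self) -> None:
        """End of the theatre's regular hours.  A patient who was selected
        for surgery today but stayed blocked behind a full CICU for the
        whole session has their case cancelled: cause ``complication`` when
        a CICU occupant is in a complication state, ``no_cicu_bed``
        otherwise.  The patient keeps precedence for the next opportunity."""
        now = self.sim.now
        for p in self.waiting_surgical:
            if p.pid not in self._blocked_today or not math.isnan(p.t_surgery_start):
                continue
            cause = ("complication"
                     if any(q.in_complication_state(now) for q in self.cicu_occupants)
                     else "no_cicu_bed")
            p.cancellations[cause] += 1
            self.cancellation_events.append((now, cause, p.pid))
            if p.klass == "elective_surgical":
                p.eligible_at = now + self.config.cancellation_reschedule_days * HOURS_PER_DAY
            else:
                # emergencies come back the next day regardless
                p.eligible_at = (day_index(now) + 1) * HOURS_PER_DAY + self.config.or_session_start
            self.sim.schedule(p.eligible_at, self._try_start_surgeries)
        self._blocked_today.clear()

    def _day_cap_reached(self, now: float) -> bool:
        if not self.config.one_surgery_per_day:
            return False
        return self._surgeries_started_by_day.get(day_index(now), 0) >= 1

    def _try_start_surgeries(self) -> None:
        now = self.sim.now
        while True:
            if self.theatre.in_use > 0 or self._day_cap_reached(now):
                return
            p = self._select_next_surgery(now)
            if p is None:
                self._admit_nonsurgical_cicu()
                return
            if self.cicu.in_use < self.cicu.capacity:
                self._start_surgery(p)
                continue
            # CICU gate shut: the selected patient waits for a bed release;
            # if none comes before the session closes the case is cancelled
            self._blocked_today.add(p.pid)
            return

    def _start_surgery(self, p: Patient) -> None:
        now = self.sim.now
        self._surgeries_started_by_day[day_index(now)] = (
            self._surgeries_started_by_day.get(day_index(now), 0) + 1)
        if p.klass == "elective_surgical":
            self._elective_quota_today -= 1
        self.waiting_surgical.remove(p)
        self._set_waitlist(-1)
        self.ward.release(p.pid)  # preoperative bed freed
        self._leave_preop(p)
        self.cicu.acquire(p.pid, lambda: None)  # bed reserved before theatre entry
        self.cicu_occupants.append(p)
        self.theatre.acquire(p.pid, lambda: None)
        p.t_surgery_start = now
        self.sim.schedule_in(p.surgery_dur, lambda: self._surgery_ends(p))

    def _surgery_ends(self, p: Patient) -> None:
        now = self.sim.now
        p.t_surgery_end = now
        p.t_cicu_in = now
        self.theatre.release(p.pid)
        self._assign_complications(p)
        if p.u_reop < self.config.reoperation_prob and not p.reoperation:
            self.sim.schedule_in(p.reop_delay, lambda: self._reoperation(p))
        self._schedule_cicu_exit(p, base=max(self.config.min_cicu_hours, p.cicu_base))
        self._try_start_surgeries()

    # -- complications ----------------------------------------------------
    def _assign_complications(self, p: Patient) -> None:
        cfg = self.config
        drawn: list = []
        if cfg.allow_multiple_complications:
            # independent per-type flags behind the any-complication gate
            total = sum(c.prevalence for c in cfg.complications)
            if p.u_complication < cfg.complication_any_prob and total > 0:
                for i, c in enumerate(cfg.complications):
                    q = min(1.0, c.prevalence / cfg.complication_any_prob)
                    if p.u_flags[i] < q:
                        drawn.append((i, c))
                if not drawn:
                    # guarantee "at least one" for gated patients
                    u = p.u_flags[0] * total
                    acc = 0.0
                    for i, c in enumerate(cfg.complications):
                        acc += c.prevalence
                        if u < acc:
                            drawn.append((i, c))
                            break
        else:
            for i, (threshold, c) in enumerate(self._comp_cum):
                if p.u_complication < threshold:
                    drawn.append((i, c))
                    break
        for i, c in drawn:
            location = "CICU" if (c.cicu_only or p.u_locations[i] < cfg.cicu_location_share) else "ward"
            p.complications.append((c, location))
            extra = c.effective_excess_days(cfg.negative_excess_as_zero) * HOURS_PER_DAY
            if location == "CICU":
                p.excess_cicu_hours += extra
            else:
                p.excess_ward_hours += extra

    # -- postoperative pathway -------------------------------------------
    def _schedule_cicu_exit(self, p: Patient, base: float) -> None:
        p.exit_epoch += 1
        epoch = p.exit_epoch
        p.t_cicu_ready_exit = self.sim.now + base + p.excess_cicu_hours
        self.sim.schedule(p.t_cicu_ready_exit, lambda: self._cicu_exit_ready(p, epoch))

    def _reoperation(self, p: Patient) -> None:
        # unplanned return to theatre (e.g. bleeding); outranks electives,
        # exempt from the daily cap, and the patient keeps the CICU bed
        self.theatre.acquire(p.pid, lambda: self._reop_starts(p), priority=0.5)

    def _reop_starts(self, p: Patient) -> None:
        p.reoperation = True
        self.sim.schedule_in(p.reop_dur, lambda: self._reop_ends(p))

    def _reop_ends(self, p: Patient) -> None:
        self.theatre.release(p.pid)
        self._schedule_cicu_exit(
            p, base=max(self.config.min_cicu_hours, p.cicu_base_after_reop))
        self._try_start_surgeries()

    def _cicu_exit_ready(self, p: Patient, epoch: int) -> None:
        if epoch != p.exit_epoch:  # superseded by a reoperation
            return
        round_hour = self.config.transfer_round_hour
        if round_hour is not None and round_hour >= 0:
            # fit-for-transfer patients leave at the next daily round
            now = self.sim.now
            next_round = day_index(now) * HOURS_PER_DAY + round_hour
            if next_round < now:
                next_round += HOURS_PER_DAY
            if next_round > now:
                self.sim.schedule(next_round, lambda: self._cicu_exit_go(p, epoch))
                return
        self._cicu_exit_go(p, epoch)

    def _cicu_exit_go(self, p: Patient, epoch: int) -> None:
        if epoch != p.exit_epoch:
            return
        if self.config.mortality_enabled and p.u_death < self.config.mortality_prob:
            p.died = True
            self.cicu.release(p.pid)
            self.cicu_occupants.remove(p)
            p.t_cicu_out = p.t_discharge = self.sim.now
            self._on_cicu_release()
            return
        p.waiting_ward = True
        p.t_ward_requested = self.sim.now
        self.ward.acquire(p.pid, lambda: self._transfer_to_ward(p), priority=PRIO_TRANSFER)

    def _transfer_to_ward(self, p: Patient) -> None:
        now = self.sim.now
        p.waiting_ward = False
        wait = now - p.t_ward_requested
        if wait > 0:
            self.cicu.add_blocked_time(wait)
        self.cicu.release(p.pid)
        self.cicu_occupants.remove(p)
        p.t_cicu_out = now
        p.t_ward_in = now
        cicu_base_hours = (p.t_cicu_ready_exit - p.excess_cicu_hours) - p.t_cicu_in
        ward_base = max(0.0, p.postop_total - cicu_base_hours) * self.config.ward_postop_scale
        stay = ward_base + p.excess_ward_hours
        p.t_discharge_planned = now + stay
        self.sim.schedule_in(stay, lambda: self._discharge(p))
        self._on_cicu_release()

    def _on_cicu_release(self) -> None:
        self._try_start_surgeries()
        self._admit_nonsurgical_cicu()

    def _discharge(self, p: Patient) -> None:
        self.ward.release(p.pid)
        p.t_discharge = self.sim.now

    # -- running ----------------------------------------------------------
    def run(self, horizon_hours: float) -> None:
        self._schedule_next_referral()
        self._schedule_next_nonsurgical()
        self.sim.schedule(self.config.or_session_start, self._day_opens)
        self.sim.run_until(horizon_hours)

    # -- output -----------------------------------------------------------
    def patient_table(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append({
                "pid": p.pid,
                "klass": p.klass,
                "surgery_type": p.surgery_type,
                "t_referral": p.t_referral,
                "t_admission": p.t_admission,
                "t_ready": p.t_ready,
                "t_surgery_start": p.t_surgery_start,
                "t_surgery_end": p.t_surgery_end,
                "t_cicu_in": p.t_cicu_in,
                "t_cicu_ready_exit": p.t_cicu_ready_exit,
                "t_cicu_out": p.t_cicu_out,
                "t_ward_requested": p.t_ward_requested,
                "t_ward_in": p.t_ward_in,
                "t_discharge": p.t_discharge,
                "t_discharge_planned": p.t_discharge_planned,
                "complications": ";".join(c.name for c, _loc in p.complications),
                "comp_locations": ";".join(loc for _c, loc in p.complications),
                "excess_cicu_hours": p.excess_cicu_hours,
                "excess_ward_hours": p.excess_ward_hours,
                "excess_los_hours": p.excess_los_hours,
                "complication_cost_usd": sum(c.marginal_cost_usd for c, _ in p.complications),
                "reoperation": p.reoperation,
                "died": p.died,
                "cancel_complication": p.cancellations["complication"],
                "cancel_no_cicu_bed": p.cancellations["no_cicu_bed"],
                "cancel_no_or_session": p.cancellations["no_or_session"],
            })
        return pd.DataFrame(rows)

    def trace_fingerprint(self) -> str:
        """Hash of the realised event trace, for determinism checks."""
        import hashlib
        df = self.patient_table()
        payload = df.to_csv(index=False).encode() + str(self.sim.events_executed).encode()
        return hashlib.sha256(payload).hexdigest()


def run_single(config: SystemConfig, seed: int, horizon_hours: float) -> CardiacUnitModel:
    """Build and run one replication; returns the finished model."""
    model = CardiacUnitModel(config, seed)
    model.run(horizon_hours)
    return model
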