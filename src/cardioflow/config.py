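"""Model configuration: capacities, schedules, complication and cost tables.

The whole simulation is driven by a :class:`SystemConfig`, which mirrors a
YAML configuration file field-for-field.  The shipped default file
(``data/default_config.yaml``) transcribes the published calibration of the
cardiothoracic department under study: a single operating theatre running
Sunday–Wednesday 08:00–14:30 with one elective case per day, a 5-bed
cardiac intensive care unit (CICU) gating theatre starts, an 18-bed ward,
and fifteen complication types with their prevalences, excess length of
stay (marginal effect, days) and marginal charges (USD).

Probabilities are per patient; durations are hours; costs are USD
(converted from Omani Rial at a fixed factor of 2.56).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import yaml

from .distributions import ConfigurationError, DistributionSpec, Violation

__all__ = [
    "SURGERY_TYPES",
    "CATEGORIES",
    "ComplicationSpec",
    "SystemConfig",
    "default_config",
    "validate_config",
    "load_config",
    "save_config",
]

SURGERY_TYPES = ("isolated_cabg", "isolated_valve", "cabg_valve", "other")
CATEGORIES = ("cardiac", "pulmonary", "infection", "neurological")


@dataclass(frozen=True)
class ComplicationSpec:
    """One adverse-event type and its resource footprint.

    ``excess_los_days`` is the marginal effect of the complication on
    postoperative LOS (days) from the attribution regression; it may be
    negative or non-significant as estimated, in which case the flow model
    treats it as zero (see :meth:`effective_excess_days`).
    """

    name: str
    category: str
    prevalence: float
    excess_los_days: float
    marginal_cost_usd: float
    cicu_only: bool = False
    significant: bool = True

    def effective_excess_days(self, negative_as_zero: bool = True) -> float:
        """Excess LOS actually applied in the flow model (days, >= 0)."""
        if not self.significant:
            return 0.0
        if negative_as_zero and self.excess_los_days < 0:
            return 0.0
        return self.excess_los_days

    def violations(self, prefix: str = "") -> list[Violation]:
        out: list[Violation] = []
        f = f"{prefix}complications[{self.name}]"
        if not 0.0 <= self.prevalence <= 1.0:
            out.append(Violation(f + ".prevalence", "probability in [0, 1]", self.prevalence))
        if self.category not in CATEGORIES:
            out.append(Violation(f + ".category", f"one of {CATEGORIES}", self.category))
        if not 0.0 <= self.marginal_cost_usd:
            out.append(Violation(f + ".marginal_cost_usd", ">= 0", self.marginal_cost_usd))
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "category": self.category,
            "prevalence": self.prevalence,
            "excess_los_days": self.excess_los_days,
            "marginal_cost_usd": self.marginal_cost_usd,
            "cicu_only": self.cicu_only,
            "significant": self.significant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComplicationSpec":
        return cls(**d)


@dataclass(frozen=True)
class SystemConfig:
    # capacities and schedule; week starts on Sunday (weekday 0)
    cicu_beds: int = 5
    ward_beds: int = 18
    or_days: tuple[int, ...] = (0, 1, 2, 3)  # Sunday–Wednesday
    or_session_start: float = 8.0  # hour of day
    or_session_end: float = 14.5
    electives_per_day: int = 1
    one_surgery_per_day: bool = True

    # arrivals and routing
    referral_interarrival: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("exponential_interarrival", (33.0,))
    )
    nonsurgical_cicu_interarrival: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("exponential_interarrival", (55.0,))
    )
    nonelective_share: float = 0.15
    # fraction of referrals that proceed to the surgical pathway at all
    # (the remainder decline, are unfit, or are referred on); reconciles
    # the referral inter-arrival rate with the department's yearly volume
    referral_acceptance: float = 0.78
    pct_admitted_not_operated: float = 0.10
    reoperation_prob: float = 0.04
    # elective patients wait at home and are admitted a few days before
    # surgery; at most this many are in the preoperative ward at once
    preop_admission_buffer: int = 5

    # complications
    complication_any_prob: float = 0.48
    cicu_location_share: float = 0.40
    allow_multiple_complications: bool = False
    negative_excess_as_zero: bool = True
    complications: tuple[ComplicationSpec, ...] = ()

    # stays
    preop_los: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta_scaled", (1.61, 1.3, 75.0, 152.0))
    )
    cicu_los: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta_scaled", (1.04, 1.6, 48.0, 111.0))
    )
    # non-surgical CICU admissions are short observation stays (follow-up,
    # post-catheterisation monitoring), not bound by the 48 h postoperative
    # minimum
    nonsurgical_cicu_los: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("triangular", (12.0, 24.0, 48.0))
    )
    surgery_duration: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("triangular", (2.5, 2.8, 6.0))
    )
    postop_los_by_surgery_type: dict = field(default_factory=dict)
    surgery_type_mix: dict = field(
        default_factory=lambda: {
            "isolated_cabg": 0.60,
            "isolated_valve": 0.20,
            "cabg_valve": 0.10,
            "other": 0.10,
        }
    )
    min_cicu_hours: float = 48.0
    ward_postop_scale: float = 1.0  # scenario knob: scales the ward share of postop LOS
    # CICU -> ward transfers happen at a daily discharge round (hour of
    # day); null/negative disables the round (continuous transfers)
    transfer_round_hour: float = 7.0
    # a cancelled elective case is rescheduled this many days later
    cancellation_reschedule_days: float = 10.0

    # accounting: nurse utilisation is patient census over the staffed
    # care capacity (patients-per-shift the roster can carry); units
    # routinely staff below bed count
    cicu_nursing_capacity: int = 4  # 1:1 nursing, 4 nurses per shift
    ward_nursing_capacity: int = 13
    currency_factor: float = 2.56
    lost_days_divisor: int = 23  # departmental bed count used for per-bed figures
    mortality_enabled: bool = False
    mortality_prob: float = 0.04

    # ------------------------------------------------------------------
    def complication(self, name: str) -> ComplicationSpec:
        for c in self.complications:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def complications_by_name(self) -> dict:
        return {c.name: c for c in self.complications}

    def to_dict(self) -> dict:
        return {
            "cicu_beds": self.cicu_beds,
            "ward_beds": self.ward_beds,
            "or_days": list(self.or_days),
            "or_session_start": self.or_session_start,
            "or_session_end": self.or_session_end,
            "electives_per_day": self.electives_per_day,
            "one_surgery_per_day": self.one_surgery_per_day,
            "referral_interarrival": self.referral_interarrival.to_dict(),
            "nonsurgical_cicu_interarrival": self.nonsurgical_cicu_interarrival.to_dict(),
            "nonelective_share": self.nonelective_share,
            "referral_acceptance": self.referral_acceptance,
            "pct_admitted_not_operated": self.pct_admitted_not_operated,
            "reoperation_prob": self.reoperation_prob,
            "preop_admission_buffer": self.preop_admission_buffer,
            "complication_any_prob": self.complication_any_prob,
            "cicu_location_share": self.cicu_location_share,
            "allow_multiple_complications": self.allow_multiple_complications,
            "negative_excess_as_zero": self.negative_excess_as_zero,
            "complications": [c.to_dict() for c in self.complications],
            "preop_los": self.preop_los.to_dict(),
            "cicu_los": self.cicu_los.to_dict(),
            "nonsurgical_cicu_los": self.nonsurgical_cicu_los.to_dict(),
            "surgery_duration": self.surgery_duration.to_dict(),
            "postop_los_by_surgery_type": {
                k: v.to_dict() for k, v in self.postop_los_by_surgery_type.items()
            },
            "surgery_type_mix": dict(self.surgery_type_mix),
            "min_cicu_hours": self.min_cicu_hours,
            "ward_postop_scale": self.ward_postop_scale,
            "transfer_round_hour": self.transfer_round_hour,
            "cancellation_reschedule_days": self.cancellation_reschedule_days,
            "cicu_nursing_capacity": self.cicu_nursing_capacity,
            "ward_nursing_capacity": self.ward_nursing_capacity,
            "currency_factor": self.currency_factor,
            "lost_days_divisor": self.lost_days_divisor,
            "mortality_enabled": self.mortality_enabled,
            "mortality_prob": self.mortality_prob,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SystemConfig":
        d = dict(d)
        for key in ("referral_interarrival", "nonsurgical_cicu_interarrival",
                    "preop_los", "cicu_los", "nonsurgical_cicu_los", "surgery_duration"):
            if key in d:
                d[key] = DistributionSpec.from_dict(d[key])
        if "postop_los_by_surgery_type" in d:
            d["postop_los_by_surgery_type"] = {
                k: DistributionSpec.from_dict(v)
                for k, v in d["postop_los_by_surgery_type"].items()
            }
        if "complications" in d:
            d["complications"] = tuple(
                ComplicationSpec.from_dict(c) for c in d["complications"]
            )
        if "or_days" in d:
            d["or_days"] = tuple(d["or_days"])
        return cls(**d)

    def with_updates(self, **kwargs) -> "SystemConfig":
        return replace(self, **kwargs)


# ----------------------------------------------------------------------
def validate_config(config: SystemConfig) -> list[Violation]:
    """Check every structural invariant; returns violations, never raises."""
    out: list[Violation] = []

    def check_prob(name: str, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            out.append(Violation(name, "probability in [0, 1]", value))

    for name in ("cicu_beds", "ward_beds", "electives_per_day", "lost_days_divisor",
                 "preop_admission_buffer", "cicu_nursing_capacity", "ward_nursing_capacity"):
        v = getattr(config, name)
        if not (isinstance(v, int) and v >= 1):
            out.append(Violation(name, "integer count >= 1", v))

    for name in ("nonelective_share", "referral_acceptance",
                 "pct_admitted_not_operated", "reoperation_prob",
                 "complication_any_prob", "cicu_location_share", "mortality_prob"):
        check_prob(name, getattr(config, name))

    mix = config.surgery_type_mix
    if set(mix) != set(SURGERY_TYPES):
        out.append(Violation("surgery_type_mix", f"keys are {SURGERY_TYPES}", sorted(mix)))
    else:
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            out.append(Violation("surgery_type_mix", "sums to 1 within 1e-9", total))
        for k, v in mix.items():
            check_prob(f"surgery_type_mix[{k}]", v)

    for name in ("referral_interarrival", "nonsurgical_cicu_interarrival",
                 "preop_los", "cicu_los", "nonsurgical_cicu_los", "surgery_duration"):
        out.extend(getattr(config, name).violations(name))
    for k, spec in config.postop_los_by_surgery_type.items():
        out.extend(spec.violations(f"postop_los_by_surgery_type[{k}]"))
    if set(config.postop_los_by_surgery_type) != set(SURGERY_TYPES):
        out.append(Violation("postop_los_by_surgery_type",
                             f"one spec per surgery type {SURGERY_TYPES}",
                             sorted(config.postop_los_by_surgery_type)))

    names = [c.name for c in config.complications]
    if len(names) != len(set(names)):
        out.append(Violation("complications", "unique names", names))
    for c in config.complications:
        out.extend(c.violations())
        if c.significant and c.effective_excess_days() < 0:
            out.append(Violation(f"complications[{c.name}].excess_los_days",
                                 ">= 0 when significant", c.excess_los_days))

    if not 0.0 <= config.or_session_start < config.or_session_end <= 24.0:
        out.append(Violation("or_session", "0 <= start < end <= 24",
                             (config.or_session_start, config.or_session_end)))
    if any(not 0 <= d <= 6 for d in config.or_days):
        out.append(Violation("or_days", "weekday indices 0–6 (0 = Sunday)", config.or_days))
    if config.min_cicu_hours < 0:
        out.append(Violation("min_cicu_hours", ">= 0", config.min_cicu_hours))
    if config.ward_postop_scale < 0:
        out.append(Violation("ward_postop_scale", ">= 0", config.ward_postop_scale))
    return out


# ----------------------------------------------------------------------
def load_config(path) -> SystemConfig:
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} did not parse to a mapping")
    return SystemConfig.from_dict(data)


def save_config(config: SystemConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def default_config() -> SystemConfig:
    """The shipped baseline calibration (read from the packaged YAML file)."""
    ref = importlib.resources.files("cardioflow").joinpath("data/default_config.yaml")
    data = yaml.safe_load(ref.read_text())
    return SystemConfig.from_dict(data)
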