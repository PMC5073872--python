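"""Parametric duration distributions for the patient-flow model.

All durations are in hours.  Each input of the simulation (length of stay,
inter-arrival gaps, surgery duration) is described by a
:class:`DistributionSpec` — a family name plus an ordered parameter tuple —
so that a whole model configuration can round-trip through YAML.

Families
--------
``beta_scaled``
    ``(shape1, shape2, min, max)``; a Beta(shape1, shape2) draw rescaled to
    ``[min, max]``.  Used for the bounded LOS inputs.
``weibull_shifted`` / ``gamma_shifted``
    ``(offset, shape, scale)``; ``offset`` is a lower bound added to the
    draw.  Used for the heavier-tailed postoperative LOS inputs.
``triangular``
    ``(min, mode, max)``.  Surgery duration.
``exponential_interarrival``
    ``(mean,)``; exponential gaps, i.e. a Poisson arrival process.
``bernoulli``
    ``(p,)``; returns 0.0 or 1.0.
``fixed``
    ``(value,)``; degenerate, mainly for tests and scenario overrides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistributionSpec",
    "ConfigurationError",
    "Violation",
    "sample_duration",
    "analytic_mean",
]

_FAMILIES = {
    "beta_scaled": 4,
    "weibull_shifted": 3,
    "gamma_shifted": 3,
    "triangular": 3,
    "exponential_interarrival": 1,
    "bernoulli": 1,
    "fixed": 1,
}


class ConfigurationError(ValueError):
    """Raised when a spec or config field cannot be interpreted at all."""


@dataclass(frozen=True)
class Violation:
    """A machine-readable invariant violation: which field, which rule, what value."""

    field: str
    rule: str
    value: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule} (got {self.value!r})"


@dataclass(frozen=True)
class DistributionSpec:
    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {sorted(_FAMILIES)}"
            )
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _FAMILIES[self.family]:
            raise ConfigurationError(
                f"family {self.family!r} takes {_FAMILIES[self.family]} "
                f"parameters, got {len(params)}"
            )

    # -- validation ------------------------------------------------------
    def violations(self, field_name: str = "distribution") -> list[Violation]:
        p = self.params
        out: list[Violation] = []

        def bad(rule: str, value: object) -> None:
            out.append(Violation(field_name, rule, value))

        if self.family == "beta_scaled":
            a, b, lo, hi = p
            if a <= 0:
                bad("shape1 > 0", a)
            if b <= 0:
                bad("shape2 > 0", b)
            if not lo < hi:
                bad("min < max", (lo, hi))
        elif self.family in ("weibull_shifted", "gamma_shifted"):
            off, shape, scale = p
            if off < 0:
                bad("offset >= 0", off)
            if shape <= 0:
                bad("shape > 0", shape)
            if scale <= 0:
                bad("scale > 0", scale)
        elif self.family == "triangular":
            lo, mode, hi = p
            if not (lo <= mode <= hi):
                bad("min <= mode <= max", p)
        elif self.family == "exponential_interarrival":
            if p[0] <= 0:
                bad("mean > 0", p[0])
        elif self.family == "bernoulli":
            if not 0.0 <= p[0] <= 1.0:
                bad("p in [0, 1]", p[0])
        return out

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        try:
            return cls(family=d["family"], params=tuple(d["params"]))
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed distribution spec {d!r}") from exc


def sample_duration(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one duration (hours) from *spec* using *rng*.

    The draw respects each family's lower bound by construction: scaled
    Beta stays inside ``[min, max]``, shifted families return
    ``offset + positive draw``.
    """
    p = spec.params
    fam = spec.family
    if fam == "beta_scaled":
        a, b, lo, hi = p
        return lo + (hi - lo) * rng.beta(a, b)
    if fam == "weibull_shifted":
        off, shape, scale = p
        return off + scale * rng.weibull(shape)
    if fam == "gamma_shifted":
        off, shape, scale = p
        return off + rng.gamma(shape, scale)
    if fam == "triangular":
        lo, mode, hi = p
        if lo == hi:  # numpy rejects a degenerate triangle
            return lo
        return rng.triangular(lo, mode, hi)
    if fam == "exponential_interarrival":
        return rng.exponential(p[0])
    if fam == "bernoulli":
        return float(rng.random() < p[0])
    if fam == "fixed":
        return p[0]
    raise ConfigurationError(f"unknown family {fam!r}")  # pragma: no cover


def analytic_mean(spec: DistributionSpec) -> float:
    """Closed-form mean of *spec*; the oracle for sampling tests."""
    from math import gamma as gamma_fn

    p = spec.params
    fam = spec.family
    if fam == "beta_scaled":
        a, b, lo, hi = p
        return lo + (hi - lo) * a / (a + b)
    if fam == "weibull_shifted":
        off, shape, scale = p
        return off + scale * gamma_fn(1.0 + 1.0 / shape)
    if fam == "gamma_shifted":
        off, shape, scale = p
        return off + shape * scale
    if fam == "triangular":
        return sum(p) / 3.0
    if fam == "exponential_interarrival":
        return p[0]
    if fam == "bernoulli":
        return p[0]
    if fam == "fixed":
        return p[0]
    raise ConfigurationError(f"unknown family {fam!r}")  # pragma: no cover
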