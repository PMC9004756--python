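"""Parasitoid attack-rate families and their log sensitivities.

The whole stability analysis is organised around the elasticities
(log sensitivities) of the attack rate ``f(h, p)`` with respect to the
host and parasitoid densities,

    f_h = (h / f) df/dh,      f_p = (p / f) df/dp,

evaluated at the coexistence equilibrium.  ``f_h < 0`` is a Type II
(saturating) functional response, ``f_h > 0`` an accelerating (Type III)
one; ``f_p < 0`` is mutual interference between parasitoids and
``f_p > 0`` cooperation.  Net attack rates per host and per parasitoid
are assumed non-decreasing in the respective density, which bounds both
sensitivities below by -1.

Families
--------
``constant``
    f = c.  The classical Lotka-Volterra / Nicholson-Bailey rate.
``type2``
    f = c1 / (1 + c1*Th*h).  Saturating (handling-time) response;
    c1 is the attack rate at low host density, Th the handling time.
``generalized_hill``
    f = c1*h**q / (1 + c1*Th*h**(q+1)).  Sigmoidal net response for
    q > 0; reduces to ``type2`` at q = 0.
``parasitoid_power``
    f = c1*p**alpha with -1 < alpha < 1.  Parasitoid interference
    (alpha < 0) or cooperation (alpha > 0).
``monomial``
    f = c * h**a * p**b.  Its log sensitivities are the exponents
    themselves, making it the canonical bridge to the (f_h, f_p)
    plane used by the stability atlas.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "Family",
    "AttackRateModel",
    "LogSensitivities",
    "DomainError",
    "ConfigurationError",
    "evaluate",
    "log_sensitivities",
    "numeric_log_sensitivities",
    "type2_fh_closed_form",
]


class DomainError(ValueError):
    """Raised when densities or parameters leave the model's domain."""


class ConfigurationError(ValueError):
    """Raised for an unknown family or an invalid parameter set."""


class Family(str, enum.Enum):
    CONSTANT = "constant"
    TYPE2 = "type2"
    GENERALIZED_HILL = "generalized_hill"
    PARASITOID_POWER = "parasitoid_power"
    MONOMIAL = "monomial"


#: required parameter names per family
_REQUIRED = {
    Family.CONSTANT: ("c",),
    Family.TYPE2: ("c1", "Th"),
    Family.GENERALIZED_HILL: ("c1", "Th", "q"),
    Family.PARASITOID_POWER: ("c1", "alpha"),
    Family.MONOMIAL: ("c", "a", "b"),
}


@dataclass(frozen=True)
class LogSensitivities:
    """Dimensionless elasticities (f_h, f_p) of the attack rate.

    Both are bounded below by -1 so that the net attack rates
    f*h (per parasitoid) and f*p (per host) are non-decreasing in
    the respective density.
    """

    fh: float
    fp: float

    def __post_init__(self) -> None:
        if self.fh < -1.0 or self.fp < -1.0:
            raise DomainError(
                f"log sensitivities must satisfy fh >= -1 and fp >= -1, "
                f"got (fh={self.fh}, fp={self.fp})"
            )

    def __iter__(self):
        yield self.fh
        yield self.fp


def as_sensitivities(sens) -> LogSensitivities:
    """Coerce a pair or LogSensitivities to LogSensitivities."""
    if isinstance(sens, LogSensitivities):
        return sens
    fh, fp = sens
    return LogSensitivities(float(fh), float(fp))


@dataclass(frozen=True)
class AttackRateModel:
    """A parameterised, strictly positive attack-rate function f(h, p).

    Parameters
    ----------
    family : Family or str
        One of the families documented in the module docstring.
    params : mapping
        Named real parameters; requirements depend on the family.
    """

    family: Family
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        try:
            fam = Family(self.family)
        except ValueError:
            raise ConfigurationError(f"unknown attack-rate family: {self.family!r}")
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "params", dict(self.params))
        missing = [k for k in _REQUIRED[fam] if k not in self.params]
        if missing:
            raise ConfigurationError(
                f"family {fam.value!r} requires parameters {missing}"
            )
        p = self.params
        if fam is Family.CONSTANT and p["c"] <= 0:
            raise ConfigurationError("constant family requires c > 0")
        if fam is Family.TYPE2 and (p["c1"] <= 0 or p["Th"] < 0):
            raise ConfigurationError("type2 requires c1 > 0 and Th >= 0")
        if fam is Family.GENERALIZED_HILL and (
            p["c1"] <= 0 or p["Th"] < 0 or p["q"] < 0
        ):
            raise ConfigurationError(
                "generalized_hill requires c1 > 0, Th >= 0 and q >= 0"
            )
        if fam is Family.PARASITOID_POWER and (
            p["c1"] <= 0 or not -1.0 < p["alpha"] < 1.0
        ):
            raise ConfigurationError(
                "parasitoid_power requires c1 > 0 and -1 < alpha < 1"
            )
        if fam is Family.MONOMIAL and p["c"] <= 0:
            raise ConfigurationError("monomial requires c > 0")

    # families that ignore one density simply do not reference it
    def __call__(self, h: float, p: float) -> float:
        return evaluate(self, h, p)

    def sensitivities(self, h: float, p: float) -> LogSensitivities:
        return log_sensitivities(self, h, p)


def _check_densities(h: float, p: float) -> None:
    if not (h > 0 and p > 0):
        raise DomainError(f"densities must be positive, got (h={h}, p={p})")


def evaluate(model: AttackRateModel, h: float, p: float) -> float:
    """Evaluate f(h, p) > 0 for the model's family."""
    _check_densities(h, p)
    pr = model.params
    fam = model.family
    if fam is Family.CONSTANT:
        return pr["c"]
    if fam is Family.TYPE2:
        return pr["c1"] / (1.0 + pr["c1"] * pr["Th"] * h)
    if fam is Family.GENERALIZED_HILL:
        q = pr["q"]
        return pr["c1"] * h**q / (1.0 + pr["c1"] * pr["Th"] * h ** (q + 1.0))
    if fam is Family.PARASITOID_POWER:
        return pr["c1"] * p ** pr["alpha"]
    if fam is Family.MONOMIAL:
        return pr["c"] * h ** pr["a"] * p ** pr["b"]
    raise ConfigurationError(f"unknown family {fam!r}")  # pragma: no cover


def log_sensitivities(model: AttackRateModel, h: float, p: float) -> LogSensitivities:
    """Analytic elasticities (f_h, f_p) of the attack rate at (h, p)."""
    _check_densities(h, p)
    pr = model.params
    fam = model.family
    if fam is Family.CONSTANT:
        return LogSensitivities(0.0, 0.0)
    if fam is Family.TYPE2:
        x = pr["c1"] * pr["Th"] * h
        return LogSensitivities(-x / (1.0 + x), 0.0)
    if fam is Family.GENERALIZED_HILL:
        q = pr["q"]
        x = pr["c1"] * pr["Th"] * h ** (q + 1.0)
        # d log f / d log h = q - (q+1) * x / (1+x)
        return LogSensitivities(q - (q + 1.0) * x / (1.0 + x), 0.0)
    if fam is Family.PARASITOID_POWER:
        return LogSensitivities(0.0, pr["alpha"])
    if fam is Family.MONOMIAL:
        return LogSensitivities(pr["a"], pr["b"])
    raise ConfigurationError(f"unknown family {fam!r}")  # pragma: no cover


def numeric_log_sensitivities(
    model: AttackRateModel, h: float, p: float, rel_step: float = 1e-6
) -> tuple[float, float]:
    """Central-difference elasticities in log space.

    Independent fallback/cross-check for :func:`log_sensitivities`;
    agreement to ~1e-6 relative is part of the module contract.
    """
    _check_densities(h, p)
    d = rel_step

    def dlog(xup: float, xdn: float) -> float:
        return (math.log(xup) - math.log(xdn)) / (2.0 * d)

    fh = dlog(
        evaluate(model, h * math.exp(d), p), evaluate(model, h * math.exp(-d), p)
    )
    fp = dlog(
        evaluate(model, h, p * math.exp(d)), evaluate(model, h, p * math.exp(-d))
    )
    return fh, fp


def type2_fh_closed_form(c1: float, Th: float, h: float) -> float:
    """Host elasticity -c1*Th*h / (1 + c1*Th*h) of the saturating response.

    Lies in (-1, 0] and tends to -1 as the handling time grows, which is
    why long handling times alone can never be rescued by interference.
    """
    if c1 <= 0 or Th < 0 or h <= 0:
        raise DomainError("require c1 > 0, Th >= 0, h > 0")
    x = c1 * Th * h
    return -x / (1.0 + x)
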