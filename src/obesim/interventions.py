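"""Intervention impact algebra and the alternative/scenario catalogs.

Two kinds of intervention act on the behavioral parameters:

* prevention — reduces social transmission rates (adult prevention reduces
  the adult-to-adult rate; child prevention reduces the child-to-child rate
  and, at a discounted strength, the adult-to-child rate);
* treatment — increases the proportion of overweight/obese individuals
  engaging in weight-loss behaviors.

An intervention aimed at one age group also carries over to the other at a
fraction set by the impact factors: psi_a scales how much adult interventions
reach children, psi_c how much child interventions reach adults. Total impacts
are the direct impact plus the carried-over fraction of the other group's
impact. Effects ramp in linearly over the simulation horizon, reaching the
full total impact (a relative change of the targeted parameter) at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import FrozenSet, List

from .model import BehaviorParams, ParamSchedule

#: Default relative change of each directly targeted parameter at the end of
#: the ramp (50% increase for engagement proportions, 50% decrease for
#: transmission rates).
DEFAULT_MAGNITUDE = 0.5
#: Default attenuation of child prevention's effect on the adult-to-child
#: transmission rate relative to its effect on the child-to-child rate.
DEFAULT_DISCOUNT = 0.5

ADULT_PREVENTION = "adult_prevention"
ADULT_TREATMENT = "adult_treatment"
CHILD_PREVENTION = "child_prevention"
CHILD_TREATMENT = "child_treatment"
COMPONENTS = (ADULT_PREVENTION, ADULT_TREATMENT, CHILD_PREVENTION, CHILD_TREATMENT)


def _check_unit(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not math.isfinite(v) or v < 0 or v > 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class InterventionImpacts:
    """Direct intervention impacts per targetable subgroup (fractions).

    ``eta_na``/``eta_nc``: adult/child prevention; ``eta_sa``/``eta_sc``:
    adult/child overweight treatment; ``eta_oa``/``eta_oc``: adult/child
    obesity treatment.
    """

    eta_nc: float = 0.0
    eta_sc: float = 0.0
    eta_oc: float = 0.0
    eta_na: float = 0.0
    eta_sa: float = 0.0
    eta_oa: float = 0.0

    def __post_init__(self) -> None:
        _check_unit(self, ("eta_nc", "eta_sc", "eta_oc", "eta_na", "eta_sa", "eta_oa"))


@dataclass(frozen=True)
class ImpactFactors:
    """Cross-group carry-over fractions and the adult-to-child discount."""

    psi_a: float
    psi_c: float
    discount: float = DEFAULT_DISCOUNT

    def __post_init__(self) -> None:
        _check_unit(self, ("psi_a", "psi_c", "discount"))


@dataclass(frozen=True)
class TotalImpacts:
    """Coupled total impacts: direct impact plus carried-over fraction."""

    h_nc: float = 0.0
    h_sc: float = 0.0
    h_oc: float = 0.0
    h_na: float = 0.0
    h_sa: float = 0.0
    h_oa: float = 0.0

    def __post_init__(self) -> None:
        for name in ("h_nc", "h_sc", "h_oc", "h_na", "h_sa", "h_oa"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def total_impacts(impacts: InterventionImpacts, factors: ImpactFactors) -> TotalImpacts:
    """Couple direct impacts across age groups.

    Each total is the direct impact plus the corresponding impact on the
    other age group scaled by that group's carry-over factor: child totals
    gain psi_a times the adult impact, adult totals gain psi_c times the
    child impact.
    """
    return TotalImpacts(
        h_nc=impacts.eta_nc + factors.psi_a * impacts.eta_na,
        h_sc=impacts.eta_sc + factors.psi_a * impacts.eta_sa,
        h_oc=impacts.eta_oc + factors.psi_a * impacts.eta_oa,
        h_na=impacts.eta_na + factors.psi_c * impacts.eta_nc,
        h_sa=impacts.eta_sa + factors.psi_c * impacts.eta_sc,
        h_oa=impacts.eta_oa + factors.psi_c * impacts.eta_oc,
    )


def effective_params(
    base: BehaviorParams,
    totals: TotalImpacts,
    factors: ImpactFactors,
    t: float,
    ramp_horizon: float,
) -> BehaviorParams:
    """Behavioral parameters at time ``t`` under a linear intervention ramp.

    With ramp fraction r(t) = min(t / ramp_horizon, 1), exactly seven
    parameters are modified:

    * transmission rates scale down: beta_aa by (1 - h_na*r), beta_cc by
      (1 - h_nc*r), beta_ac by (1 - discount*h_nc*r);
    * engagement proportions scale up: rho_awl by (1 + h_sa*r), eps_awl by
      (1 + h_oa*r), rho_cwl by (1 + h_sc*r), eps_cwl by (1 + h_oc*r),
      each capped at 1.

    Progression rates and transition times are never modified. Raises
    ValueError if an uncapped total would drive a transmission rate negative.
    """
    if ramp_horizon <= 0:
        raise ValueError(f"ramp_horizon must be > 0, got {ramp_horizon}")
    r = min(t / ramp_horizon, 1.0)
    for name, h in (("beta_aa", totals.h_na), ("beta_cc", totals.h_nc)):
        if h * r > 1.0:
            raise ValueError(
                f"total impact {h} would make {name} negative at t={t}"
            )
    if factors.discount * totals.h_nc * r > 1.0:
        raise ValueError(
            f"discounted total impact would make beta_ac negative at t={t}"
        )
    return replace(
        base,
        beta_aa=base.beta_aa * (1.0 - totals.h_na * r),
        beta_cc=base.beta_cc * (1.0 - totals.h_nc * r),
        beta_ac=base.beta_ac * (1.0 - factors.discount * totals.h_nc * r),
        rho_awl=min(base.rho_awl * (1.0 + totals.h_sa * r), 1.0),
        eps_awl=min(base.eps_awl * (1.0 + totals.h_oa * r), 1.0),
        rho_cwl=min(base.rho_cwl * (1.0 + totals.h_sc * r), 1.0),
        eps_cwl=min(base.eps_cwl * (1.0 + totals.h_oc * r), 1.0),
    )


def intervention_schedule(
    base: BehaviorParams,
    totals: TotalImpacts,
    factors: ImpactFactors,
    ramp_horizon: float,
) -> ParamSchedule:
    """Time-dependent parameter schedule for the integrator."""
    return lambda t: effective_params(base, totals, factors, t, ramp_horizon)


@dataclass(frozen=True)
class Alternative:
    """A named combination of prevention/treatment components."""

    name: str
    components: FrozenSet[str]

    def __post_init__(self) -> None:
        unknown = set(self.components) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")

    def impacts(self, magnitude: float = DEFAULT_MAGNITUDE) -> InterventionImpacts:
        """Direct impacts: each active component sets its subgroup impacts."""
        return InterventionImpacts(
            eta_na=magnitude if ADULT_PREVENTION in self.components else 0.0,
            eta_sa=magnitude if ADULT_TREATMENT in self.components else 0.0,
            eta_oa=magnitude if ADULT_TREATMENT in self.components else 0.0,
            eta_nc=magnitude if CHILD_PREVENTION in self.components else 0.0,
            eta_sc=magnitude if CHILD_TREATMENT in self.components else 0.0,
            eta_oc=magnitude if CHILD_TREATMENT in self.components else 0.0,
        )


@dataclass(frozen=True)
class Scenario:
    """A (psi_a, psi_c) impact-factor setting."""

    label: str
    psi_a: float
    psi_c: float

    def factors(self, discount: float = DEFAULT_DISCOUNT) -> ImpactFactors:
        return ImpactFactors(psi_a=self.psi_a, psi_c=self.psi_c, discount=discount)


_ALTERNATIVES = [
    ("AP", (ADULT_PREVENTION,)),
    ("CP", (CHILD_PREVENTION,)),
    ("AT", (ADULT_TREATMENT,)),
    ("CT", (CHILD_TREATMENT,)),
    ("APCP", (ADULT_PREVENTION, CHILD_PREVENTION)),
    ("ATCT", (ADULT_TREATMENT, CHILD_TREATMENT)),
    ("ATCP", (ADULT_TREATMENT, CHILD_PREVENTION)),
    ("APCT", (ADULT_PREVENTION, CHILD_TREATMENT)),
    ("CPCT", (CHILD_PREVENTION, CHILD_TREATMENT)),
    ("APAT", (ADULT_PREVENTION, ADULT_TREATMENT)),
    ("APCPCT", (ADULT_PREVENTION, CHILD_PREVENTION, CHILD_TREATMENT)),
    ("ATCPCT", (ADULT_TREATMENT, CHILD_PREVENTION, CHILD_TREATMENT)),
    ("APATCP", (ADULT_PREVENTION, ADULT_TREATMENT, CHILD_PREVENTION)),
    ("APATCT", (ADULT_PREVENTION, ADULT_TREATMENT, CHILD_TREATMENT)),
    ("ALL", COMPONENTS),
]


def alternative_catalog() -> List[Alternative]:
    """The 15 named prevention/treatment combinations.

    "ALL" (all four components) is also reported in results as APATCPCT.
    """
    return [Alternative(name, frozenset(comps)) for name, comps in _ALTERNATIVES]


def scenario_catalog() -> List[Scenario]:
    """The 6 impact-factor scenarios: psi_a in {25%, 50%, 75%} crossed with
    psi_c in {10%, 25%}."""
    out = []
    for i, psi_c in enumerate((0.10, 0.25)):
        for j, psi_a in enumerate((0.25, 0.50, 0.75)):
            out.append(Scenario(label=f"Scenario {3 * i + j + 1}", psi_a=psi_a, psi_c=psi_c))
    return out
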