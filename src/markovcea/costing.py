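"""Intervention and per-cycle state cost construction.

One-time intervention costs (equipment amortised per patient, personnel
time over a 20-session course, a per-course drug cost) are summed from
components.  Per-cycle state costs combine utilization-weighted
healthcare costs (physician visits, specialist referrals, diagnostic
tests, drugs) with human-capital productivity losses (paid hours valued
at the average wage, unpaid hours at the minimum wage).  All amounts
are 2020 Canadian dollars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import STATES

__all__ = [
    "CostComponent",
    "InterventionCostComponents",
    "StateUtilizationProfile",
    "ProductivityProfile",
    "SOCIETAL",
    "PAYER",
    "PERSPECTIVES",
    "personnel_session_cost",
    "total_intervention_cost",
    "amortize_equipment",
    "state_cycle_healthcare_cost",
    "productivity_cycle_cost",
    "apply_perspective",
    "TEST_GIVEN_EITHER",
    "TEST_GIVEN_VISIT",
    "TEST_INCLUSION_EXCLUSION",
]

SOCIETAL = "societal"
PAYER = "payer"
PERSPECTIVES = (SOCIETAL, PAYER)

# Composition rules for the conditional diagnostic-test probability.
TEST_GIVEN_EITHER = "additive"            # p(test) * (p(visit) + p(referral))
TEST_GIVEN_VISIT = "visit-only"           # p(test) * p(visit)
TEST_INCLUSION_EXCLUSION = "inclusion-exclusion"  # p(test) * (p(v)+p(r)-p(v)p(r))


@dataclass(frozen=True)
class CostComponent:
    """One additive piece of an intervention cost (already per patient).

    ``sd`` is the PSA standard deviation; ``None`` marks a fixed input
    (no distribution printed for it).
    """

    name: str
    mean: float
    sd: float | None = None
    dist: str = "fixed"

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError(f"cost component {self.name!r} must be non-negative")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"cost component {self.name!r} sd must be non-negative")


@dataclass(frozen=True)
class InterventionCostComponents:
    """All per-patient components of a strategy's one-time intervention cost."""

    components: tuple[CostComponent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def total(self) -> float:
        return total_intervention_cost(self)


@dataclass(frozen=True)
class StateUtilizationProfile:
    """Per-state healthcare utilization with shared unit costs.

    Per two-week cycle and per state: probability of a physician visit,
    probability of a specialist referral, conditional probability that a
    diagnostic test is ordered given contact, and a drug cost.  Unit
    costs are shared across states.
    """

    p_physician_visit: np.ndarray
    p_specialist_referral: np.ndarray
    p_diagnostic_test: np.ndarray
    drug_cost: np.ndarray
    unit_cost_physician: float
    unit_cost_specialist: float
    unit_cost_test: float
    test_rule: str = TEST_GIVEN_EITHER

    def __post_init__(self) -> None:
        for name in ("p_physician_visit", "p_specialist_referral", "p_diagnostic_test"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (len(STATES),):
                raise ValueError(f"{name} must have one entry per state")
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
            object.__setattr__(self, name, v)
        drugs = np.asarray(self.drug_cost, dtype=float)
        if drugs.shape != (len(STATES),) or np.any(drugs < 0):
            raise ValueError("drug_cost must be a non-negative per-state vector")
        object.__setattr__(self, "drug_cost", drugs)
        for name in ("unit_cost_physician", "unit_cost_specialist", "unit_cost_test"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.test_rule not in (TEST_GIVEN_EITHER, TEST_GIVEN_VISIT, TEST_INCLUSION_EXCLUSION):
            raise ValueError(f"unknown test composition rule {self.test_rule!r}")


@dataclass(frozen=True)
class ProductivityProfile:
    """Human-capital productivity losses per state.

    Hours lost per *month* from paid and unpaid work; a two-week cycle
    accrues half a month's hours.  Paid hours are valued at the average
    hourly wage, unpaid hours at the minimum hourly wage.
    """

    paid_hours_per_month: np.ndarray
    unpaid_hours_per_month: np.ndarray
    average_hourly_wage: float
    minimum_hourly_wage: float

    def __post_init__(self) -> None:
        for name in ("paid_hours_per_month", "unpaid_hours_per_month"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (len(STATES),) or np.any(v < 0):
                raise ValueError(f"{name} must be a non-negative per-state vector")
            object.__setattr__(self, name, v)
        if self.average_hourly_wage <= 0 or self.minimum_hourly_wage <= 0:
            raise ValueError("wages must be positive")


def personnel_session_cost(
    n_sessions: int,
    first_session_minutes: float,
    subsequent_session_minutes: float,
    hourly_rate: float,
) -> float:
    """Personnel cost over a session course.

    The first session runs longer (registration and set-up); total time
    is ``first + (n_sessions - 1) * subsequent`` minutes, billed at the
    hourly rate.

    Examples
    --------
    A 20-session course (45 min first, 30 min after) at $36.12/h is
    10.25 h -> $370.23.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if first_session_minutes < 0 or subsequent_session_minutes < 0 or hourly_rate < 0:
        raise ValueError("durations and rate must be non-negative")
    hours = (first_session_minutes + (n_sessions - 1) * subsequent_session_minutes) / 60.0
    return hours * hourly_rate


def total_intervention_cost(components: InterventionCostComponents) -> float:
    """Arithmetic sum of per-patient component costs."""
    return float(sum(c.mean for c in components.components))


def amortize_equipment(
    purchase_cost: float, lifespan_years: float, patients_per_year: float
) -> float:
    """Per-patient share of an equipment purchase over its lifespan."""
    if lifespan_years <= 0 or patients_per_year <= 0:
        raise ValueError("lifespan_years and patients_per_year must be positive")
    if purchase_cost < 0:
        raise ValueError("purchase_cost must be non-negative")
    return purchase_cost / (lifespan_years * patients_per_year)


def _contact_weight(p_visit: float, p_ref: float, rule: str) -> float:
    if rule == TEST_GIVEN_EITHER:
        return p_visit + p_ref
    if rule == TEST_GIVEN_VISIT:
        return p_visit
    if rule == TEST_INCLUSION_EXCLUSION:
        return p_visit + p_ref - p_visit * p_ref
    raise ValueError(f"unknown test composition rule {rule!r}")


def state_cycle_healthcare_cost(profile: StateUtilizationProfile, state: str) -> float:
    """Utilization-weighted healthcare cost for one state and one cycle.

    cost = p(visit) c(visit) + p(referral) c(specialist)
           + p(test | contact) w(contact) c(test) + drug cost,

    where the contact weight ``w`` defaults to ``p(visit) + p(referral)``
    (configurable via ``profile.test_rule``).
    """
    i = STATES.index(state)
    w = _contact_weight(
        profile.p_physician_visit[i], profile.p_specialist_referral[i], profile.test_rule
    )
    return float(
        profile.p_physician_visit[i] * profile.unit_cost_physician
        + profile.p_specialist_referral[i] * profile.unit_cost_specialist
        + profile.p_diagnostic_test[i] * w * profile.unit_cost_test
        + profile.drug_cost[i]
    )


def productivity_cycle_cost(profile: ProductivityProfile, state: str) -> float:
    """Human-capital productivity loss for one state over one two-week cycle."""
    i = STATES.index(state)
    return float(
        profile.paid_hours_per_month[i] / 2.0 * profile.average_hourly_wage
        + profile.unpaid_hours_per_month[i] / 2.0 * profile.minimum_hourly_wage
    )


def apply_perspective(
    healthcare_costs, productivity_costs, perspective: str
) -> np.ndarray:
    """Combine per-state cost components under an analytic perspective.

    The societal perspective adds productivity losses to healthcare
    costs; the public-healthcare-payer perspective counts healthcare
    costs only.
    """
    hc = np.asarray(healthcare_costs, dtype=float)
    pr = np.asarray(productivity_costs, dtype=float)
    if perspective == SOCIETAL:
        return hc + pr
    if perspective == PAYER:
        return hc.copy()
    raise ValueError(f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}")


def state_cost_vector(
    utilization: StateUtilizationProfile,
    productivity: ProductivityProfile,
    perspective: str = SOCIETAL,
) -> np.ndarray:
    """Per-cycle cost vector over (mild, moderate, severe) under a perspective."""
    hc = np.array([state_cycle_healthcare_cost(utilization, s) for s in STATES])
    pr = np.array([productivity_cycle_cost(productivity, s) for s in STATES])
    return apply_perspective(hc, pr, perspective)
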