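"""Scenario analyses: perspective, horizon, utility-set and cost overrides.

Six shipped scenarios mirror the published sensitivity analyses:

* ``payer`` — public-healthcare-payer perspective (productivity costs
  excluded);
* ``1-year`` / ``2-year`` — horizon extended beyond three months with
  state membership frozen at the 3-month occupancy; the 2-year scenario
  discounts at 1.5% per annum;
* ``utilities-dixon`` / ``utilities-gordon`` — alternative utility sets
  (0.93/0.80/0.34 and 0.71/0.47/0.20);
* ``alt-vr-cost`` — virtual-reality equipment recosted at $3,500 per
  year, amortised per patient.

Long-term (3-12 month and year-2) per-state costs are synthetic
placeholder inputs, so extended-horizon cost outputs are structural
rather than value-reproducing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .costing import SOCIETAL, CostComponent, InterventionCostComponents
from .markov import CYCLE_LENGTH_YEARS, CohortTrace, ModelSpec, UtilitySet
from .params import ParameterSet
from .psa import BASE_HORIZON_YEARS, _extend, run_psa

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "scenario_names",
    "discount",
    "extend_horizon",
    "apply_scenario",
    "run_scenario",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Partial override of the base-case analysis configuration."""

    name: str
    perspective: str = SOCIETAL
    horizon_years: float = BASE_HORIZON_YEARS
    discount_rate: float = 0.0
    utility_set: str = "base"
    vr_equipment_annual_cost: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")
        if self.horizon_years < BASE_HORIZON_YEARS:
            raise ValueError("scenario horizon must not be shorter than the base horizon")


SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in (
        ScenarioSpec(
            "payer",
            perspective="payer",
            description="Public healthcare payer perspective: productivity costs excluded.",
        ),
        ScenarioSpec(
            "1-year",
            horizon_years=1.0,
            description="Horizon extended to 1 year with frozen state membership.",
        ),
        ScenarioSpec(
            "2-year",
            horizon_years=2.0,
            discount_rate=0.015,
            description="Horizon extended to 2 years; 1.5%/yr discount rate.",
        ),
        ScenarioSpec(
            "utilities-dixon",
            utility_set="dixon",
            description="Alternative utilities 0.93 / 0.80 / 0.34.",
        ),
        ScenarioSpec(
            "utilities-gordon",
            utility_set="gordon",
            description="Alternative utilities 0.71 / 0.47 / 0.20.",
        ),
        ScenarioSpec(
            "alt-vr-cost",
            vr_equipment_annual_cost=3500.0,
            description="VR equipment recosted at $3,500 per year, amortised per patient.",
        ),
    )
}

#: Names of the VI equipment components replaced by the alt-VR-cost scenario.
_VR_EQUIPMENT = (
    "Projector",
    "Screen",
    "Video",
    "Portable computer",
    "Vertical mirror",
    "Loudspeakers",
)


def scenario_names() -> list[str]:
    return list(SCENARIOS)


def discount(stream, annual_rate: float, cycle_length: float = CYCLE_LENGTH_YEARS) -> float:
    """Discounted total of a per-cycle value stream.

    The value at cycle k (k = 0, 1, ...) is multiplied by
    ``(1 + rate)^(-k * cycle_length_in_years)``.  The base case uses
    rate 0 (no discounting over the three-month horizon).
    """
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    v = np.asarray(stream, dtype=float)
    k = np.arange(v.size)
    return float((v * (1.0 + annual_rate) ** (-(k * cycle_length))).sum())


def extend_horizon(
    trace: CohortTrace,
    horizon_years: float,
    long_term_costs,
    utilities: UtilitySet,
    discount_rate: float = 0.0,
    cycle_length: float = CYCLE_LENGTH_YEARS,
) -> tuple[float, float]:
    """Cost and QALY accrued from the 3-month point out to ``horizon_years``.

    The final 3-month occupancy is held fixed; ``long_term_costs`` is a
    per-state *per-cycle* cost vector applied over the extension, with
    utility-weighted time accrued in parallel and both discounted per
    cycle at the annual rate.  Returns ``(extension_cost,
    extension_qaly)``; an extension of zero returns ``(0, 0)``.
    """
    lt = np.asarray(long_term_costs, dtype=float)[None, :]
    cost, qaly = _extend(
        trace.final[None, :],
        np.asarray(utilities.means, dtype=float)[None, :],
        lt,
        horizon_years,
        discount_rate,
        cycle_length,
    )
    return float(cost[0]), float(qaly[0])


def apply_scenario(scenario: ScenarioSpec, params: ParameterSet) -> ParameterSet:
    """Parameter-level overrides for a scenario (currently VR recosting)."""
    if scenario.vr_equipment_annual_cost is None:
        return params
    per_patient = scenario.vr_equipment_annual_cost / params.patients_per_year
    vi = params.strategies["vi_tdcs"]
    kept = tuple(c for c in vi.intervention.components if c.name not in _VR_EQUIPMENT)
    new = kept + (
        CostComponent("VR equipment (annual recosting)", per_patient, per_patient * 0.25, "gamma"),
    )
    strategies = dict(params.strategies)
    strategies["vi_tdcs"] = replace(vi, intervention=InterventionCostComponents(new))
    return replace(params, strategies=strategies)


def run_scenario(
    name_or_spec: str | ScenarioSpec,
    params: ParameterSet,
    spec: ModelSpec | None = None,
    n_iterations: int = 1000,
    seed: int = 2020,
) -> pd.DataFrame:
    """Run one scenario through the PSA pipeline.

    Returns a per-strategy results table (mean cost and QALYs with 95%
    CIs, incrementals versus standard care, ICER or dominance label).
    Unknown scenario names raise with the list of valid names.
    """
    if isinstance(name_or_spec, str):
        try:
            scenario = SCENARIOS[name_or_spec]
        except KeyError:
            raise KeyError(
                f"unknown scenario {name_or_spec!r}; valid names: {scenario_names()}"
            ) from None
    else:
        scenario = name_or_spec
    sc_params = apply_scenario(scenario, params)
    result = run_psa(
        sc_params,
        spec=spec,
        n_iterations=n_iterations,
        seed=seed,
        perspective=scenario.perspective,
        utility_set=scenario.utility_set,
        horizon_years=scenario.horizon_years,
        discount_rate=scenario.discount_rate,
    )
    table = result.summary()
    table.insert(0, "scenario", scenario.name)
    return table
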