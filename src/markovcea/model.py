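"""Model/Results interface over the cohort engine.

:class:`CostUtilityModel` bundles a parameter set with a run
configuration.  ``run()`` evaluates the deterministic base case
(expected values at the parameter means) and ``fit()`` performs the
probabilistic sensitivity analysis; both return results objects with a
``summary()`` table shaped like a published base-case results table.

    >>> from markovcea import CostUtilityModel
    >>> model = CostUtilityModel.from_defaults()
    >>> base = model.run()          # deterministic expected values
    >>> psa = model.fit(seed=2020)  # 1,000-iteration PSA
    >>> psa.summary()               # costs, QALYs, CIs, ICERs
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .costing import SOCIETAL, state_cost_vector, total_intervention_cost
from .markov import CohortTrace, ModelSpec, run_cohort
from .params import STRATEGY_LABELS, STRATEGY_ORDER, ParameterSet, builtin_parameter_set
from .psa import (
    BASE_HORIZON_YEARS,
    PSAResult,
    evaluate_deterministic,
    incremental_analysis,
    run_psa,
)

__all__ = ["CostUtilityModel", "DeterministicResults"]


@dataclass(frozen=True)
class DeterministicResults:
    """Expected costs and QALYs per strategy at the parameter means."""

    costs: dict[str, float]
    qalys: dict[str, float]
    traces: dict[str, CohortTrace]
    perspective: str
    metadata: dict = field(default_factory=dict)

    def occupancy(self, strategy: str) -> np.ndarray:
        """Final state-occupancy vector (mild, moderate, severe)."""
        return self.traces[strategy].final

    def incremental(self, reference: str = "standard_care") -> pd.DataFrame:
        return incremental_analysis((self.costs, self.qalys), reference=reference)

    def summary(self, reference: str = "standard_care") -> pd.DataFrame:
        inc = self.incremental(reference)
        rows = []
        for s in self.costs:
            r = inc.loc[s]
            rows.append(
                {
                    "strategy": STRATEGY_LABELS.get(s, s),
                    "cost": self.costs[s],
                    "incremental_cost": r["incremental_cost"],
                    "qaly": self.qalys[s],
                    "incremental_qaly": r["incremental_qaly"],
                    "icer": r["icer"],
                    "label": r["label"],
                }
            )
        return pd.DataFrame(rows, index=list(self.costs))


class CostUtilityModel:
    """Three-state Markov cohort cost-utility model.

    Parameters
    ----------
    params : ParameterSet
        Model inputs (transitions, utilities, costs, PSA distributions).
    spec : ModelSpec, optional
        Cycle structure; defaults to the three-month base case (6
        transitions of two weeks each, all mass starting severe,
        initial state counted).
    perspective : str
        ``societal`` (default) or ``payer``.
    utility_set : str
        Which utility set in ``params.utilities`` to use.
    horizon_years, discount_rate : float
        Horizon (default 0.25 = three months) and annual discount rate
        (default 0); horizons beyond three months freeze state
        membership at the 3-month occupancy.
    """

    def __init__(
        self,
        params: ParameterSet,
        spec: ModelSpec | None = None,
        perspective: str = SOCIETAL,
        utility_set: str = "base",
        horizon_years: float = BASE_HORIZON_YEARS,
        discount_rate: float = 0.0,
    ) -> None:
        self.params = params
        self.spec = spec or ModelSpec()
        self.perspective = perspective
        self.utility_set = utility_set
        self.horizon_years = horizon_years
        self.discount_rate = discount_rate

    @classmethod
    def from_defaults(cls, **kwargs) -> "CostUtilityModel":
        """Model with the built-in (published) parameter set."""
        return cls(builtin_parameter_set(), **kwargs)

    @classmethod
    def from_json(cls, path: str | Path, **kwargs) -> "CostUtilityModel":
        """Model from a JSON parameter document."""
        return cls(ParameterSet.from_json(path), **kwargs)

    # -- deterministic -----------------------------------------------

    def trace(self, strategy: str) -> CohortTrace:
        """Deterministic cohort trace for one strategy."""
        tm = self.params.strategies[strategy].transitions.deterministic()
        return run_cohort(self.spec, tm)

    def state_costs(self) -> np.ndarray:
        """Per-cycle state cost vector under the model's perspective."""
        return state_cost_vector(
            self.params.utilization, self.params.productivity, self.perspective
        )

    def intervention_cost(self, strategy: str) -> float:
        return total_intervention_cost(self.params.strategies[strategy].intervention)

    def run(self) -> DeterministicResults:
        """Deterministic base case: expected values at the parameter means."""
        costs, qalys = evaluate_deterministic(
            self.params,
            self.spec,
            perspective=self.perspective,
            utility_set=self.utility_set,
            horizon_years=self.horizon_years,
            discount_rate=self.discount_rate,
        )
        traces = {s: self.trace(s) for s in STRATEGY_ORDER}
        return DeterministicResults(
            costs=costs,
            qalys=qalys,
            traces=traces,
            perspective=self.perspective,
            metadata={
                "utility_set": self.utility_set,
                "horizon_years": self.horizon_years,
                "discount_rate": self.discount_rate,
            },
        )

    # -- probabilistic -----------------------------------------------

    def fit(self, n_iterations: int = 1000, seed: int = 2020) -> PSAResult:
        """Probabilistic sensitivity analysis (Monte Carlo).

        Returns a :class:`~markovcea.psa.PSAResult`; its ``summary()``,
        ``ceac()`` and ``ce_plane()`` methods derive the published
        outputs.
        """
        return run_psa(
            self.params,
            spec=self.spec,
            n_iterations=n_iterations,
            seed=seed,
            perspective=self.perspective,
            utility_set=self.utility_set,
            horizon_years=self.horizon_years,
            discount_rate=self.discount_rate,
        )
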