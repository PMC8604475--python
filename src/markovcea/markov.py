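"""Deterministic three-state Markov cohort engine.

The cohort model tracks the proportion of a neuropathic-pain cohort in
three mutually exclusive pain-severity states (mild, moderate, severe,
defined by NRS bands 0-3 / 4-6 / 7-10) over two-week cycles.  An
*induction* transition matrix governs the first transition (the initial
treatment cycle) and a *maintenance* matrix governs every later
transition.  QALYs and costs are accumulated over the resulting
state-occupancy trace.

Two counting conventions are supported.  The default,
``include-initial-state``, counts the initial occupancy vector as a full
cycle of accrual, so a run with ``n_transitions = 6`` accrues over seven
occupancy vectors; ``exclude-initial-state`` skips the time-zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STATES",
    "NRS_RANGES",
    "HealthState",
    "TransitionModel",
    "ModelSpec",
    "CohortTrace",
    "UtilitySet",
    "CYCLE_LENGTH_YEARS",
    "INCLUDE_INITIAL",
    "EXCLUDE_INITIAL",
    "normalize_transition_rows",
    "run_cohort",
    "accumulate_qalys",
    "accumulate_costs",
]

#: State labels in canonical order.  All vectors and matrices in this
#: package use this ordering.
STATES = ("mild", "moderate", "severe")

#: Pain-intensity bands on the 11-point numerical rating scale.
NRS_RANGES = {"mild": (0, 3), "moderate": (4, 6), "severe": (7, 10)}

#: Two-week cycle expressed in years.
CYCLE_LENGTH_YEARS = 2.0 / 52.0

INCLUDE_INITIAL = "include-initial-state"
EXCLUDE_INITIAL = "exclude-initial-state"


@dataclass(frozen=True)
class HealthState:
    """A pain-severity health state with its NRS band."""

    label: str
    nrs_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.label not in STATES:
            raise ValueError(f"unknown health state {self.label!r}; expected one of {STATES}")
        if self.nrs_range != NRS_RANGES[self.label]:
            raise ValueError(
                f"NRS range {self.nrs_range} does not match the canonical band "
                f"{NRS_RANGES[self.label]} for {self.label!r}"
            )

    @property
    def index(self) -> int:
        return STATES.index(self.label)


HEALTH_STATES = tuple(HealthState(s, NRS_RANGES[s]) for s in STATES)


def normalize_transition_rows(matrix: np.ndarray) -> np.ndarray:
    """Rescale each row of a non-negative matrix to sum to one.

    Printed transition tables occasionally carry rounding slack (a row
    summing to 1.01, say); dividing each row by its own sum restores a
    proper stochastic matrix while leaving exact-zero entries at zero
    and preserving the ordering of magnitudes within a row.

    Parameters
    ----------
    matrix : array-like, shape (n, n)
        Non-negative transition probabilities.

    Returns
    -------
    numpy.ndarray
        Row-stochastic copy of ``matrix``.

    Raises
    ------
    ValueError
        If any entry is negative or any row sums to zero.
    """
    m = np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise ValueError("transition probabilities must be non-negative")
    sums = m.sum(axis=1)
    if np.any(sums <= 0):
        bad = int(np.flatnonzero(sums <= 0)[0])
        raise ValueError(f"invalid transition matrix: row {bad} sums to zero")
    return m / sums[:, None]


def _check_row_stochastic(m: np.ndarray, name: str, atol: float = 1e-12) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (len(STATES), len(STATES)):
        raise ValueError(f"{name} matrix must be {len(STATES)}x{len(STATES)}, got {m.shape}")
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError(f"{name} matrix entries must lie in [0, 1]")
    if not np.allclose(m.sum(axis=1), 1.0, atol=atol):
        raise ValueError(f"{name} matrix rows must sum to 1 (normalize first)")
    return m


@dataclass(frozen=True)
class TransitionModel:
    """Induction- and maintenance-cycle transition matrices for one strategy.

    ``induction`` is applied for the first transition only (the initial
    treatment cycle); ``maintenance`` for every transition thereafter.
    Both must be row-stochastic on construction.
    """

    induction: np.ndarray
    maintenance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "induction", _check_row_stochastic(self.induction, "induction"))
        object.__setattr__(
            self, "maintenance", _check_row_stochastic(self.maintenance, "maintenance")
        )

    @classmethod
    def from_unnormalized(cls, induction, maintenance) -> "TransitionModel":
        """Build a model, renormalising rows that carry rounding slack."""
        return cls(
            normalize_transition_rows(induction),
            normalize_transition_rows(maintenance),
        )

    @classmethod
    def absorbing(cls, state: str = "severe") -> "TransitionModel":
        """Model for a cohort that never leaves ``state`` (nor enters it).

        Used for standard pharmacological care in a treatment-resistant
        cohort: everyone starts and remains severe.
        """
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}")
        eye = np.eye(len(STATES))
        return cls(eye, eye.copy())


@dataclass(frozen=True)
class ModelSpec:
    """Run configuration for the cohort engine.

    Parameters
    ----------
    cycle_length : float
        Cycle length in years (default two weeks).
    n_transitions : int
        Number of transitions applied; 6 for the three-month base case
        (one induction transition plus five maintenance transitions).
    initial_occupancy : array-like of length 3
        Probability vector over (mild, moderate, severe); the base case
        starts all mass in severe.
    counting : str
        ``include-initial-state`` (default; the calibrated convention,
        7 accrual vectors for the base case) or ``exclude-initial-state``.
    """

    cycle_length: float = CYCLE_LENGTH_YEARS
    n_transitions: int = 6
    initial_occupancy: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    counting: str = INCLUDE_INITIAL

    def __post_init__(self) -> None:
        occ = np.asarray(self.initial_occupancy, dtype=float)
        if occ.shape != (len(STATES),):
            raise ValueError("initial_occupancy must have one entry per state")
        if np.any(occ < 0) or not np.isclose(occ.sum(), 1.0, atol=1e-9):
            raise ValueError("initial_occupancy must be a probability vector summing to 1")
        object.__setattr__(self, "initial_occupancy", occ)
        if self.n_transitions < 1:
            raise ValueError("n_transitions must be >= 1")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.counting not in (INCLUDE_INITIAL, EXCLUDE_INITIAL):
            raise ValueError(
                f"counting must be {INCLUDE_INITIAL!r} or {EXCLUDE_INITIAL!r}"
            )


@dataclass(frozen=True)
class CohortTrace:
    """Sequence of state-occupancy vectors; index k = occupancy after k transitions."""

    occupancy: np.ndarray  # shape (n_transitions + 1, 3)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != len(STATES):
            raise ValueError("trace must be (n_cycles, n_states)")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every occupancy vector must sum to 1")
        object.__setattr__(self, "occupancy", occ)

    def __len__(self) -> int:
        return self.occupancy.shape[0]

    @property
    def final(self) -> np.ndarray:
        """Occupancy after the last transition."""
        return self.occupancy[-1]

    def counted(self, spec: ModelSpec) -> np.ndarray:
        """Occupancy vectors that accrue utility/cost under ``spec.counting``."""
        if spec.counting == INCLUDE_INITIAL:
            return self.occupancy
        return self.occupancy[1:]

    def to_frame(self):
        """Trace as a DataFrame: one row per cycle, one column per state."""
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(len(self)))
        return df


@dataclass(frozen=True)
class UtilitySet:
    """Per-state utilities (0-1) with standard deviations for the PSA."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if means.shape != (len(STATES),) or sds.shape != (len(STATES),):
            raise ValueError("utility means/sds must have one entry per state")
        if np.any(means < 0) or np.any(means > 1):
            raise ValueError("utilities must lie in [0, 1]")
        if np.any(sds < 0):
            raise ValueError("utility sds must be non-negative")
        if not (means[2] <= means[1] <= means[0]):
            raise ValueError("utilities must be non-increasing with severity")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)


def run_cohort(spec: ModelSpec, tm: TransitionModel) -> CohortTrace:
    """Propagate the cohort through the chain.

    ``occupancy[0]`` is the initial vector; ``occupancy[1]`` applies the
    induction matrix; every later step applies the maintenance matrix.
    """
    occ = np.empty((spec.n_transitions + 1, len(STATES)))
    occ[0] = spec.initial_occupancy
    occ[1] = occ[0] @ tm.induction
    for k in range(2, spec.n_transitions + 1):
        occ[k] = occ[k - 1] @ tm.maintenance
    return CohortTrace(occ)


def accumulate_qalys(trace: CohortTrace, utilities: UtilitySet, spec: ModelSpec) -> float:
    """Total QALYs: utility-weighted time in state, summed over counted cycles.

    Each counted occupancy vector contributes
    ``(occupancy . utilities) * cycle_length`` years.
    """
    counted = trace.counted(spec)
    return float((counted @ utilities.means).sum() * spec.cycle_length)


def accumulate_costs(
    trace: CohortTrace,
    per_cycle_state_costs,
    intervention_cost: float,
    spec: ModelSpec,
) -> float:
    """Total cost: one-time intervention cost plus per-cycle state costs.

    The intervention cost is charged once at model start; per-cycle
    costs are occupancy-weighted over the same counted vectors as
    :func:`accumulate_qalys`.
    """
    costs = np.asarray(per_cycle_state_costs, dtype=float)
    if costs.shape != (len(STATES),):
        raise ValueError("per_cycle_state_costs must have one entry per state")
    if np.any(costs < 0) or intervention_cost < 0:
        raise ValueError("costs must be non-negative")
    counted = trace.counted(spec)
    return float(intervention_cost + (counted @ costs).sum())
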