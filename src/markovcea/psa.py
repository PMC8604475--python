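"""Probabilistic sensitivity analysis and cost-effectiveness products.

Each PSA iteration draws one value per uncertain parameter (gamma for
costs, beta for utilities and utilization probabilities, a calibrated
Dirichlet for transition rows), reruns all three strategies on the
shared draws (utilities and state costs are common across strategies
within an iteration), and records total cost and QALYs per strategy.
From the resulting draws the module derives incremental analyses with
dominance labels, cost-effectiveness planes with 95% confidence
ellipses, and cost-effectiveness acceptability curves (CEACs).

Draws are fully reproducible given the seed: the sampling order is
fixed (shared parameters first, then each strategy in canonical order).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import costing
from .costing import SOCIETAL, TEST_GIVEN_EITHER, TEST_GIVEN_VISIT, TEST_INCLUSION_EXCLUSION
from .distributions import sample_beta, sample_gamma, sample_transition_row
from .markov import CYCLE_LENGTH_YEARS, INCLUDE_INITIAL, STATES, ModelSpec
from .params import STRATEGY_LABELS, STRATEGY_ORDER, ParameterSet

__all__ = [
    "BASE_HORIZON_YEARS",
    "DEFAULT_WTP_GRID",
    "PSAResult",
    "CEACCurve",
    "CEPlane",
    "ConfidenceEllipse",
    "run_psa",
    "evaluate_deterministic",
    "incremental_analysis",
    "classify_increment",
    "ceac",
    "ce_plane",
]

#: Nominal length of the primary analysis (three months), in years.
BASE_HORIZON_YEARS = 0.25

#: Default willingness-to-pay grid: 101 points on [0, 100000] $/QALY.
DEFAULT_WTP_GRID = np.linspace(0.0, 100_000.0, 101)

DOMINATES = "dominates"
DOMINATED = "dominated"


# ---------------------------------------------------------------------------
# Core accrual (shared by the deterministic and probabilistic paths)


def _cohort_paths(induction: np.ndarray, maintenance: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Batched cohort propagation: (n,3,3) matrices -> (n, T+1, 3) traces."""
    n = induction.shape[0]
    occ = np.empty((n, spec.n_transitions + 1, len(STATES)))
    occ[:, 0, :] = spec.initial_occupancy
    occ[:, 1, :] = np.einsum("ni,nij->nj", occ[:, 0, :], induction)
    for k in range(2, spec.n_transitions + 1):
        occ[:, k, :] = np.einsum("ni,nij->nj", occ[:, k - 1, :], maintenance)
    return occ


def _accrue(
    occ_paths: np.ndarray,
    utilities: np.ndarray,
    state_costs: np.ndarray,
    intervention: np.ndarray,
    spec: ModelSpec,
    discount_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Costs and QALYs over the counted in-horizon cycles.

    Cycle k accruals are discounted by (1+r)^(-k * cycle_length); the
    one-time intervention cost is charged undiscounted at model start.
    """
    first = 0 if spec.counting == INCLUDE_INITIAL else 1
    ks = np.arange(first, spec.n_transitions + 1)
    disc = (1.0 + discount_rate) ** (-(ks * spec.cycle_length))
    counted = occ_paths[:, ks, :]
    qalys = np.einsum("nmj,nj,m->n", counted, utilities, disc) * spec.cycle_length
    costs = intervention + np.einsum("nmj,nj,m->n", counted, state_costs, disc)
    return costs, qalys


def _extend(
    final_occ: np.ndarray,
    utilities: np.ndarray,
    long_term_cycle_costs: np.ndarray,
    horizon_years: float,
    discount_rate: float,
    cycle_length: float = CYCLE_LENGTH_YEARS,
) -> tuple[np.ndarray, np.ndarray]:
    """Frozen-membership accrual from the 3-month point to the horizon.

    State membership is held at the final 3-month occupancy; per-state
    long-term costs and utility-weighted time accrue per two-week cycle
    (fractional final cycle allowed), discounted at the annual rate from
    the nominal 3-month mark.
    """
    ext_years = horizon_years - BASE_HORIZON_YEARS
    if ext_years < 0:
        raise ValueError("horizon must not be shorter than the 3-month base case")
    if ext_years == 0:
        z = np.zeros(final_occ.shape[0])
        return z, z.copy()
    n_cycles = ext_years / cycle_length
    n_full = math.floor(n_cycles)
    weights = np.ones(math.ceil(n_cycles))
    if n_cycles > n_full:
        weights[-1] = n_cycles - n_full
    t = BASE_HORIZON_YEARS + np.arange(len(weights)) * cycle_length
    disc = weights * (1.0 + discount_rate) ** (-t)
    per_cycle_q = (final_occ * utilities).sum(axis=1) * cycle_length
    per_cycle_c = (final_occ * long_term_cycle_costs).sum(axis=1)
    return per_cycle_c * disc.sum(), per_cycle_q * disc.sum()


# ---------------------------------------------------------------------------
# Parameter sampling


def _contact_weight_batch(pv, pr, rule):
    if rule == TEST_GIVEN_EITHER:
        return pv + pr
    if rule == TEST_GIVEN_VISIT:
        return pv
    if rule == TEST_INCLUSION_EXCLUSION:
        return pv + pr - pv * pr
    raise ValueError(f"unknown test composition rule {rule!r}")


def _sample_state_vec(means, sds, kind, rng, n):
    cols = []
    for mu, sd in zip(means, sds):
        if kind == "beta":
            cols.append(sample_beta(float(mu), float(sd), rng, size=n))
        else:
            cols.append(sample_gamma(float(mu), float(sd), rng, size=n))
    return np.column_stack(cols)


def _sample_shared(params: ParameterSet, utility_set: str, rng, n: int, need_long_term: bool):
    """Draw the parameters shared by all strategies, in fixed order."""
    u = params.utilities[utility_set]
    utilities = _sample_state_vec(u.means, u.sds, "beta", rng, n)

    unc = params.uncertainty
    util = params.utilization
    pv = _sample_state_vec(util.p_physician_visit, [unc.p_sd] * 3, "beta", rng, n)
    pr = _sample_state_vec(util.p_specialist_referral, [unc.p_sd] * 3, "beta", rng, n)
    pt = _sample_state_vec(util.p_diagnostic_test, [unc.p_sd] * 3, "beta", rng, n)
    drug = _sample_state_vec(
        util.drug_cost, util.drug_cost * unc.drug_cost_sd_fraction, "gamma", rng, n
    )
    c_phys = sample_gamma(
        util.unit_cost_physician, util.unit_cost_physician * unc.unit_cost_sd_fraction, rng, n
    )
    c_spec = sample_gamma(
        util.unit_cost_specialist, util.unit_cost_specialist * unc.unit_cost_sd_fraction, rng, n
    )
    c_test = sample_gamma(
        util.unit_cost_test, util.unit_cost_test * unc.unit_cost_sd_fraction, rng, n
    )
    w = _contact_weight_batch(pv, pr, util.test_rule)
    healthcare = (
        pv * c_phys[:, None] + pr * c_spec[:, None] + pt * w * c_test[:, None] + drug
    )

    prod = params.productivity
    paid = _sample_state_vec(
        prod.paid_hours_per_month,
        prod.paid_hours_per_month * unc.hours_sd_fraction,
        "gamma", rng, n,
    )
    unpaid = _sample_state_vec(
        prod.unpaid_hours_per_month,
        prod.unpaid_hours_per_month * unc.hours_sd_fraction,
        "gamma", rng, n,
    )
    productivity = paid / 2.0 * prod.average_hourly_wage + unpaid / 2.0 * prod.minimum_hourly_wage

    long_term = None
    if need_long_term:
        lt = params.long_term
        hc = _sample_state_vec(
            lt.healthcare_annual, lt.healthcare_annual * lt.sd_fraction, "gamma", rng, n
        )
        pc = _sample_state_vec(
            lt.productivity_annual, lt.productivity_annual * lt.sd_fraction, "gamma", rng, n
        )
        long_term = (hc, pc)
    return utilities, healthcare, productivity, long_term


def _sample_transition_matrices(strategy, rng, n: int):
    """Per-iteration induction/maintenance matrices for one strategy."""
    tr = strategy.transitions
    out = []
    for means, sds in (
        (tr.induction_means, tr.induction_sds),
        (tr.maintenance_means, tr.maintenance_sds),
    ):
        mats = np.empty((n, len(STATES), len(STATES)))
        for i in range(len(STATES)):
            row = means[i] / means[i].sum()
            mats[:, i, :] = sample_transition_row(means[i], float(sds[i]), rng, size=n) \
                if sds[i] > 0 else np.broadcast_to(row, (n, len(STATES)))
        out.append(mats)
    return out[0], out[1]


def _sample_intervention(strategy, rng, n: int) -> np.ndarray:
    total = np.zeros(n)
    for c in strategy.intervention.components:
        if c.dist == "gamma" and c.sd:
            total += sample_gamma(c.mean, c.sd, rng, n)
        else:
            total += c.mean
    return total


# ---------------------------------------------------------------------------
# Result containers


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration costs and QALYs for every strategy.

    ``costs`` and ``qalys`` are (n_iterations, n_strategies) arrays in
    the order of ``strategies``.
    """

    strategies: tuple[str, ...]
    costs: np.ndarray
    qalys: np.ndarray
    n_iterations: int
    seed: int | None
    perspective: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        costs = np.asarray(self.costs, dtype=float)
        qalys = np.asarray(self.qalys, dtype=float)
        shape = (self.n_iterations, len(self.strategies))
        if costs.shape != shape or qalys.shape != shape:
            raise ValueError("costs/qalys must be (n_iterations, n_strategies)")
        object.__setattr__(self, "costs", costs)
        object.__setattr__(self, "qalys", qalys)

    def _idx(self, strategy: str) -> int:
        try:
            return self.strategies.index(strategy)
        except ValueError:
            raise KeyError(f"unknown strategy {strategy!r}; have {self.strategies}") from None

    def cost_draws(self, strategy: str) -> np.ndarray:
        return self.costs[:, self._idx(strategy)]

    def qaly_draws(self, strategy: str) -> np.ndarray:
        return self.qalys[:, self._idx(strategy)]

    def mean_cost(self, strategy: str) -> float:
        return float(self.cost_draws(strategy).mean())

    def mean_qaly(self, strategy: str) -> float:
        return float(self.qaly_draws(strategy).mean())

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws table (iteration, strategy, cost, qaly)."""
        frames = []
        for j, s in enumerate(self.strategies):
            frames.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_iterations),
                        "strategy": s,
                        "cost": self.costs[:, j],
                        "qaly": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(
        self, reference: str = "standard_care", ci_method: str = "mean"
    ) -> pd.DataFrame:
        """Base-case-style results table with incremental analysis.

        One row per strategy: mean cost and QALYs with 95% confidence
        intervals, incremental cost/QALYs versus ``reference``, and the
        ICER or a dominance label.  ``ci_method='mean'`` (default) gives
        a normal-approximation CI of the mean (the width scale of the
        published tables); ``'percentile'`` gives the 2.5/97.5
        percentiles of the draws.
        """
        if ci_method not in ("mean", "percentile"):
            raise ValueError("ci_method must be 'mean' or 'percentile'")

        def ci(x):
            if ci_method == "percentile":
                return np.percentile(x, 2.5), np.percentile(x, 97.5)
            se = x.std(ddof=1) / np.sqrt(len(x))
            return x.mean() - 1.959963984540054 * se, x.mean() + 1.959963984540054 * se

        rows = []
        inc = incremental_analysis(self, reference=reference)
        for s in self.strategies:
            c, q = self.cost_draws(s), self.qaly_draws(s)
            clo, chi = ci(c)
            qlo, qhi = ci(q)
            r = inc.loc[s]
            rows.append(
                {
                    "strategy": STRATEGY_LABELS.get(s, s),
                    "mean_cost": c.mean(),
                    "cost_ci_low": clo,
                    "cost_ci_high": chi,
                    "incremental_cost": r["incremental_cost"],
                    "mean_qaly": q.mean(),
                    "qaly_ci_low": qlo,
                    "qaly_ci_high": qhi,
                    "incremental_qaly": r["incremental_qaly"],
                    "icer": r["icer"],
                    "label": r["label"],
                }
            )
        return pd.DataFrame(rows, index=list(self.strategies))

    def ceac(self, wtp_grid=None, comparator: str = "standard_care") -> "CEACCurve":
        return ceac(self, wtp_grid, comparator)

    def ce_plane(self, strategy: str, reference: str = "standard_care") -> "CEPlane":
        return ce_plane(self, strategy, reference)


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy is cost-effective versus the comparator."""

    wtp: np.ndarray
    probabilities: dict[str, np.ndarray]
    comparator: str

    def to_frame(self) -> pd.DataFrame:
        d = {"wtp": self.wtp}
        d.update(self.probabilities)
        return pd.DataFrame(d)


@dataclass(frozen=True)
class ConfidenceEllipse:
    """95% confidence ellipse of (incremental QALY, incremental cost)."""

    center: tuple[float, float]
    width: float   # full axis length along `angle_deg`
    height: float
    angle_deg: float

    def to_dict(self) -> dict:
        return {
            "center_dqaly": self.center[0],
            "center_dcost": self.center[1],
            "width": self.width,
            "height": self.height,
            "angle_deg": self.angle_deg,
        }


@dataclass(frozen=True)
class CEPlane:
    """Incremental cost-effectiveness scatter with its 95% ellipse."""

    strategy: str
    reference: str
    d_qaly: np.ndarray
    d_cost: np.ndarray
    ellipse: ConfidenceEllipse | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.d_qaly)),
                "incremental_qaly": self.d_qaly,
                "incremental_cost": self.d_cost,
            }
        )


# ---------------------------------------------------------------------------
# Drivers


def _evaluate_strategies(
    params: ParameterSet,
    spec: ModelSpec,
    n: int,
    rng: np.random.Generator | None,
    perspective: str,
    utility_set: str,
    horizon_years: float,
    discount_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared evaluation path for deterministic (n=1, rng=None) and PSA runs."""
    extend = horizon_years > BASE_HORIZON_YEARS

    if rng is None:  # deterministic: point-mass draws at the means
        frozen = params.without_uncertainty()
        rng = np.random.default_rng(0)  # never consumed: every sd is zero
        params = frozen

    utilities, healthcare, productivity, long_term = _sample_shared(
        params, utility_set, rng, n, need_long_term=extend
    )
    state_costs = costing.apply_perspective(healthcare, productivity, perspective)

    if extend:
        lt_hc, lt_prod = long_term
        lt_cycle = costing.apply_perspective(lt_hc, lt_prod, perspective) / 26.0

    costs = np.empty((n, len(STRATEGY_ORDER)))
    qalys = np.empty((n, len(STRATEGY_ORDER)))
    for j, name in enumerate(STRATEGY_ORDER):
        strat = params.strategies[name]
        induction, maintenance = _sample_transition_matrices(strat, rng, n)
        intervention = _sample_intervention(strat, rng, n)
        paths = _cohort_paths(induction, maintenance, spec)
        c, q = _accrue(paths, utilities, state_costs, intervention, spec, discount_rate)
        if extend:
            ec, eq = _extend(
                paths[:, -1, :], utilities, lt_cycle, horizon_years, discount_rate,
                spec.cycle_length,
            )
            c, q = c + ec, q + eq
        costs[:, j], qalys[:, j] = c, q
    return costs, qalys


def run_psa(
    params: ParameterSet,
    spec: ModelSpec | None = None,
    n_iterations: int = 1000,
    seed: int = 2020,
    perspective: str = SOCIETAL,
    utility_set: str = "base",
    horizon_years: float = BASE_HORIZON_YEARS,
    discount_rate: float = 0.0,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Repeats the cohort model ``n_iterations`` times (1,000 by default).
    Within an iteration the shared parameters — utilities and per-state
    utilization/productivity costs — use one draw across all strategies;
    transition rows and intervention cost components are drawn per
    strategy.  Identical seeds give bitwise-identical results.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    spec = spec or ModelSpec()
    rng = np.random.default_rng(seed)
    costs, qalys = _evaluate_strategies(
        params, spec, n_iterations, rng, perspective, utility_set, horizon_years, discount_rate
    )
    return PSAResult(
        strategies=STRATEGY_ORDER,
        costs=costs,
        qalys=qalys,
        n_iterations=n_iterations,
        seed=seed,
        perspective=perspective,
        metadata={
            "utility_set": utility_set,
            "horizon_years": horizon_years,
            "discount_rate": discount_rate,
            "counting": spec.counting,
        },
    )


def evaluate_deterministic(
    params: ParameterSet,
    spec: ModelSpec | None = None,
    perspective: str = SOCIETAL,
    utility_set: str = "base",
    horizon_years: float = BASE_HORIZON_YEARS,
    discount_rate: float = 0.0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Base-case expected costs and QALYs per strategy (no sampling)."""
    spec = spec or ModelSpec()
    costs, qalys = _evaluate_strategies(
        params, spec, 1, None, perspective, utility_set, horizon_years, discount_rate
    )
    return (
        {s: float(costs[0, j]) for j, s in enumerate(STRATEGY_ORDER)},
        {s: float(qalys[0, j]) for j, s in enumerate(STRATEGY_ORDER)},
    )


# ---------------------------------------------------------------------------
# Incremental analysis, CEAC, CE plane


def classify_increment(d_cost: float, d_qaly: float) -> tuple[float, str]:
    """ICER (or NaN) and a label for one incremental comparison.

    The ICER Δcost/ΔQALY is reported when ΔQALY > 0 and Δcost >= 0, or
    when both are negative; a strategy with lower cost and higher QALYs
    "dominates"; the reverse is "dominated"; ΔQALY = 0 leaves the ICER
    undefined.
    """
    if d_qaly > 0 and d_cost < 0:
        return math.nan, DOMINATES
    if d_qaly < 0 and d_cost > 0:
        return math.nan, DOMINATED
    if d_qaly == 0:
        return math.nan, "undefined (ΔQALY = 0)"
    return d_cost / d_qaly, "icer"


def incremental_analysis(
    results: "PSAResult | tuple[dict[str, float], dict[str, float]]",
    reference: str = "standard_care",
) -> pd.DataFrame:
    """Incremental cost, incremental QALY and ICER/dominance vs a reference.

    Accepts a :class:`PSAResult` (uses the means of the draws) or a
    ``(costs, qalys)`` pair of per-strategy dicts from the deterministic
    run.
    """
    if isinstance(results, PSAResult):
        costs = {s: results.mean_cost(s) for s in results.strategies}
        qalys = {s: results.mean_qaly(s) for s in results.strategies}
    else:
        costs, qalys = results
    if reference not in costs:
        raise KeyError(f"reference strategy {reference!r} not present")
    rows = []
    for s in costs:
        if s == reference:
            rows.append(
                {"strategy": s, "incremental_cost": 0.0, "incremental_qaly": 0.0,
                 "icer": math.nan, "label": "reference"}
            )
            continue
        d_cost = costs[s] - costs[reference]
        d_qaly = qalys[s] - qalys[reference]
        icer, label = classify_increment(d_cost, d_qaly)
        rows.append(
            {"strategy": s, "incremental_cost": d_cost, "incremental_qaly": d_qaly,
             "icer": icer, "label": label}
        )
    return pd.DataFrame(rows).set_index("strategy")


def ceac(
    results: PSAResult, wtp_grid=None, comparator: str = "standard_care"
) -> CEACCurve:
    """Cost-effectiveness acceptability curves, pairwise vs a comparator.

    At each willingness-to-pay λ the probability that a strategy is
    cost-effective is the fraction of iterations in which its net
    monetary benefit λ·QALY − cost **strictly exceeds** the
    comparator's.  At λ = 0 this is the probability of being
    cost-saving; as λ grows it approaches P(ΔQALY > 0).
    """
    wtp = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ValueError("the willingness-to-pay grid must not be empty")
    jc = results._idx(comparator)
    nmb_c = wtp[:, None] * results.qalys[None, :, jc] - results.costs[None, :, jc]
    probs = {}
    for j, s in enumerate(results.strategies):
        nmb_s = wtp[:, None] * results.qalys[None, :, j] - results.costs[None, :, j]
        probs[s] = (nmb_s > nmb_c).mean(axis=1)
    return CEACCurve(wtp=wtp, probabilities=probs, comparator=comparator)


def ce_plane(
    results: PSAResult, strategy: str, reference: str = "standard_care"
) -> CEPlane:
    """Incremental (ΔQALY, Δcost) scatter with a 95% confidence ellipse.

    The ellipse is drawn from the sample mean and covariance of the
    per-iteration increments at the χ²(2 df, 0.95) contour.  A singular
    covariance (e.g. identical points) emits a warning and omits the
    ellipse.
    """
    if results.n_iterations < 3:
        raise ValueError("need at least 3 iterations for a CE plane")
    d_qaly = results.qaly_draws(strategy) - results.qaly_draws(reference)
    d_cost = results.cost_draws(strategy) - results.cost_draws(reference)
    cov = np.cov(np.vstack([d_qaly, d_cost]))
    ellipse = None
    if np.linalg.matrix_rank(cov) < 2 or not np.all(np.isfinite(cov)):
        warnings.warn(
            "singular covariance of (ΔQALY, Δcost); confidence ellipse omitted",
            stacklevel=2,
        )
    else:
        chi2_95 = stats.chi2.ppf(0.95, df=2)
        eigvals, eigvecs = np.linalg.eigh(cov)
        # eigh returns ascending eigenvalues; major axis last
        width, height = 2.0 * np.sqrt(eigvals[::-1] * chi2_95)
        major = eigvecs[:, -1]
        angle = math.degrees(math.atan2(major[1], major[0]))
        ellipse = ConfidenceEllipse(
            center=(float(d_qaly.mean()), float(d_cost.mean())),
            width=float(width),
            height=float(height),
            angle_deg=float(angle),
        )
    return CEPlane(
        strategy=strategy, reference=reference, d_qaly=d_qaly, d_cost=d_cost, ellipse=ellipse
    )
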