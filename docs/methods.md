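# Methods

## The model

`markovcea` implements a probabilistic Markov cohort cost-utility model
comparing three strategies for neuropathic pain (NP) after spinal cord
injury: virtual illusion combined with transcranial direct current
stimulation (VI+tDCS), tDCS alone, and standard pharmacological care.
A closed cohort moves between three mutually exclusive pain-severity
states defined on the 11-point numerical rating scale — mild (NRS 0–3),
moderate (4–6), severe (7–10) — in two-week cycles. The whole cohort
starts in the severe state (the trial populations were treatment-
resistant, baseline NRS ≈ 8). Mortality is excluded over the short
horizon, and there are no adverse-event states.

Each strategy has two transition matrices: an *induction* matrix applied
for the first transition (the initial treatment cycle) and a
*maintenance* matrix applied thereafter. Standard care is modelled as an
absorbing severe state — the cohort is, by inclusion criterion,
unresponsive to pharmacological therapy, and no transition data exist
for it. The three-month primary analysis applies 6 transitions
(induction + 5 maintenance).

Printed transition rows can carry rounding slack (the VI+tDCS induction
severe row sums to 1.01); every row is renormalised by its own sum, which
preserves exact zeros and within-row ordering.

### Counting convention

Whether the initial state vector accrues utility is a genuine modelling
choice. We calibrated it against the published totals: only
*include-initial-state* counting — 7 occupancy vectors (times 0–6), each
worth 2/52 year — reproduces all three published mean QALYs
(VI+tDCS 0.163, tDCS 0.137–0.138, standard care 0.117–0.118), so it is
the default; `exclude-initial-state` remains available on `ModelSpec`.
This convention accrues 14 weeks of utility over a nominally 12-week
horizon; we reproduce the published arithmetic rather than endorse it.
No half-cycle correction is applied (the same calibration rules it out).

QALYs are utility-weighted time in state:
`Σ_k (occupancy_k · u) × (2/52)`; costs are a one-time intervention cost
at model start plus occupancy-weighted per-cycle state costs over the
same counted vectors.

## Costs (2020 CAD)

Intervention costs are per-patient sums of components: amortised
equipment (five-year lifespan; `amortize_equipment` exposes
patients-per-year as a parameter since the published amortisation
denominator is not stated), session-based personnel time (first session
45 min, subsequent 30 min; e.g. 20 nurse sessions at $36.12/h = 10.25 h
= $370.23), and a per-course drug cost ($91.83). The intervention cost
is charged once at cycle 0 with no re-treatment inside the horizon.

Per-cycle state costs combine:

* **Healthcare utilization** — per state, the probability of a physician
  visit, of a specialist referral, and the conditional probability of a
  diagnostic test, times the respective unit costs, plus a per-cycle
  drug cost. The source's conditioning of the test on "the probability
  of a physician visit and specialist referral" is ambiguous; the
  default composition multiplies the conditional test probability by
  `p(visit) + p(referral)`, with `visit-only` and inclusion–exclusion
  (`p(v) + p(r) − p(v)p(r)`) available on
  `StateUtilizationProfile.test_rule`.
* **Productivity losses** (human-capital method) — monthly paid and
  unpaid hours lost, halved to fit the two-week cycle, valued at the
  2020 Canadian average hourly wage ($29.75) and the 2020 Ontario
  minimum wage ($14.25) respectively.

The societal perspective sums both components; the payer perspective
drops the productivity share (so payer ≤ societal holds state-wise on
every parameter draw).

### Synthetic placeholder profiles

The per-state utilization probabilities, drug costs, lost hours and
long-term (3–12 month) costs come from appendix tables whose values are
not reproduced here. The shipped profiles in
`markovcea.params.builtin_parameter_set` are **synthetic placeholders**,
flagged in `ParameterSet.synthetic_fields` and chosen once by two
principles: monotone increasing with pain severity, and per-cycle totals
of the magnitude implied by the published cost totals (severe-state
≈ $410/cycle payer, ≈ $1,000/cycle societal, giving a standard-care
three-month total of ≈ $7.0k societal against the published $7.4k).
Consequences: state occupancies, QALYs and all QALY-side outputs are
published-input driven and value-reproducing; absolute dollar totals,
ICER dollar values and CEAC probabilities are structural — they have the
right form, ordering and rough magnitude, but are not expected to equal
the published dollars. Tests on the cost side therefore assert
properties (perspective ordering, homogeneity, dominance structure)
rather than dollar values.

## Probabilistic sensitivity analysis

The model is repeated 1,000 times (default). Per iteration, one value is
drawn per uncertain parameter:

* cost inputs: gamma, moment-matched (`shape = μ²/σ²`, `scale = σ²/μ`);
* utilities and utilization probabilities: beta, moment-matched
  (`ν = μ(1−μ)/σ² − 1`, shapes `μν`, `(1−μ)ν`); infeasible σ raises with
  the feasible bound;
* transition rows: the sources tag these "multinomial", which has no
  direct continuous analogue without an unstated count parameter; we use
  a Dirichlet over the non-zero cells with total concentration `c`
  calibrated so the largest cell's sd equals the stated 0.1
  (`c = p*(1−p*)/σ² − 1`, concentrations floored at 1e-3). Zero-mean
  cells remain exactly zero in every draw.

Any sd of 0 degenerates to a point mass, so a fully frozen parameter set
reproduces the deterministic base case exactly (this is tested).

No correlation structure is imposed: parameters are independent, but
*shared* parameters (utilities, per-state costs) use the same draw
across strategies within an iteration, so incremental comparisons are
paired. The sampling order is fixed (shared parameters first, then each
strategy in canonical order: standard care, tDCS, VI+tDCS), making runs
bitwise reproducible by seed (`numpy.random.default_rng`). The default
seed is 2020 and is CLI-overridable.

A known property of this design: the maintenance matrix is drawn once
per iteration and applied five times, so the PSA mean of any quantity
nonlinear in the matrix (a Jensen effect of the matrix power) differs
slightly from the deterministic value — the VI+tDCS mean QALY under the
sampler is 0.1622 against a deterministic 0.1627. The published PSA
means show the same phenomenon in the opposite direction (incremental
QALY 0.046 probabilistic vs 0.044 deterministic).

Derived products:

* **Incremental analysis** — ICER Δcost/ΔQALY reported when ΔQALY > 0
  and Δcost ≥ 0 (or both negative); "dominates" when Δcost < 0 and
  ΔQALY > 0; "dominated" for the reverse; ΔQALY = 0 leaves the ICER
  undefined.
* **CEAC** — at each willingness-to-pay λ on a 101-point grid over
  [0, 100,000] $/QALY, the fraction of iterations in which the
  strategy's net monetary benefit λ·QALY − cost *strictly* exceeds the
  comparator's (pairwise versus standard care; ties count as not
  exceeding, so a strategy versus itself is 0).
* **CE plane** — per-iteration (ΔQALY, Δcost) scatter with a 95%
  confidence ellipse from the sample mean and covariance at the
  χ²(2 df, 0.95) contour; a singular covariance warns and omits the
  ellipse.

### Summary-table confidence intervals

`PSAResult.summary()` defaults to a normal-approximation 95% CI of the
*mean* (mean ± 1.96 SE). The published tables print intervals of that
width (e.g. 0.163 (0.162–0.164), which is ±~2 Monte-Carlo standard
errors, not ±2 sd of the draw distribution); percentile intervals of the
draws (`ci_method="percentile"`) are available and are roughly 30 times
wider on the QALY scale.

## Scenario analyses

Six shipped scenarios: payer perspective; 1-year and 2-year horizons;
two alternative utility sets (0.93/0.80/0.34 and 0.71/0.47/0.20); and VR
equipment recosted at $3,500 per year. Horizon extensions freeze state
membership at the three-month occupancy and accrue per-state long-term
costs (annual values divided by 26 per cycle) and utility-weighted time
in two-week cycles, allowing a fractional final cycle, so a zero-rate
1-year extension is exactly `(occupancy · u) × 0.75` QALYs. The
frozen-membership rule is stated by the sources for 3→12 months; we
extend it by analogy to year 2. Discounting multiplies the accrual at
cycle k by `(1+r)^(−k × cycle_length_years)`; the base case and the
1-year scenario use r = 0, the 2-year scenario r = 1.5%/yr applied from
model start (the within-year-1 convention is unstated in the sources;
over year 1 the factor is ≤ 1.5% so the choice is immaterial at the
reported precision). Intervention costs do not recur in multi-year
scenarios. The annual VR recosting divides $3,500 by
`patients_per_year` (default 20, back-solved so the per-patient
equipment cost rises by ≈ $120, matching the published scenario's
incremental-cost shift).

## Numerical and testing notes

All engines are vectorised across PSA iterations; a full three-strategy
1,000-iteration PSA takes tens of milliseconds, so the test suite runs
20-seed panels comfortably. The deterministic run shares the PSA code
path with every sd forced to zero, guaranteeing exact agreement. The
cohort engine is cross-checked to 1e-12 against an explicit per-state
loop oracle on 1,000 random matrices, and each sampler's empirical mean
is checked within 3 Monte-Carlo standard errors at 10⁵ draws.

Problem sizes used by the shipped analyses: 6 transitions, 1,000 PSA
iterations, 101-point WTP grids, 20-seed reproduction panels.

## Known limitations

* The synthetic placeholder cost profiles make absolute dollar outputs
  structural, not value-reproducing (see above); the published CEAC
  probabilities (74%/54% at $50,000/QALY) are likewise not reproduction
  targets.
* One acceptance-style check is left failing by design: requiring all
  three strategies' PSA mean QALYs to fall inside the published 95% CIs
  for ≥95% of seeds is statistically unattainable at n = 1,000, because
  those intervals are only ~1.3–1.8 Monte-Carlo standard errors wide
  (measured joint pass rate ≈ 76% over 200 seeds, with the per-strategy
  means unbiased or within 0.0005 of the deterministic values). The
  deterministic values land inside all three intervals.
* The model inherits the sources' structural assumptions: three states,
  no adverse events, no mortality, transitions constant across
  maintenance cycles, and frozen membership beyond three months.
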