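# markovcea

A Markov cohort cost-utility model comparing **virtual illusion plus
transcranial direct current stimulation (VI+tDCS)**, **tDCS alone**, and
**standard pharmacological care** for neuropathic pain (NP) after spinal
cord injury, from Canadian societal and public-payer perspectives
(2020 CAD).

Most people living with spinal cord injury experience neuropathic pain,
and a large fraction do not respond to first-line drugs. Non-invasive
adjuncts — tDCS, and tDCS combined with a virtual walking illusion —
reduce pain intensity in trials, but at additional equipment and
personnel cost. This package lets health-economics analysts reproduce
and extend the cost-utility comparison of those options.

## The model

A closed cohort occupies three mutually exclusive pain-severity states
defined on the numerical rating scale — mild (NRS 0–3), moderate (4–6),
severe (7–10) — and transitions every two-week cycle under a
strategy-specific pair of matrices `P_induction` (first cycle) and
`P_maintenance` (later cycles), starting entirely severe. Over the
three-month horizon (6 transitions) the model accumulates

* QALYs: `Σ_k (x_k · u) × 2/52`, where `x_k` is the state-occupancy
  vector after `k` transitions and `u` the state utilities
  (0.77 / 0.63 / 0.44), and
* costs: a one-time per-patient intervention cost plus
  occupancy-weighted per-cycle state costs (healthcare utilization +
  human-capital productivity losses),

and reports incremental cost-effectiveness ratios
`ICER = ΔC/ΔE` versus standard care, with dominance labelling.
Parameter uncertainty is propagated by a 1,000-iteration Monte Carlo
probabilistic sensitivity analysis (gamma costs, beta utilities and
probabilities, calibrated Dirichlet transition rows), from which
cost-effectiveness planes with 95% confidence ellipses and
cost-effectiveness acceptability curves (probability of the highest net
monetary benefit `λ·E − C` at willingness-to-pay `λ`) are derived.

Per-state utilization, productivity and long-term cost profiles are
**synthetic placeholders** (their published sources are appendix tables
not reproduced here): dollar-side outputs are structural, while the
occupancy and QALY sides reproduce published values. See
`docs/methods.md` for details and all modelling choices.

## Worked example

```python
from markovcea import CostUtilityModel

model = CostUtilityModel.from_defaults()   # published base-case inputs
base = model.run()                         # deterministic expected values
print(base.summary())

psa = model.fit(n_iterations=1000, seed=2020)  # probabilistic analysis
print(psa.summary())
```

The deterministic run prints:

```
     strategy        cost  incremental_cost     qaly  incremental_qaly         icer     label
Standard care 6987.750000          0.000000 0.118462          0.000000          NaN reference
         tDCS 7673.667303        685.917303 0.137917          0.019456 35255.005923      icer
    VI + tDCS 7250.290102        262.540102 0.162689          0.044227  5936.162491      icer
```

Reading it: after three months the VI+tDCS cohort sits at 28% mild /
57% moderate / 15% severe (`base.occupancy("vi_tdcs")`), against
0% / 36% / 64% for tDCS alone, which is why VI+tDCS gains 0.044 QALYs
over standard care versus 0.019 for tDCS — matching the published QALY
splits. VI+tDCS also *dominates* tDCS alone (lower cost, higher QALYs).
The dollar columns use the package's synthetic placeholder state-cost
profiles, so their magnitudes and ordering are meaningful but they are
not the published totals.

The PSA summary adds 95% confidence intervals of the means and
Monte-Carlo incremental estimates, e.g. mean VI+tDCS QALYs 0.1621
(0.1609–0.1632); `psa.ceac()` and `psa.ce_plane("vi_tdcs")` produce the
acceptability curves and the incremental scatter with its 95% ellipse,
and `markovcea.plotting` renders them.

Scenario analyses (payer perspective, 1- and 2-year horizons with
frozen state membership, two alternative utility sets, annual VR
recosting):

```python
from markovcea import run_scenario, builtin_parameter_set
table = run_scenario("payer", builtin_parameter_set(), seed=2020)
```

Everything is also exposed on a CLI:

```sh
markovcea run-base-case
markovcea run-psa --seed 2020 --iterations 1000 --out results/
markovcea run-scenarios --name payer
markovcea ceac --perspective payer
markovcea make-fixtures --out parameters.json   # editable JSON inputs
```

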