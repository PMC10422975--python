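# oqct-cea

A Markov cohort (state-transition) model of osteoporosis screening for
vertebral-fracture (VF) prevention, comparing three strategies for
hypothetical cohorts of 1,000 women and men aged 65 over a 5-year horizon
from the U.S. health-care perspective (2022 USD):

* **no screening** — no testing, no treatment;
* **DXA screening** — annual dual-energy X-ray absorptiometry at reported
  real-world uptake rates (9.5%/yr women, 1.7%/yr men);
* **oQCT screening** — one-shot opportunistic quantitative CT: bone mineral
  density read from routine CT scans, screening everyone once at baseline.

It is written for health economists and methods-minded clinicians who want a
fully scriptable, testable alternative to spreadsheet/TreeAge implementations
of this class of model: every mechanization convention is an explicit switch,
and an individual-level microsimulation oracle validates the cohort engine.

## Model

The cohort moves in annual cycles through four health states — alive without
VF, alive without VF on treatment, alive with VF, dead (absorbing) — with
tunnel sub-states for years on treatment and years since fracture, so that
time-dependent re-fracture risk (RR 5.0 in year 1, 2.5 in years 2–5),
post-fracture excess mortality, decaying fracture costs and disutilities
remain Markovian. Screening is a Bayes split on the annual incidence: a test
with sensitivity *se* and specificity *sp* sends a fraction
`se·p + (1−sp)(1−p)` of the screened to treatment carrying the elevated
conditional risk `P(VF | +)`, while negatives continue at the reduced
`P(VF | −)`; the mass-weighted risks recover the prior (law of total
probability). Bisphosphonate treatment multiplies fracture risk by the
intention-to-treat relative risk `RR_eff = a·RR + (1−a)` with adherence
`a = 0.5`.

Outcomes are cumulative discounted costs and QALYs (3%/yr), VF counts,
pairwise incremental cost-effectiveness ratios `ICER = ΔC/ΔE` with explicit
dominance handling, and classification against willingness-to-pay thresholds
of $70,249 and $210,746 per QALY. Sensitivity machinery: one-way tornado
analysis over the published ranges, bisection for the oQCT unit-cost
thresholds (cost-effectiveness and breakeven), and probabilistic sensitivity
analysis sampling beta/gamma distributions (method of moments) with
net-monetary-benefit acceptability curves.

See `docs/methods.md` for the full model description, the calibrated
convention switches, and known limitations.

## Worked example

```sh
oqct-cea run --sex female --out results/
```

prints the three strategy rows for 1,000 women over 5 years:

```
no_screening: cost $3,342,255, QALYs 4,533.7, VFs 89.8
dxa: cost $3,263,057, QALYs 4,534.7, VFs 85.6
oqct: cost $3,167,626, QALYs 4,537.2, VFs 82.5
```

oQCT screening is cheapest (it averts the most fractures, whose costs
dominate), gains the most QALYs, and prevents ~3.1 more VFs than DXA
screening per 1,000 women — it *dominates* both comparators, so no ICER is
reported for women (the pairwise table marks it cost-saving). The same run
writes `strategies_female.csv`, the pairwise CEA table, per-cycle traces and
a reproducibility manifest. Other commands:

```sh
oqct-cea threshold --sex female --objective equal_total_cost --out results/
# equal_total_cost vs dxa (female): oQCT unit cost $178.04 (tol $0.5)
#   -> oQCT stays outright cost-saving up to ~$178 per scan (base case $82.61)

oqct-cea psa --sex male -n 5000 --seed 7 --out results/
# oQCT cost-effective vs DXA at $70,249/QALY in 90.4% of 5,000 iterations
```

The same API is available from Python:

```python
from oqct_cea import default_parameters, make_policy, run_cohort

params = default_parameters("male")
result = run_cohort(params, make_policy("oqct", params))
print(result.cumulative_discounted_cost, result.total_vf_events)
```

## Layout

| Module | Contents |
| --- | --- |
| `oqct_cea.parameters` | Typed parameter set, validation, YAML/JSON config I/O, PSA distribution annotations |
| `oqct_cea.markov_cohort` | State space, transition probabilities, cohort propagation, discounting |
| `oqct_cea.strategies` | Screening policies, Bayes test-result split |
| `oqct_cea.cea` | ICERs, dominance, WTP classification, pairwise comparisons |
| `oqct_cea.sensitivity` | Tornado, cost-threshold bisection, PSA + CEAC |
| `oqct_cea.microsim_oracle` | Individual-level Monte Carlo oracle, trajectory enumeration, synthetic fixtures |
| `oqct_cea.cli_reporting` | `oqct-cea run/psa/tornado/threshold`, manifests |
| `oqct_cea.plots` | Optional CE-plane / CEAC / tornado figures |
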