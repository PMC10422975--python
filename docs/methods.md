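# Methods

## Decision problem

Osteoporosis is underdiagnosed; bone mineral density (BMD) can be read
opportunistically from routine CT scans ("oQCT") at low marginal cost,
identifying patients at risk of vertebral fractures (VFs) who would start
bisphosphonate therapy. The model asks whether oQCT screening of
65-year-olds is cost-effective relative to standard-of-care DXA screening
and to no screening, over a 5-year horizon from the U.S. health-care
perspective in 2022 USD, with outcomes discounted at 3%/year.

## Cohort engine

A discrete-time Markov cohort model with annual cycles propagates expected
occupancy over an expanded state space:

* `NO_VF_UNTREATED` — alive, no fracture, not on therapy;
* `NO_VF_TREATED(y)` — treatment tunnel, `y = 1..duration` (2 years);
* `POST_VF(j, treated)` — post-fracture tunnel, `j = 0..horizon−1` years
  since the (most recent) fracture, split by active treatment;
* `DEAD` — absorbing.

Events within a cycle are ordered screening → fracture/death transition →
reward accrual. Fracture and death compete as *marginal branch
probabilities*: both apply at their printed annual values, the remainder
stays put, and the fracture branch is capped at the surviving mass
(`P(frac) = min(p_frac, 1 − p_death)`) so the distribution remains well
formed for degenerate inputs (e.g. a perfect test whose positives fracture
with probability 1). A raw fracture probability above 1 signals
inconsistent inputs and raises an error rather than being silently clipped.

A re-fracture resets the years-since-fracture clock and counts as a new VF
event (event counts are totals, not persons). Post-VF transition inputs are
indexed by years since the event: re-fracture relative risk 5.0 in the
first year and 2.5 afterwards multiplies the background incidence; the
post-VF death probability decays from 0.103 (women, year 1) to 0.043 by
year 5.

The internal propagation keys refine the public state space by the
screening risk class (a multiplier on background incidence) and by the
exact remaining treatment course; the public 14-state space (horizon 5,
2-year course) is the aggregation used in traces and invariants.

## Screening mechanics

Test accuracy is wired as a Bayes split on the annual first-fracture
incidence. For prior risk `p`, a test (sensitivity `se`, specificity `sp`)
splits the screened mass into a positive fraction
`f+ = se·p + (1−sp)(1−p)` carrying `P(VF|+) = se·p/f+` and a negative
fraction carrying `P(VF|−) = (1−se)p/(1−f+)`; the mixture recovers `p`
exactly, so screening never manufactures or destroys cohort-level risk.
Positives start treatment; negatives stay untreated. Conditional risks
persist over the horizon by default (`risk_persistence="horizon"`);
the alternative (`"cycle"`) reverts everyone to background incidence after
the screening cycle and is exposed as a switch because neither convention
is observable from published outputs alone — persistence is required to
produce screening effects of the published size.

Test-negatives re-enter the eligible pool in later cycles
(`rescreen_negatives=True`); a re-screened negative is updated by a second
likelihood-ratio factor applied to its current posterior, which keeps the
split risk-conserving under repeated testing. Positives are never
re-screened.

The three policies differ in schedule and care pathway:

* **oQCT**: everyone screened once at baseline; positives receive a single
  2-year treatment course (effect and cost end with the course).
* **DXA**: annual screening at the reported uptake rate; a DXA-initiated
  course is renewed at the annual monitoring visits and persists over the
  horizon. In addition, a patient suffering an incident VF in this
  standard-of-care arm receives a diagnostic work-up and starts sustained
  treatment with probability equal to the test's sensitivity — which is
  exactly `P(test+ | incident VF)`, the quantity the published accuracy
  studies report. Both pathway attributes are policy-level flags.
* **no screening**: no testing and no treatment.

With a completely uninformative free test (`se = 0`, `sp = 1`, zero cost)
every pathway collapses and both screening arms reproduce the no-screening
arm exactly; this is enforced by the test suite.

Treatment: adherence enters as an intention-to-treat effective relative
risk `RR_eff = a·RR + (1−a)` (a = 0.5; RR 0.55 women / 0.44 men), applied
to first-fracture and re-fracture risk while treatment is active; the $100
annual drug cost is paid by the adherent fraction only.

## Accounting conventions (calibrated switches)

Several conventions are not identifiable from the published inputs and are
exposed as `ModelOptions` switches. The defaults were fixed by a one-time
calibration of the strategy-level cost and QALY totals and are recorded in
every run manifest:

| Switch | Default | Alternatives |
| --- | --- | --- |
| `cycle_accounting` | `stage` (rewards at stages 0..H, discounted (1+r)^−t — the six accrual points of common decision-tree software) | `end`, `half_cycle` |
| `vf_cost_accrual` | `event_lump` (the undiscounted 5-year post-fracture cost schedule, $39,482, charged once at the fracture transition) | `annual` (year-k cost in year k, truncated at horizon) |
| `postvf_mortality` | `additive` (excess added to background) | `substitute` |
| `perifracture_mortality` | off (year-0 probability unused) | on |
| `risk_persistence` | `horizon` | `cycle` |
| `rescreen_negatives` | on | off |

The `stage` accounting is the only convention consistent with published
QALY totals that exceed `horizon × utility × cohort` (4,511 > 4,200 per
1,000 women), which pins six accrual points. The lump-sum fracture cost is
the only convention that reaches the published cost level (a
horizon-truncated annual accrual falls ~25% short). Under these defaults
all twelve strategy-level cost/QALY cells reproduce within ±2%. Residual
gaps remain in some incremental quantities (the women's fractures averted
vs DXA computes 3.1 vs the published 2.6; the men's oQCT-vs-DXA ICER
computes ≈$19k vs the published $11,996) and are inherent to the
unpublished wiring of the original implementation; they were deliberately
not tuned away where doing so would break structural invariants.

QALYs: base utility 0.84 (women) / 0.87 (men) in all alive non-fracture
states ("unimpaired quality of life" on treatment); post-VF utility is
multiplied by 0.860 in the first year after the event and 0.965 afterwards;
the dead state accrues nothing.

## Comparative outcomes

Pairwise incremental costs and effects are computed from full-precision
totals; rounding is left to the reporting layer. ICERs carry explicit
dominance markers: cheaper-and-more-effective is *cost-saving* (no ratio),
dearer-and-less-effective is *dominated*, a zero QALY difference is
*undefined*; the south-west quadrant (cheaper, less effective) keeps the
numeric ratio. Classification uses the 1× / 3× GDP-per-capita thresholds
($70,249 / $210,746 per QALY). Every comparison is labeled with its
comparator; no mixed-comparator tables are emitted.

## Sensitivity analyses

*One-way (tornado)*: each annotated parameter moves to the ends of its
range with everything else at base case. Ranges are the printed ones where
available; otherwise a ±20% band clipped to the valid support (flagged as
derived, tornado-only). Entries are sorted by the ICER spread between the
two runs.

*Cost thresholds*: Brent bisection (tolerance $0.5) on the oQCT unit cost
for (a) the cost at which the oQCT-vs-DXA ICER equals the WTP threshold —
implemented as the net-monetary-benefit root, which remains well behaved
across dominance quadrants — and (b) the breakeven cost equalising total
discounted costs.

*PSA*: every parameter with a distribution annotation is sampled
independently — beta for probabilities, utilities and sub-unity relative
risks, gamma for costs; the re-fracture relative risks exceed 1 and are
sampled from gamma; the degenerate baseline oQCT screening rate (1.0) is
held fixed. Hyperparameters come from method-of-moments with
`SE = (high − low)/(2·1.96)` where a printed range exists (ranges read as
95% intervals) and `SE = 0.1·mean` otherwise. Each draw re-runs the
strategy arms (the cohort model is deterministic given parameters, so no
common random numbers are needed); acceptability is `WTP·ΔQALY − ΔC > 0`,
and the acceptability curve reports the probability each strategy has the
highest net monetary benefit over a $0–250,000 grid in $2,500 steps.

## Validation strategy

The individual-level microsimulation re-implements the identical process
with per-patient Bernoulli draws, vectorized over individuals. Because it
shares the probability construction, it validates the *accounting*
(discounting, tunnels, costs, event counting) by the law of large numbers:
the suite requires cohort/microsim agreement within 3 Monte Carlo standard
errors at n = 200,000 for all five synthetic fixture kinds (base,
perturbed, no-risk, perfect test, useless test), both sexes and all three
strategies. The *probabilities* are validated separately by an independent
exhaustive trajectory enumeration on two-cycle models, which must agree
with the engine to 10⁻⁶, and by a flat-risk configuration in which total
events per person must equal `horizon × incidence` (binomial check).

The synthetic fixtures emulate parameter perturbation and boundary cases,
not real-world heterogeneity: the cohort is homogeneous (no covariates,
no age progression beyond the five printed mortality rows, vertebral
fractures only), so passing tests certify internal consistency of the
model, not external validity for any real screening population.

## Numerical notes

State-vector mass is checked to 10⁻⁹ every cycle; a violated bound raises
rather than renormalises. Beta moment-matching clips the standard error
just inside the feasible support when a wide range meets an extreme mean.
A deterministic three-strategy run takes ~1 ms; a 30,000-iteration PSA
~25 s on one CPU.

## Known limitations

* Hip and non-vertebral fractures, societal/indirect costs, treatment
  side-effects and FRAX-style risk tools are out of scope.
* The incidence band for ages 65–75 is held constant over the 5-year
  horizon; the model is not meant for lifetime extrapolation.
* The unpublished wiring of the original TreeAge implementation could not
  be fully recovered; the convention switches bracket the plausible
  choices, and the calibrated defaults reproduce strategy-level totals
  but not every incremental quantity (see the accounting section).
* PSA draws are independent across parameters; any correlation structure
  (e.g. between sensitivity and specificity of one test) is ignored.
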