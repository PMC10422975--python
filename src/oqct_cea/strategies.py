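"""Screening strategies: who is tested when, and what a result implies.

Three policies are modeled: no screening (and no treatment), DXA screening at
the reported annual uptake rates, and one-shot opportunistic-QCT screening of
everyone at baseline.  A test result is mechanized as a Bayes split on the
annual first-fracture incidence: test-positives move to treatment carrying
their elevated conditional fracture risk, test-negatives remain untreated at
their reduced conditional risk, and the mass-weighted conditional risks
average back to the prior incidence (law of total probability).

Two policy-level care-pathway attributes distinguish the arms beyond the
test itself (see docs/methods.md for the calibration rationale):

* ``treatment_persistence`` — a DXA-initiated course is renewed at the annual
  monitoring visits and persists over the horizon; an oQCT-initiated course
  runs once for ``treatment_duration_years``.
* ``secondary_prevention`` — in the DXA (standard-of-care) arm, a patient who
  suffers an incident fracture receives a diagnostic work-up and initiates
  sustained treatment with probability equal to the test's sensitivity
  (which is exactly P(test positive | incident VF)).
"""

from __future__ import annotations

from dataclasses import dataclass

from .markov_cohort import StateTag, Stratum
from .parameters import ConfigError, ModelParameters, TestCharacteristics

__all__ = [
    "StrategyPolicy",
    "ScreeningOutcome",
    "STRATEGY_NAMES",
    "make_policy",
    "screening_split",
    "apply_screening",
]

STRATEGY_NAMES = ("no_screening", "dxa", "oqct")


@dataclass
class StrategyPolicy:
    name: str
    test: TestCharacteristics | None
    screening_schedule: list[float]
    treatment_persistence: str = "course"  # "course" | "horizon"
    secondary_prevention: bool = False

    def __post_init__(self):
        if self.name == "no_screening" and self.test is not None:
            raise ConfigError("no_screening policy carries no test")
        if any(not 0.0 <= r <= 1.0 for r in self.screening_schedule):
            raise ConfigError("screening schedule entries must lie in [0, 1]")
        if self.treatment_persistence not in ("course", "horizon"):
            raise ConfigError(
                f"unknown treatment persistence {self.treatment_persistence!r}")


@dataclass
class ScreeningOutcome:
    """Bayes decomposition of the screened population."""

    fraction_test_positive: float
    p_vf_given_positive: float
    p_vf_given_negative: float


def make_policy(name: str, params: ModelParameters) -> StrategyPolicy:
    """Build one of the three named policies from a parameter set."""
    h = params.econ.horizon_years
    if name == "no_screening":
        return StrategyPolicy(name, None, [0.0] * h)
    if name == "oqct":
        return StrategyPolicy(name, params.oqct,
                              list(params.oqct.screening_rate_by_year),
                              treatment_persistence="course")
    if name == "dxa":
        return StrategyPolicy(name, params.dxa,
                              list(params.dxa.screening_rate_by_year),
                              treatment_persistence="horizon",
                              secondary_prevention=True)
    raise ConfigError(f"unknown strategy name {name!r}")


def screening_split(incidence: float, test: TestCharacteristics) -> ScreeningOutcome:
    """Condition the annual fracture risk on the test result.

    ``fraction_test_positive = sens*inc + (1-spec)*(1-inc)``; the positive and
    negative conditional risks follow from Bayes' rule and recover the prior
    incidence under the law of total probability.
    """
    sens, spec = test.sensitivity, test.specificity
    if not 0.0 <= incidence < 1.0:
        raise ConfigError(f"incidence must lie in [0, 1), got {incidence}")
    f_pos = sens * incidence + (1.0 - spec) * (1.0 - incidence)
    p_pos = sens * incidence / f_pos if f_pos > 0.0 else 0.0
    p_neg = ((1.0 - sens) * incidence / (1.0 - f_pos)
             if f_pos < 1.0 else 0.0)
    return ScreeningOutcome(f_pos, p_pos, p_neg)


def apply_screening(
    occupancy: dict[Stratum, float],
    cycle: int,
    policy: StrategyPolicy,
    params: ModelParameters,
) -> tuple[dict[Stratum, float], float]:
    """Screen the eligible no-VF mass at the start of ``cycle`` (1-based).

    A fraction ``screening_schedule[cycle-1]`` of eligible occupancy is
    screened and pays the test's unit cost; positives move to treatment with
    their elevated conditional risk, negatives stay untreated at their
    reduced conditional risk.  Eligible are untreated no-VF individuals never
    screened before (plus past test-negatives when
    ``options.rescreen_negatives`` is set; test-positives are never
    re-screened).  The no-screening policy is the identity with zero cost.

    Returns the new occupancy and the (undiscounted, per-person) screening
    cost incurred.
    """
    if policy.test is None:
        return occupancy, 0.0
    rate = policy.screening_schedule[cycle - 1]
    if rate <= 0.0:
        return occupancy, 0.0

    inc = params.risks.annual_vf_incidence
    tx0 = (-1 if policy.treatment_persistence == "horizon"
           else params.risks.treatment_duration_years)

    rescreen = params.options.rescreen_negatives
    new: dict[Stratum, float] = {}
    cost = 0.0
    for k, v in occupancy.items():
        eligible = (
            k.tag == StateTag.NO_VF_UNTREATED
            and k.tx_left == 0
            and (k.risk == 1.0 or (rescreen and k.risk < 1.0))
        )
        if not eligible or v == 0.0:
            new[k] = new.get(k, 0.0) + v
            continue
        # Bayes split on the stratum's own prior (a re-screened negative is
        # updated from its already-reduced posterior, conserving total risk)
        prior = k.risk * inc
        outcome = screening_split(prior, policy.test)
        risk_pos = outcome.p_vf_given_positive / inc if inc > 0 else 1.0
        risk_neg = outcome.p_vf_given_negative / inc if inc > 0 else 1.0
        screened = v * rate
        cost += screened * policy.test.unit_cost
        pos = screened * outcome.fraction_test_positive
        neg = screened - pos
        new[k] = new.get(k, 0.0) + (v - screened)
        # conditional risks apply from the imminent transition on; under
        # cycle-only persistence the engine reverts them afterwards
        kp = Stratum(StateTag.NO_VF_TREATED, tx0, 0, risk_pos)
        new[kp] = new.get(kp, 0.0) + pos
        kn = Stratum(StateTag.NO_VF_UNTREATED, 0, 0, risk_neg)
        new[kn] = new.get(kn, 0.0) + neg
    return new, cost
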