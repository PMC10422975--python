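"""Model parameters for the osteoporosis screening cost-effectiveness model.

Every input of the decision model lives here: screening test characteristics
(opportunistic QCT and DXA), vertebral-fracture (VF) incidence and mortality,
treatment effect and adherence, costs, utilities, and the economic settings
(discount rate, willingness-to-pay thresholds, cohort size, horizon).  All
values are typed, validated, serializable to/from YAML or JSON, and annotated
with probabilistic-sensitivity-analysis (PSA) distributions.

Money is stored as decimal USD (the source cost tables use European comma
decimals; ``$82,61`` is 82.61 USD here).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "ConfigError",
    "ValidationError",
    "Violation",
    "TestCharacteristics",
    "RiskParameters",
    "CostParameters",
    "UtilityParameters",
    "EconomicSettings",
    "ModelOptions",
    "DistributionSpec",
    "ModelParameters",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "validate",
    "PARAMETER_REGISTRY",
    "get_parameter",
    "set_parameter",
]


class ConfigError(Exception):
    """A configuration file is missing, malformed, or has unknown keys."""


class ValidationError(Exception):
    """A parameter value violates its invariant (names field and bound)."""


@dataclass
class Violation:
    """One invariant violation found by :func:`validate`."""

    field: str
    value: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r} violates: {self.rule}"


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class TestCharacteristics:
    """Accuracy, cost and uptake of one screening test.

    ``screening_rate_by_year`` is the probability that a not-yet-positively
    screened individual is screened in each model year (length = horizon).
    Opportunistic QCT screens everyone once at baseline (``[1, 0, 0, 0, 0]``);
    DXA applies the reported annual uptake every year.
    """

    sensitivity: float
    specificity: float
    unit_cost: float
    screening_rate_by_year: list[float]


@dataclass
class RiskParameters:
    """Fracture incidence, mortality and treatment-effect inputs.

    ``annual_vf_incidence`` is the first-fracture probability per person-year
    for ages 65-75 (held constant over the 5-year horizon, which lies inside
    that age band).  ``post_vf_death_prob`` is indexed by years since fracture
    0..5 (the year-0 entry is peri-fracture mortality, applied only when
    ``ModelOptions.perifracture_mortality`` is on).  ``rr_refracture_by_year``
    multiplies the incidence for re-fracture; index 0 is the first year after
    a VF.
    """

    annual_vf_incidence: float
    post_vf_death_prob: list[float]
    background_death_prob: list[float]
    rr_treatment: float
    rr_refracture_by_year: list[float]
    adherence: float
    treatment_duration_years: int

    @property
    def effective_rr_treatment(self) -> float:
        """Intention-to-treat relative risk: adherence-weighted mixture.

        ``RR_eff = adherence * rr_treatment + (1 - adherence)``; the
        non-adherent fraction keeps untreated risk.
        """
        return self.adherence * self.rr_treatment + (1.0 - self.adherence)


@dataclass
class CostParameters:
    """Direct medical costs (2022 USD). Screening costs live on the tests.

    ``vf_cost_by_year`` holds the excess cost of a vertebral fracture in
    years 1..5 after the event; the schedule decreases as the acute episode
    resolves.
    """

    vf_cost_by_year: list[float]
    annual_treatment_cost: float

    @property
    def vf_event_cost(self) -> float:
        """Undiscounted sum of the 5-year post-fracture cost schedule.

        Under the default accrual convention this total is charged once, at
        the fracture event (see ``ModelOptions.vf_cost_accrual``).
        """
        return float(sum(self.vf_cost_by_year))


@dataclass
class UtilityParameters:
    base_utility: float
    disutility_mult_first_year: float
    disutility_mult_subsequent: float


@dataclass
class EconomicSettings:
    discount_rate: float
    wtp_primary: float
    wtp_upper: float
    cohort_size: int
    horizon_years: int
    starting_age: int


@dataclass
class ModelOptions:
    """Mechanization conventions not dictated by the published inputs.

    The defaults are the calibrated set under which the model reproduces the
    published strategy-level costs and QALYs; every switch can be flipped to
    explore the alternative conventions (see docs/methods.md).

    cycle_accounting
        ``"stage"`` accrues state rewards at stages 0..H discounted by
        (1+r)^-t (six accrual points for a 5-year horizon, the convention of
        common decision-tree software); ``"end"`` accrues at cycle ends
        1..H; ``"half_cycle"`` discounts end-of-cycle accruals at t - 1/2.
    vf_cost_accrual
        ``"event_lump"`` charges the full (undiscounted) 5-year fracture cost
        schedule once at the fracture transition; ``"annual"`` accrues
        year-k cost in the k-th post-fracture year, truncated at the horizon.
    postvf_mortality
        ``"additive"`` adds the post-VF excess death probability to background
        mortality; ``"substitute"`` uses it as the total death probability.
    perifracture_mortality
        Apply the year-0 post-VF death probability within the fracture cycle.
    risk_persistence
        ``"horizon"`` keeps Bayes-updated conditional fracture risks for the
        rest of the horizon; ``"cycle"`` reverts to background incidence after
        the screening cycle.
    rescreen_negatives
        Whether test-negative individuals re-enter the screening-eligible pool
        in later cycles.
    """

    cycle_accounting: str = "stage"
    vf_cost_accrual: str = "event_lump"
    postvf_mortality: str = "additive"
    perifracture_mortality: bool = False
    risk_persistence: str = "horizon"
    rescreen_negatives: bool = True

    _CHOICES = {
        "cycle_accounting": ("stage", "end", "half_cycle"),
        "vf_cost_accrual": ("event_lump", "annual"),
        "postvf_mortality": ("additive", "substitute"),
        "risk_persistence": ("horizon", "cycle"),
    }


@dataclass
class DistributionSpec:
    """PSA sampling annotation for one parameter.

    ``family`` is ``beta`` (probabilities, utilities, relative risks below 1),
    ``gamma`` (costs and relative risks above 1) or ``fixed``.  ``range_low``
    / ``range_high`` are the one-way sensitivity bounds.  When the source
    tables print a range it is taken verbatim and ``range_printed`` is True;
    otherwise a default +/-20% band (clipped to the valid support) is derived
    for tornado completeness and the PSA standard error falls back to
    0.1 x mean.
    """

    family: str
    mean: float
    range_low: float | None = None
    range_high: float | None = None
    range_printed: bool = False

    def standard_error(self) -> float:
        """Method-of-moments SE: (high-low)/(2*1.96) for printed ranges
        (range read as a 95% interval), else 0.1*mean."""
        if self.family == "fixed":
            return 0.0
        if self.range_printed and self.range_low is not None:
            return (self.range_high - self.range_low) / (2.0 * 1.96)
        return 0.1 * self.mean

    def moment_match(self) -> tuple[float, float]:
        """Distribution hyperparameters from (mean, SE).

        beta: (alpha, beta); gamma: (shape, scale).  For beta an SE too large
        for the support is clipped just inside the feasible bound.
        """
        m, s = self.mean, self.standard_error()
        if self.family == "beta":
            if not 0.0 < m < 1.0:
                raise ValidationError(
                    f"beta mean must lie in (0,1), got {m}"
                )
            s = min(s, 0.99 * math.sqrt(m * (1.0 - m)))
            nu = m * (1.0 - m) / (s * s) - 1.0
            return m * nu, (1.0 - m) * nu
        if self.family == "gamma":
            if m <= 0:
                raise ValidationError(f"gamma mean must be > 0, got {m}")
            return (m / s) ** 2, s * s / m
        raise ValidationError(f"unknown distribution family {self.family!r}")


@dataclass
class ModelParameters:
    """The complete parameter set for one sex, with PSA annotations."""

    sex: str
    oqct: TestCharacteristics
    dxa: TestCharacteristics
    risks: RiskParameters
    costs: CostParameters
    utilities: UtilityParameters
    econ: EconomicSettings
    options: ModelOptions = field(default_factory=ModelOptions)
    psa: dict[str, DistributionSpec] = field(default_factory=dict)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Base-case values (source cost/utility/epidemiology tables, one sex each)
# ---------------------------------------------------------------------------

_SHARED = dict(
    oqct_sens=0.59,
    oqct_spec=0.81,
    oqct_cost=82.61,
    dxa_cost=111.19,
    vf_costs=[24012.0, 5958.0, 4234.0, 3033.0, 2245.0],
    treatment_cost=100.0,
    rr_refracture=[5.0, 2.5, 2.5, 2.5, 2.5],
    adherence=0.5,
    treatment_duration=2,
    disutility_first=0.860,
    disutility_subsequent=0.965,
    discount=0.03,
    wtp_primary=70249.0,
    wtp_upper=210746.0,
    cohort=1000,
    horizon=5,
    age=65,
)

_BY_SEX = {
    "female": dict(
        dxa_sens=0.565,
        dxa_spec=0.688,
        dxa_rate=0.095,
        incidence=0.017,
        post_vf_death=[0.129, 0.103, 0.083, 0.066, 0.053, 0.043],
        background_death=[0.009638, 0.010386, 0.011235, 0.012237, 0.013393],
        rr_treatment=0.55,
        utility=0.84,
        # printed one-way / 95% ranges
        dxa_sens_range=(0.5, 0.65),
        dxa_rate_range=(0.04, 0.15),
        incidence_range=(0.012, 0.022),
    ),
    "male": dict(
        dxa_sens=0.215,
        dxa_spec=0.967,
        dxa_rate=0.017,
        incidence=0.0051,
        post_vf_death=[0.134, 0.107, 0.085, 0.068, 0.054, 0.043],
        background_death=[0.016078, 0.017216, 0.018401, 0.019666, 0.021099],
        rr_treatment=0.44,
        utility=0.87,
        dxa_sens_range=(0.15, 0.4),
        dxa_rate_range=(0.005, 0.030),
        incidence_range=(0.0035, 0.0065),
    ),
}


def _derived_range(mean: float, lo_support: float, hi_support: float) -> tuple[float, float]:
    """Default +/-20% one-way range, clipped to the valid support."""
    return max(lo_support, 0.8 * mean), min(hi_support, 1.2 * mean)


def _cost_range(mean: float) -> tuple[float, float]:
    # screening costs are printed as varied by +/-30%
    return 0.7 * mean, 1.3 * mean


def _build_psa(sex_vals: dict) -> dict[str, DistributionSpec]:
    """Distribution annotations mirroring the published table's Distr. column.

    Probabilities, utilities and sub-unity relative risks are beta; costs are
    gamma.  Re-fracture relative risks exceed 1 and are sampled from gamma
    (a beta cannot represent them).  The baseline oQCT screening rate of 1.0
    is a degenerate probability and is kept fixed.
    """

    def beta(mean, rng=None, printed=False, support=(0.0, 1.0)):
        lo, hi = rng if rng else _derived_range(mean, *support)
        return DistributionSpec("beta", mean, lo, hi, range_printed=printed)

    def gamma(mean, rng=None, printed=False):
        lo, hi = rng if rng else _derived_range(mean, 0.0, math.inf)
        return DistributionSpec("gamma", mean, lo, hi, range_printed=printed)

    s = _SHARED
    v = sex_vals
    psa: dict[str, DistributionSpec] = {
        "oqct.sensitivity": beta(s["oqct_sens"], (0.5, 0.7), printed=True),
        "oqct.specificity": beta(s["oqct_spec"]),
        "oqct.unit_cost": gamma(s["oqct_cost"], _cost_range(s["oqct_cost"]), printed=True),
        "dxa.sensitivity": beta(v["dxa_sens"], v["dxa_sens_range"], printed=True),
        "dxa.specificity": beta(v["dxa_spec"]),
        "dxa.unit_cost": gamma(s["dxa_cost"], _cost_range(s["dxa_cost"]), printed=True),
        "dxa.screening_rate": beta(v["dxa_rate"], v["dxa_rate_range"], printed=True),
        "risks.annual_vf_incidence": beta(v["incidence"], v["incidence_range"], printed=True),
        "risks.rr_treatment": beta(v["rr_treatment"]),
        "risks.adherence": beta(s["adherence"], (0.3, 0.7), printed=True),
        "risks.rr_refracture_year1": gamma(s["rr_refracture"][0]),
        "risks.rr_refracture_later": gamma(s["rr_refracture"][1]),
        "costs.annual_treatment_cost": gamma(s["treatment_cost"]),
        "utilities.base_utility": beta(v["utility"]),
        "utilities.disutility_mult_first_year": beta(s["disutility_first"]),
        "utilities.disutility_mult_subsequent": beta(s["disutility_subsequent"]),
    }
    for j, p in enumerate(v["post_vf_death"]):
        psa[f"risks.post_vf_death_prob[{j}]"] = beta(p)
    for j, p in enumerate(v["background_death"]):
        psa[f"risks.background_death_prob[{j}]"] = beta(p)
    for j, c in enumerate(s["vf_costs"]):
        psa[f"costs.vf_cost_year{j + 1}"] = gamma(c)
    return psa


def default_parameters(sex: str) -> ModelParameters:
    """The full printed base case for one sex, with PSA annotations."""
    if sex not in _BY_SEX:
        raise ConfigError(f"sex must be 'female' or 'male', got {sex!r}")
    s, v = _SHARED, _BY_SEX[sex]
    horizon = s["horizon"]
    return ModelParameters(
        sex=sex,
        oqct=TestCharacteristics(
            sensitivity=s["oqct_sens"],
            specificity=s["oqct_spec"],
            unit_cost=s["oqct_cost"],
            screening_rate_by_year=[1.0] + [0.0] * (horizon - 1),
        ),
        dxa=TestCharacteristics(
            sensitivity=v["dxa_sens"],
            specificity=v["dxa_spec"],
            unit_cost=s["dxa_cost"],
            screening_rate_by_year=[v["dxa_rate"]] * horizon,
        ),
        risks=RiskParameters(
            annual_vf_incidence=v["incidence"],
            post_vf_death_prob=list(v["post_vf_death"]),
            background_death_prob=list(v["background_death"]),
            rr_treatment=v["rr_treatment"],
            rr_refracture_by_year=list(s["rr_refracture"]),
            adherence=s["adherence"],
            treatment_duration_years=s["treatment_duration"],
        ),
        costs=CostParameters(
            vf_cost_by_year=list(s["vf_costs"]),
            annual_treatment_cost=s["treatment_cost"],
        ),
        utilities=UtilityParameters(
            base_utility=v["utility"],
            disutility_mult_first_year=s["disutility_first"],
            disutility_mult_subsequent=s["disutility_subsequent"],
        ),
        econ=EconomicSettings(
            discount_rate=s["discount"],
            wtp_primary=s["wtp_primary"],
            wtp_upper=s["wtp_upper"],
            cohort_size=s["cohort"],
            horizon_years=horizon,
            starting_age=s["age"],
        ),
        options=ModelOptions(),
        psa=_build_psa(v),
    )


# ---------------------------------------------------------------------------
# Parameter registry: flat-name access for sensitivity analyses
# ---------------------------------------------------------------------------


def _risk_list_access(attr: str, idx: int):
    def get(p: ModelParameters) -> float:
        return getattr(p.risks, attr)[idx]

    def set_(p: ModelParameters, x: float) -> None:
        getattr(p.risks, attr)[idx] = x

    return get, set_


def _registry() -> dict:
    reg = {
        "oqct.sensitivity": (lambda p: p.oqct.sensitivity,
                             lambda p, x: setattr(p.oqct, "sensitivity", x)),
        "oqct.specificity": (lambda p: p.oqct.specificity,
                             lambda p, x: setattr(p.oqct, "specificity", x)),
        "oqct.unit_cost": (lambda p: p.oqct.unit_cost,
                           lambda p, x: setattr(p.oqct, "unit_cost", x)),
        "dxa.sensitivity": (lambda p: p.dxa.sensitivity,
                            lambda p, x: setattr(p.dxa, "sensitivity", x)),
        "dxa.specificity": (lambda p: p.dxa.specificity,
                            lambda p, x: setattr(p.dxa, "specificity", x)),
        "dxa.unit_cost": (lambda p: p.dxa.unit_cost,
                          lambda p, x: setattr(p.dxa, "unit_cost", x)),
        "dxa.screening_rate": (
            lambda p: p.dxa.screening_rate_by_year[0],
            lambda p, x: p.dxa.__setattr__(
                "screening_rate_by_year", [x] * p.econ.horizon_years),
        ),
        "risks.annual_vf_incidence": (
            lambda p: p.risks.annual_vf_incidence,
            lambda p, x: setattr(p.risks, "annual_vf_incidence", x)),
        "risks.rr_treatment": (lambda p: p.risks.rr_treatment,
                               lambda p, x: setattr(p.risks, "rr_treatment", x)),
        "risks.adherence": (lambda p: p.risks.adherence,
                            lambda p, x: setattr(p.risks, "adherence", x)),
        "risks.rr_refracture_year1": (
            lambda p: p.risks.rr_refracture_by_year[0],
            lambda p, x: p.risks.rr_refracture_by_year.__setitem__(0, x)),
        "risks.rr_refracture_later": (
            lambda p: p.risks.rr_refracture_by_year[1],
            lambda p, x: p.risks.rr_refracture_by_year.__setitem__(
                slice(1, None), [x] * (len(p.risks.rr_refracture_by_year) - 1))),
        "costs.annual_treatment_cost": (
            lambda p: p.costs.annual_treatment_cost,
            lambda p, x: setattr(p.costs, "annual_treatment_cost", x)),
        "utilities.base_utility": (
            lambda p: p.utilities.base_utility,
            lambda p, x: setattr(p.utilities, "base_utility", x)),
        "utilities.disutility_mult_first_year": (
            lambda p: p.utilities.disutility_mult_first_year,
            lambda p, x: setattr(p.utilities, "disutility_mult_first_year", x)),
        "utilities.disutility_mult_subsequent": (
            lambda p: p.utilities.disutility_mult_subsequent,
            lambda p, x: setattr(p.utilities, "disutility_mult_subsequent", x)),
    }
    for j in range(6):
        reg[f"risks.post_vf_death_prob[{j}]"] = _risk_list_access("post_vf_death_prob", j)
    for j in range(5):
        reg[f"risks.background_death_prob[{j}]"] = _risk_list_access("background_death_prob", j)
    for j in range(5):
        name = f"costs.vf_cost_year{j + 1}"
        reg[name] = (
            (lambda p, j=j: p.costs.vf_cost_by_year[j]),
            (lambda p, x, j=j: p.costs.vf_cost_by_year.__setitem__(j, x)),
        )
    return reg


PARAMETER_REGISTRY = _registry()


def get_parameter(params: ModelParameters, name: str) -> float:
    try:
        return PARAMETER_REGISTRY[name][0](params)
    except KeyError:
        raise ConfigError(f"unknown parameter name {name!r}") from None


def set_parameter(params: ModelParameters, name: str, value: float) -> None:
    try:
        PARAMETER_REGISTRY[name][1](params, value)
    except KeyError:
        raise ConfigError(f"unknown parameter name {name!r}") from None


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_prob(out: list[Violation], name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        out.append(Violation(name, value, "probability must lie in [0, 1]"))


def validate(params: ModelParameters) -> list[Violation]:
    """All invariant violations in ``params`` (empty list when valid)."""
    v: list[Violation] = []
    h = params.econ.horizon_years

    if params.sex not in ("female", "male"):
        v.append(Violation("sex", params.sex, "must be 'female' or 'male'"))

    for tname in ("oqct", "dxa"):
        t: TestCharacteristics = getattr(params, tname)
        _check_prob(v, f"{tname}.sensitivity", t.sensitivity)
        _check_prob(v, f"{tname}.specificity", t.specificity)
        if t.unit_cost < 0:
            v.append(Violation(f"{tname}.unit_cost", t.unit_cost, "must be >= 0"))
        if len(t.screening_rate_by_year) != h:
            v.append(Violation(
                f"{tname}.screening_rate_by_year",
                len(t.screening_rate_by_year),
                f"must have exactly horizon_years={h} entries"))
        for j, r in enumerate(t.screening_rate_by_year):
            _check_prob(v, f"{tname}.screening_rate_by_year[{j}]", r)

    r = params.risks
    _check_prob(v, "risks.annual_vf_incidence", r.annual_vf_incidence)
    for j, p in enumerate(r.post_vf_death_prob):
        _check_prob(v, f"risks.post_vf_death_prob[{j}]", p)
    for j, p in enumerate(r.background_death_prob):
        _check_prob(v, f"risks.background_death_prob[{j}]", p)
    if len(r.background_death_prob) < h:
        v.append(Violation("risks.background_death_prob",
                           len(r.background_death_prob),
                           f"needs an entry per model year (horizon {h})"))
    if not 0.0 < r.rr_treatment <= 1.0:
        v.append(Violation("risks.rr_treatment", r.rr_treatment,
                           "must lie in (0, 1]"))
    for j, rr in enumerate(r.rr_refracture_by_year):
        if rr < 1.0:
            v.append(Violation(f"risks.rr_refracture_by_year[{j}]", rr,
                               "must be >= 1"))
    _check_prob(v, "risks.adherence", r.adherence)
    if r.treatment_duration_years < 1:
        v.append(Violation("risks.treatment_duration_years",
                           r.treatment_duration_years, "must be >= 1"))

    c = params.costs
    for j, x in enumerate(c.vf_cost_by_year):
        if x < 0:
            v.append(Violation(f"costs.vf_cost_by_year[{j}]", x, "must be >= 0"))
    if any(a <= b for a, b in zip(c.vf_cost_by_year[1:], c.vf_cost_by_year[2:])) \
            or (len(c.vf_cost_by_year) > 1 and c.vf_cost_by_year[0] <= c.vf_cost_by_year[1]):
        v.append(Violation("costs.vf_cost_by_year", c.vf_cost_by_year,
                           "must be strictly decreasing over years 1..5"))
    if c.annual_treatment_cost < 0:
        v.append(Violation("costs.annual_treatment_cost",
                           c.annual_treatment_cost, "must be >= 0"))

    u = params.utilities
    for name, x in (("base_utility", u.base_utility),
                    ("disutility_mult_first_year", u.disutility_mult_first_year),
                    ("disutility_mult_subsequent", u.disutility_mult_subsequent)):
        if not 0.0 < x <= 1.0:
            v.append(Violation(f"utilities.{name}", x, "must lie in (0, 1]"))

    e = params.econ
    if e.discount_rate < 0:
        v.append(Violation("econ.discount_rate", e.discount_rate, "must be >= 0"))
    if not e.wtp_primary < e.wtp_upper:
        v.append(Violation("econ.wtp_primary", e.wtp_primary,
                           "must be below wtp_upper"))
    if e.horizon_years < 1:
        v.append(Violation("econ.horizon_years", e.horizon_years, "must be >= 1"))
    if e.cohort_size < 1:
        v.append(Violation("econ.cohort_size", e.cohort_size, "must be >= 1"))

    o = params.options
    for name, choices in ModelOptions._CHOICES.items():
        if getattr(o, name) not in choices:
            v.append(Violation(f"options.{name}", getattr(o, name),
                               f"must be one of {choices}"))

    for name, spec in params.psa.items():
        if name not in PARAMETER_REGISTRY:
            v.append(Violation(f"psa.{name}", name, "unknown parameter name"))
            continue
        if spec.family not in ("beta", "gamma", "fixed"):
            v.append(Violation(f"psa.{name}.family", spec.family,
                               "must be beta, gamma or fixed"))
        elif spec.family == "beta" and not 0.0 < spec.mean < 1.0:
            v.append(Violation(f"psa.{name}.mean", spec.mean,
                               "beta mean must lie in (0, 1)"))
        elif spec.family == "gamma" and spec.mean <= 0:
            v.append(Violation(f"psa.{name}.mean", spec.mean,
                               "gamma mean must be > 0"))
        if spec.range_low is not None and spec.range_high is not None:
            if not spec.range_low <= spec.mean <= spec.range_high:
                v.append(Violation(f"psa.{name}.range", (spec.range_low, spec.range_high),
                                   "must bracket the mean"))
    return v


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

_BLOCK_TYPES = {
    "oqct": TestCharacteristics,
    "dxa": TestCharacteristics,
    "risks": RiskParameters,
    "costs": CostParameters,
    "utilities": UtilityParameters,
    "econ": EconomicSettings,
    "options": ModelOptions,
}


def _to_plain(params: ModelParameters) -> dict:
    d = {
        "sex": params.sex,
        "oqct": asdict(params.oqct),
        "dxa": asdict(params.dxa),
        "risks": asdict(params.risks),
        "costs": asdict(params.costs),
        "utilities": asdict(params.utilities),
        "econ": asdict(params.econ),
        "options": asdict(params.options),
        "psa": {k: asdict(s) for k, s in params.psa.items()},
    }
    return d


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    doc = _to_plain(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def _build_block(name: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {name!r}: {', '.join(sorted(unknown))}")
    missing = known - set(data)
    if missing and cls is not ModelOptions:
        raise ConfigError(
            f"missing key(s) in section {name!r}: {', '.join(sorted(missing))}")
    return cls(**data)


def load_parameters(path: str | Path, sex: str | None = None) -> ModelParameters:
    """Load and validate a parameter set from a YAML/JSON config file.

    The file may hold a single-sex document or a two-sex document keyed by
    ``female`` / ``male`` (then ``sex`` selects the one to load).  Unknown
    keys raise :class:`ConfigError`; invariant violations raise
    :class:`ValidationError` naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping: {path}")

    if "sex" not in doc and {"female", "male"} & set(doc):
        if sex is None:
            raise ConfigError("two-sex config: pass sex='female' or 'male'")
        if sex not in doc:
            raise ConfigError(f"config has no section for sex {sex!r}")
        doc = doc[sex]

    top_known = set(_BLOCK_TYPES) | {"sex", "psa"}
    unknown = set(doc) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    missing = (set(_BLOCK_TYPES) | {"sex"}) - set(doc) - {"options"}
    if missing:
        raise ConfigError(f"missing required key(s): {', '.join(sorted(missing))}")
    if sex is not None and doc["sex"] != sex:
        raise ConfigError(f"config sex {doc['sex']!r} does not match requested {sex!r}")

    blocks = {
        name: _build_block(name, cls, doc.get(name, {}))
        for name, cls in _BLOCK_TYPES.items()
    }
    psa = {}
    for k, spec in (doc.get("psa") or {}).items():
        psa[k] = _build_block(f"psa.{k}", DistributionSpec, spec)
    params = ModelParameters(sex=doc["sex"], psa=psa, **blocks)
    violations = validate(params)
    if violations:
        raise ValidationError("; ".join(str(x) for x in violations))
    return params


def bundled_config_path() -> Path:
    """Path of the shipped two-sex base-case YAML config."""
    return Path(__file__).parent / "data" / "base_case.yaml"


def iter_table_cells(sex: str) -> Iterator[tuple[str, float]]:
    """Yield (flat name, value) for every numeric base-case input cell.

    Used by table-driven tests that pin the defaults to the published inputs.
    """
    p = default_parameters(sex)
    for name in PARAMETER_REGISTRY:
        yield name, get_parameter(p, name)
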