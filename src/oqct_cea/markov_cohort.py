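"""Discrete-time Markov cohort engine with tunnel states.

The cohort moves in annual cycles through four health states — alive without
vertebral fracture (VF), alive without VF on osteoporosis treatment, alive
after a VF, and dead (absorbing).  Time-dependence is handled with tunnel
sub-states: years on treatment (treatment effect and cost stop when the
course ends) and years since fracture (post-VF mortality, re-fracture risk,
costs and disutility all decay with time since the event).  A re-fracture
resets the years-since-fracture clock and counts as a new VF event.

The engine propagates expected occupancy (probability mass), so a single run
is deterministic and fast; the individual-level Monte Carlo mirror lives in
:mod:`oqct_cea.microsim_oracle`.

Competing risks within a cycle are resolved as marginal branch
probabilities: death and fracture both apply at their printed annual
probabilities and the remainder stays put, with the fracture branch capped
at the surviving mass (P(fracture) = min(p_frac, 1 - p_death)) so the
distribution stays well formed for extreme inputs.  A raw fracture
probability above 1 (inconsistent inputs) raises :class:`ModelError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, TYPE_CHECKING

import pandas as pd

from .parameters import ModelParameters, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .strategies import StrategyPolicy

__all__ = [
    "ModelError",
    "StateTag",
    "HealthState",
    "StateVector",
    "CycleTrace",
    "StrategyResult",
    "build_state_space",
    "transition_probabilities",
    "run_cohort",
    "discount",
]

MASS_TOL = 1e-12


class ModelError(Exception):
    """Inconsistent model inputs detected at run time (e.g. probabilities
    combining above 1)."""


class StateTag:
    NO_VF_UNTREATED = "NO_VF_UNTREATED"
    NO_VF_TREATED = "NO_VF_TREATED"
    POST_VF = "POST_VF"
    DEAD = "DEAD"


@dataclass(frozen=True)
class HealthState:
    """One state of the expanded (tunnel) state space.

    ``years_on_treatment`` (1..treatment duration) applies to NO_VF_TREATED;
    ``years_since_vf`` (0..horizon-1) and ``treated_flag`` apply to POST_VF.
    """

    tag: str
    years_on_treatment: int = 0
    years_since_vf: int = 0
    treated_flag: bool = False

    def __post_init__(self):
        if self.tag == StateTag.DEAD and (
                self.years_on_treatment or self.years_since_vf or self.treated_flag):
            raise ModelError("DEAD carries no sub-indices")


class Stratum(NamedTuple):
    """Internal propagation key: a health state refined by the screening
    risk class (``risk`` multiplies the background first-fracture incidence)
    and the exact remaining treatment course (``tx_left``; -1 = persistent)."""

    tag: str
    tx_left: int
    ys: int
    risk: float


DEAD = Stratum(StateTag.DEAD, 0, 0, 1.0)


@dataclass
class StateVector:
    """Occupancy over the public state space at one point in time."""

    occupancy: dict[HealthState, float]

    def __post_init__(self):
        total = sum(self.occupancy.values())
        if abs(total - 1.0) > 1e-9:
            raise ModelError(f"state vector mass {total} != 1")
        if any(v < -MASS_TOL for v in self.occupancy.values()):
            raise ModelError("negative occupancy")

    def total(self) -> float:
        return sum(self.occupancy.values())

    def __getitem__(self, state: HealthState) -> float:
        return self.occupancy.get(state, 0.0)


@dataclass
class CycleTrace:
    cycle_index: int
    undiscounted_cost: float
    discounted_cost: float
    undiscounted_qaly: float
    discounted_qaly: float
    incident_vf_events: float
    deaths: float
    state_vector_end: StateVector


@dataclass
class StrategyResult:
    """Cumulative discounted outcomes for one strategy, scaled to the cohort."""

    strategy: str
    cumulative_discounted_cost: float
    cumulative_discounted_qalys: float
    total_vf_events: float
    trace: list[CycleTrace] = field(repr=False)
    cumulative_undiscounted_cost: float = 0.0
    cumulative_undiscounted_qalys: float = 0.0
    total_deaths: float = 0.0
    cohort_size: int = 1000

    def trace_frame(self) -> pd.DataFrame:
        """Per-cycle trace as a tidy table (exportable as CSV)."""
        rows = []
        for t in self.trace:
            row = {
                "cycle": t.cycle_index,
                "undiscounted_cost": t.undiscounted_cost,
                "discounted_cost": t.discounted_cost,
                "undiscounted_qaly": t.undiscounted_qaly,
                "discounted_qaly": t.discounted_qaly,
                "vf_events": t.incident_vf_events,
                "deaths": t.deaths,
            }
            for s, m in t.state_vector_end.occupancy.items():
                key = s.tag
                if s.tag == StateTag.NO_VF_TREATED:
                    key += f"_y{s.years_on_treatment}"
                elif s.tag == StateTag.POST_VF:
                    key += f"_{s.years_since_vf}" + ("_tx" if s.treated_flag else "")
                row[key] = m
            rows.append(row)
        return pd.DataFrame(rows).fillna(0.0)


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------


def build_state_space(params: ModelParameters) -> list[HealthState]:
    """Deterministically ordered expanded state space.

    One untreated no-VF state, a treatment tunnel of ``treatment_duration``
    years, a post-VF tunnel of ``horizon`` years split by active treatment,
    and the absorbing dead state: ``1 + duration + 2*horizon + 1`` states.
    """
    dur = params.risks.treatment_duration_years
    h = params.econ.horizon_years
    space = [HealthState(StateTag.NO_VF_UNTREATED)]
    space += [HealthState(StateTag.NO_VF_TREATED, years_on_treatment=y)
              for y in range(1, dur + 1)]
    space += [HealthState(StateTag.POST_VF, years_since_vf=j, treated_flag=fl)
              for j in range(h) for fl in (False, True)]
    space.append(HealthState(StateTag.DEAD))
    return space


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------


def _branch_probs(params: ModelParameters, tag: str, ys: int, cycle: int,
                  fracture_rr: float, on_treatment: bool) -> tuple[float, float]:
    """(fracture probability, death probability) for one alive state/cycle.

    ``cycle`` is 1-based.  ``fracture_rr`` multiplies the background
    first-fracture incidence (screening risk class and/or treatment effect);
    from post-VF states the re-fracture relative risk applies instead, with
    the treatment effect on top when treatment is active.
    """
    r = params.risks
    rre = r.effective_rr_treatment
    bg = r.background_death_prob[min(cycle - 1, len(r.background_death_prob) - 1)]
    if tag in (StateTag.NO_VF_UNTREATED, StateTag.NO_VF_TREATED):
        p_frac = r.annual_vf_incidence * fracture_rr
        p_death = bg
    elif tag == StateTag.POST_VF:
        rrf = r.rr_refracture_by_year[min(ys, len(r.rr_refracture_by_year) - 1)]
        p_frac = r.annual_vf_incidence * rrf * (rre if on_treatment else 1.0)
        excess = r.post_vf_death_prob[min(ys + 1, len(r.post_vf_death_prob) - 1)]
        if params.options.postvf_mortality == "additive":
            p_death = min(excess + bg, 1.0)
        else:
            p_death = excess
    else:
        raise ModelError(f"no transitions from state tag {tag!r}")
    if p_frac > 1.0 + MASS_TOL:
        raise ModelError(
            f"fracture probability {p_frac} exceeds 1 in state {tag} "
            f"(cycle {cycle}): inconsistent inputs")
    # marginal branch probabilities, fracture capped at the surviving mass
    return min(p_frac, 1.0 - p_death), p_death


def transition_probabilities(
    state: HealthState,
    cycle: int,
    params: ModelParameters,
    treatment_active_fracture_rr: float = 1.0,
) -> dict[HealthState, float]:
    """One-cycle transition distribution from an alive state.

    ``treatment_active_fracture_rr`` is the effective relative risk applied
    to the first-fracture incidence for this state (1.0 for untreated
    background risk; the adherence-weighted treatment RR — possibly combined
    with a Bayes-updated risk class — for treated/stratified sub-cohorts).
    Probabilities are non-negative and sum to 1; DEAD is absorbing.
    """
    if not 1 <= cycle <= params.econ.horizon_years:
        raise ModelError(f"cycle {cycle} outside 1..{params.econ.horizon_years}")
    if state.tag == StateTag.DEAD:
        return {HealthState(StateTag.DEAD): 1.0}

    dur = params.risks.treatment_duration_years
    h = params.econ.horizon_years
    on_tx = (state.tag == StateTag.NO_VF_TREATED) or \
            (state.tag == StateTag.POST_VF and state.treated_flag)
    rr = treatment_active_fracture_rr
    p_frac, p_death = _branch_probs(params, state.tag, state.years_since_vf,
                                    cycle, rr, on_tx)

    out: dict[HealthState, float] = {HealthState(StateTag.DEAD): p_death}
    p_stay = 1.0 - p_frac - p_death

    if state.tag == StateTag.NO_VF_UNTREATED:
        fractured = HealthState(StateTag.POST_VF, years_since_vf=0)
        stay = state
    elif state.tag == StateTag.NO_VF_TREATED:
        still_on = state.years_on_treatment < dur
        fractured = HealthState(StateTag.POST_VF, years_since_vf=0,
                                treated_flag=still_on)
        stay = (HealthState(StateTag.NO_VF_TREATED,
                            years_on_treatment=state.years_on_treatment + 1)
                if still_on else HealthState(StateTag.NO_VF_UNTREATED))
    else:  # POST_VF: re-fracture resets the clock
        fractured = HealthState(StateTag.POST_VF, years_since_vf=0,
                                treated_flag=state.treated_flag)
        stay = HealthState(StateTag.POST_VF,
                           years_since_vf=min(state.years_since_vf + 1, h - 1),
                           treated_flag=state.treated_flag)

    if params.options.perifracture_mortality:
        d0 = params.risks.post_vf_death_prob[0]
        out[HealthState(StateTag.DEAD)] += p_frac * d0
        p_frac *= (1.0 - d0)
    out[fractured] = out.get(fractured, 0.0) + p_frac
    out[stay] = out.get(stay, 0.0) + p_stay
    return out


# ---------------------------------------------------------------------------
# Discounting
# ---------------------------------------------------------------------------


def discount(value: float, cycle: int, rate: float, timing: str = "end") -> float:
    """Present value of a cycle-``cycle`` amount.

    ``timing``: ``"end"`` divides by (1+r)^cycle, ``"begin"`` by
    (1+r)^(cycle-1), ``"half_cycle"`` by (1+r)^(cycle-1/2).
    """
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    if cycle < 1:
        raise ValidationError(f"cycle must be >= 1, got {cycle}")
    offset = {"end": 0.0, "begin": 1.0, "half_cycle": 0.5}
    if timing not in offset:
        raise ValidationError(f"unknown discount timing {timing!r}")
    return value / (1.0 + rate) ** (cycle - offset[timing])


# ---------------------------------------------------------------------------
# Cohort propagation
# ---------------------------------------------------------------------------


def _stratum_to_state(k: Stratum, duration: int) -> HealthState:
    if k.tag == StateTag.DEAD:
        return HealthState(StateTag.DEAD)
    if k.tag == StateTag.POST_VF:
        return HealthState(StateTag.POST_VF, years_since_vf=k.ys,
                           treated_flag=k.tx_left != 0)
    if k.tx_left != 0:
        years_on = duration if k.tx_left < 0 else duration - k.tx_left + 1
        return HealthState(StateTag.NO_VF_TREATED,
                           years_on_treatment=max(1, min(years_on, duration)))
    return HealthState(StateTag.NO_VF_UNTREATED)


def _aggregate(occ: dict[Stratum, float], duration: int) -> StateVector:
    agg: dict[HealthState, float] = {}
    for k, v in occ.items():
        s = _stratum_to_state(k, duration)
        agg[s] = agg.get(s, 0.0) + v
    return StateVector(agg)


def _accrual_plan(options, rate: float, horizon: int):
    """Discount factors per accounting convention.

    Returns (state_df, screen_df, event_df, stage_accrual) where the df's
    are indexed by transition/stage index t = 0..H-1 (plus t = H for state
    accrual under the stage convention) and ``stage_accrual`` says whether
    state rewards accrue at cycle starts (stages 0..H) or cycle ends (1..H).
    """
    v = 1.0 + rate
    mode = options.cycle_accounting
    if mode == "stage":
        state_df = [v ** -t for t in range(horizon + 1)]
        screen_df = [v ** -t for t in range(horizon)]
        event_df = [v ** -t for t in range(horizon)]
        return state_df, screen_df, event_df, True
    if mode == "end":
        state_df = [0.0] + [v ** -t for t in range(1, horizon + 1)]
        screen_df = [v ** -(t + 1) for t in range(horizon)]
        event_df = [v ** -(t + 1) for t in range(horizon)]
        return state_df, screen_df, event_df, False
    if mode == "half_cycle":
        state_df = [0.0] + [v ** -(t - 0.5) for t in range(1, horizon + 1)]
        screen_df = [v ** -(t + 1) for t in range(horizon)]
        event_df = [v ** -(t + 1) for t in range(horizon)]
        return state_df, screen_df, event_df, False
    raise ValidationError(f"unknown cycle accounting {mode!r}")


def _accrue(occ: dict[Stratum, float], params: ModelParameters,
            df: float) -> tuple[float, float, float, float]:
    """State rewards for one accrual point: (cost, qaly, disc cost, disc qaly)."""
    u = params.utilities
    tx_cost = params.costs.annual_treatment_cost * params.risks.adherence
    annual_vf = params.options.vf_cost_accrual == "annual"
    vf_costs = params.costs.vf_cost_by_year
    cost = qaly = 0.0
    for k, v in occ.items():
        if k.tag == StateTag.DEAD or v == 0.0:
            continue
        if k.tag == StateTag.POST_VF:
            mult = (u.disutility_mult_first_year if k.ys == 0
                    else u.disutility_mult_subsequent)
            qaly += v * u.base_utility * mult
            if annual_vf and k.ys < len(vf_costs):
                cost += v * vf_costs[k.ys]
        else:
            qaly += v * u.base_utility
        if k.tx_left != 0:
            cost += v * tx_cost
    return cost, qaly, cost * df, qaly * df


def run_cohort(params: ModelParameters, strategy: "StrategyPolicy") -> StrategyResult:
    """Run the cohort model for one screening strategy.

    Each cycle applies screening (Bayes split into treated test-positives and
    untreated test-negatives, handled by :mod:`oqct_cea.strategies`), then the
    fracture/death transition, accruing discounted costs, QALYs, VF events and
    deaths.  Results are scaled to ``econ.cohort_size``.
    """
    from .strategies import apply_screening  # local import: no module cycle

    h = params.econ.horizon_years
    dur = params.risks.treatment_duration_years
    n = params.econ.cohort_size
    rre = params.risks.effective_rr_treatment
    state_df, screen_df, event_df, stage_accrual = _accrual_plan(
        params.options, params.econ.discount_rate, h)
    vf_event_cost = params.costs.vf_event_cost
    event_lump = params.options.vf_cost_accrual == "event_lump"

    occ: dict[Stratum, float] = {Stratum(StateTag.NO_VF_UNTREATED, 0, 0, 1.0): 1.0}
    rows: list[CycleTrace] = []
    cum = dict(c=0.0, q=0.0, dc=0.0, dq=0.0, vf=0.0, deaths=0.0)

    for t in range(h):  # transition index t: cycle t+1
        row = dict(c=0.0, q=0.0, dc=0.0, dq=0.0, vf=0.0, deaths=0.0)

        # --- screening at the start of the cycle
        occ, scr_cost = apply_screening(occ, t + 1, strategy, params)
        row["c"] += scr_cost
        row["dc"] += scr_cost * screen_df[t]

        # --- state rewards at the cycle start (stage convention)
        if stage_accrual:
            c, q, dc, dq = _accrue(occ, params, state_df[t])
            row["c"] += c; row["q"] += q; row["dc"] += dc; row["dq"] += dq

        # --- fracture / death transition
        new: dict[Stratum, float] = {}

        def put(k: Stratum, v: float) -> None:
            new[k] = new.get(k, 0.0) + v

        for k, v in occ.items():
            if v == 0.0:
                continue
            if k.tag == StateTag.DEAD:
                put(k, v)
                continue
            on_tx = k.tx_left != 0
            frac_rr = k.risk * (rre if on_tx else 1.0) \
                if k.tag != StateTag.POST_VF else 1.0
            p_frac, p_death = _branch_probs(params, k.tag, k.ys, t + 1,
                                            frac_rr, on_tx)
            put(DEAD, v * p_death)
            row["deaths"] += v * p_death
            fr = v * p_frac
            row["vf"] += fr
            if event_lump:
                row["c"] += fr * vf_event_cost
                row["dc"] += fr * vf_event_cost * event_df[t]
            if params.options.perifracture_mortality:
                d0 = params.risks.post_vf_death_prob[0]
                put(DEAD, fr * d0)
                row["deaths"] += fr * d0
                fr *= (1.0 - d0)
            next_tx = k.tx_left if k.tx_left < 0 else max(k.tx_left - 1, 0)
            # secondary prevention: a fracture triggers a diagnostic work-up;
            # P(test positive | incident VF) = sensitivity, and positives
            # start sustained treatment
            sec = (strategy.test.sensitivity
                   if strategy.secondary_prevention and strategy.test else 0.0)
            if sec > 0.0:
                put(Stratum(StateTag.POST_VF, -1, 0, 1.0), fr * sec)
                fr = fr * (1.0 - sec)
            put(Stratum(StateTag.POST_VF, next_tx, 0, 1.0), fr)
            survive = v * (1.0 - p_frac - p_death)
            if k.tag == StateTag.POST_VF:
                put(Stratum(StateTag.POST_VF, next_tx, min(k.ys + 1, h - 1), 1.0),
                    survive)
            else:
                risk = k.risk if params.options.risk_persistence == "horizon" else 1.0
                put(Stratum(k.tag if next_tx != 0 else StateTag.NO_VF_UNTREATED,
                            next_tx, 0, risk), survive)
        occ = new

        # re-tag: treated strata whose course ended are plain NO_VF_UNTREATED
        occ = {
            (k._replace(tag=StateTag.NO_VF_UNTREATED)
             if k.tag == StateTag.NO_VF_TREATED and k.tx_left == 0 else k): v
            for k, v in occ.items()
        }

        # --- state rewards at the cycle end (end / half-cycle conventions)
        if not stage_accrual:
            c, q, dc, dq = _accrue(occ, params, state_df[t + 1])
            row["c"] += c; row["q"] += q; row["dc"] += dc; row["dq"] += dq

        # --- terminal stage reward folded into the last cycle row
        if stage_accrual and t == h - 1:
            c, q, dc, dq = _accrue(occ, params, state_df[h])
            row["c"] += c; row["q"] += q; row["dc"] += dc; row["dq"] += dq

        total = sum(occ.values())
        if abs(total - 1.0) > 1e-9:
            raise ModelError(f"mass leak: cohort total {total} after cycle {t + 1}")

        for key in cum:
            cum[key] += row[{"c": "c", "q": "q", "dc": "dc", "dq": "dq",
                             "vf": "vf", "deaths": "deaths"}[key]]
        rows.append(CycleTrace(
            cycle_index=t + 1,
            undiscounted_cost=row["c"] * n,
            discounted_cost=row["dc"] * n,
            undiscounted_qaly=row["q"] * n,
            discounted_qaly=row["dq"] * n,
            incident_vf_events=row["vf"] * n,
            deaths=row["deaths"] * n,
            state_vector_end=_aggregate(occ, dur),
        ))

    return StrategyResult(
        strategy=strategy.name,
        cumulative_discounted_cost=cum["dc"] * n,
        cumulative_discounted_qalys=cum["dq"] * n,
        total_vf_events=cum["vf"] * n,
        trace=rows,
        cumulative_undiscounted_cost=cum["c"] * n,
        cumulative_undiscounted_qalys=cum["q"] * n,
        total_deaths=cum["deaths"] * n,
        cohort_size=n,
    )
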