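"""Individual-level Monte Carlo mirror of the cohort engine.

Each simulated patient follows a stochastic trajectory through the same
screening / fracture / death process, using Bernoulli draws against the same
per-cycle probabilities the cohort engine constructs.  By the law of large
numbers the per-person means converge to the cohort engine's expected
values, so the microsimulation is a brute-force oracle for the engine's
accounting (costs, QALYs, discounting, tunnel bookkeeping).

Because it deliberately reuses the probability construction
(:func:`oqct_cea.markov_cohort._branch_probs` and the screening split), it
validates the accounting rather than the probabilities; a separate
exhaustive trajectory enumeration (:func:`expected_outcomes_by_enumeration`)
with its own probability arithmetic covers the latter on small horizons.

Also hosts the synthetic parameter-set generator used as test fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov_cohort import StateTag, _accrual_plan, _branch_probs
from .parameters import (
    ModelParameters,
    PARAMETER_REGISTRY,
    default_parameters,
    get_parameter,
    set_parameter,
)
from .strategies import StrategyPolicy

__all__ = [
    "MicrosimEstimate",
    "simulate_individuals",
    "generate_fixture",
    "expected_outcomes_by_enumeration",
]


@dataclass
class MicrosimEstimate:
    """Monte Carlo means +- standard errors, scaled to the cohort size."""

    mean_cost: float
    mean_qalys: float
    mean_vf_events: float
    se_cost: float
    se_qalys: float
    se_vf_events: float
    n_individuals: int
    seed: int

    def within(self, cost: float, qalys: float, vf: float, n_se: float = 3.0) -> bool:
        """Do the cohort-engine values lie within ``n_se`` standard errors?"""
        checks = [
            (cost, self.mean_cost, self.se_cost),
            (qalys, self.mean_qalys, self.se_qalys),
            (vf, self.mean_vf_events, self.se_vf_events),
        ]
        return all(abs(x - m) <= n_se * max(se, 1e-9) for x, m, se in checks)


def simulate_individuals(
    params: ModelParameters,
    policy: StrategyPolicy,
    n_individuals: int,
    seed: int,
) -> MicrosimEstimate:
    """Simulate ``n_individuals`` independent patient trajectories.

    Vectorized over individuals; reproducible under ``seed``.  Returns means
    and standard errors scaled to ``econ.cohort_size``.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    n = n_individuals
    h = params.econ.horizon_years
    r = params.risks
    inc = r.annual_vf_incidence
    rre = r.effective_rr_treatment
    u = params.utilities
    tx_cost = params.costs.annual_treatment_cost * r.adherence
    event_lump = params.options.vf_cost_accrual == "event_lump"
    annual_vf = not event_lump
    vf_costs = np.asarray(params.costs.vf_cost_by_year)
    lump = params.costs.vf_event_cost
    state_df, screen_df, event_df, stage_accrual = _accrual_plan(
        params.options, params.econ.discount_rate, h)
    persist = params.options.risk_persistence == "horizon"
    rescreen = params.options.rescreen_negatives
    peri = params.options.perifracture_mortality

    if policy.test is not None:
        tx0 = -1 if policy.treatment_persistence == "horizon" \
            else r.treatment_duration_years

    NOVF, POSTVF, DEADC = 0, 1, 2
    tag = np.zeros(n, dtype=np.int8)
    risk = np.ones(n)
    tx_left = np.zeros(n, dtype=np.int32)
    ys = np.zeros(n, dtype=np.int32)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    vf = np.zeros(n)

    def accrue(df: float) -> None:
        alive = tag != DEADC
        util = np.where(
            tag == POSTVF,
            u.base_utility * np.where(ys == 0, u.disutility_mult_first_year,
                                      u.disutility_mult_subsequent),
            u.base_utility,
        )
        qaly[alive] += util[alive] * df
        on_tx = alive & (tx_left != 0)
        cost[on_tx] += tx_cost * df
        if annual_vf:
            paying = (tag == POSTVF) & (ys < len(vf_costs))
            cost[paying] += vf_costs[np.minimum(ys[paying], len(vf_costs) - 1)] * df

    for t in range(h):
        # --- screening (Bayes split on each individual's current prior)
        if policy.test is not None and policy.screening_schedule[t] > 0.0:
            eligible = (tag == NOVF) & (tx_left == 0) & (
                (risk == 1.0) | (rescreen & (risk < 1.0)))
            screened = eligible & (rng.random(n) < policy.screening_schedule[t])
            cost[screened] += policy.test.unit_cost * screen_df[t]
            sens, spec = policy.test.sensitivity, policy.test.specificity
            prior = risk * inc
            f_pos = sens * prior + (1.0 - spec) * (1.0 - prior)
            positive = screened & (rng.random(n) < f_pos)
            negative = screened & ~positive
            with np.errstate(invalid="ignore", divide="ignore"):
                r_pos = np.where(f_pos > 0, sens * prior / np.maximum(f_pos, 1e-300), 0.0)
                r_neg = np.where(f_pos < 1,
                                 (1 - sens) * prior / np.maximum(1 - f_pos, 1e-300), 0.0)
            if inc > 0:
                r_pos, r_neg = r_pos / inc, r_neg / inc
            else:
                r_pos = np.ones(n)
                r_neg = np.ones(n)
            # conditional risks apply from the imminent transition; under
            # cycle-only persistence they are reverted after it
            tx_left[positive] = tx0
            risk[positive] = r_pos[positive]
            risk[negative] = r_neg[negative]

        if stage_accrual:
            accrue(state_df[t])

        # --- transition: per-individual branch probabilities
        p_frac = np.zeros(n)
        p_death = np.zeros(n)
        alive = tag != DEADC
        for code, tag_name in ((NOVF, None), (POSTVF, StateTag.POST_VF)):
            sel = alive & (tag == code)
            if not sel.any():
                continue
            if code == NOVF:
                on = tx_left[sel] != 0
                frac_rr = risk[sel] * np.where(on, rre, 1.0)
                _, pd_ = _branch_probs(params, StateTag.NO_VF_UNTREATED, 0,
                                       t + 1, 1.0, False)
                # marginal allocation, fracture capped (mirrors the engine)
                p_frac[sel] = np.minimum(inc * frac_rr, 1.0 - pd_)
                p_death[sel] = pd_
            else:
                idx = np.flatnonzero(sel)
                for j in np.unique(ys[idx]):
                    sub = idx[ys[idx] == j]
                    on = tx_left[sub] != 0
                    pf_on, pd_ = _branch_probs(params, StateTag.POST_VF, int(j),
                                               t + 1, 1.0, True)
                    pf_off, _ = _branch_probs(params, StateTag.POST_VF, int(j),
                                              t + 1, 1.0, False)
                    p_frac[sub] = np.where(on, pf_on, pf_off)
                    p_death[sub] = pd_
        if np.any(p_frac + p_death > 1.0 + 1e-12):
            raise ValueError("fracture + death probabilities exceed 1")

        draw = rng.random(n)
        dies = alive & (draw < p_death)
        fractures = alive & ~dies & (draw < p_death + p_frac)
        if peri and fractures.any():
            d0 = r.post_vf_death_prob[0]
            peri_dies = fractures & (rng.random(n) < d0)
        else:
            peri_dies = np.zeros(n, dtype=bool)

        vf[fractures] += 1
        if event_lump:
            cost[fractures] += lump * event_df[t]

        survivors = alive & ~dies & ~fractures
        # treated-course countdown for everyone alive at the cycle start
        next_tx = np.where(tx_left > 0, tx_left - 1, tx_left)
        frac_tx = next_tx.copy()
        if policy.secondary_prevention and policy.test is not None:
            # post-fracture work-up positive with P = sensitivity
            workup_pos = fractures & (rng.random(n) < policy.test.sensitivity)
            frac_tx[workup_pos] = -1

        tag[dies | peri_dies] = DEADC
        frac_alive = fractures & ~peri_dies
        tx_left[frac_alive] = frac_tx[frac_alive]
        ys[frac_alive] = 0
        risk[frac_alive] = 1.0
        tag[frac_alive] = POSTVF

        post_stay = survivors & (tag == POSTVF)
        ys[post_stay] = np.minimum(ys[post_stay] + 1, h - 1)
        novf_stay = survivors & (tag == NOVF)
        if not persist:
            risk[novf_stay] = 1.0
        tx_left[survivors] = next_tx[survivors]

        if not stage_accrual:
            accrue(state_df[t + 1])
        if stage_accrual and t == h - 1:
            accrue(state_df[h])

    scale = params.econ.cohort_size
    def mean_se(x):
        m = float(np.mean(x))
        se = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return m * scale, se * scale

    mc, sc = mean_se(cost)
    mq, sq = mean_se(qaly)
    mv, sv = mean_se(vf)
    return MicrosimEstimate(mc, mq, mv, sc, sq, sv, n, seed)


# ---------------------------------------------------------------------------
# Exhaustive trajectory enumeration (small horizons)
# ---------------------------------------------------------------------------


def expected_outcomes_by_enumeration(
    params: ModelParameters,
    policy: StrategyPolicy,
    max_horizon: int = 3,
) -> tuple[float, float, float]:
    """Exact expected (discounted cost, discounted QALYs, VF events) by
    brute-force enumeration of every trajectory.

    An independent accounting path: recursion over explicit trajectories with
    probability products, no occupancy vectors.  Exponential in the horizon,
    so guarded to small models; intended as a validation oracle.
    """
    h = params.econ.horizon_years
    if h > max_horizon:
        raise ValueError(f"enumeration limited to horizon <= {max_horizon}")
    r = params.risks
    inc = r.annual_vf_incidence
    rre = r.effective_rr_treatment
    u = params.utilities
    tx_cost = params.costs.annual_treatment_cost * r.adherence
    lump = params.costs.vf_event_cost
    event_lump = params.options.vf_cost_accrual == "event_lump"
    vf_costs = params.costs.vf_cost_by_year
    state_df, screen_df, event_df, stage_accrual = _accrual_plan(
        params.options, params.econ.discount_rate, h)
    persist = params.options.risk_persistence == "horizon"

    if policy.test is not None:
        sens, spec = policy.test.sensitivity, policy.test.specificity
        f_pos = sens * inc + (1 - spec) * (1 - inc)
        p_pos = sens * inc / f_pos if f_pos > 0 else 0.0
        p_neg = (1 - sens) * inc / (1 - f_pos) if f_pos < 1 else 0.0
        tx0 = -1 if policy.treatment_persistence == "horizon" \
            else r.treatment_duration_years

    totals = [0.0, 0.0, 0.0]  # E[cost], E[qaly], E[vf]

    def util_of(tag, ys):
        if tag == "post":
            mult = (u.disutility_mult_first_year if ys == 0
                    else u.disutility_mult_subsequent)
            return u.base_utility * mult
        return u.base_utility

    def state_reward(tag, ys, tx, df):
        c = tx_cost * df if tx != 0 else 0.0
        if not event_lump and tag == "post" and ys < len(vf_costs):
            c += vf_costs[ys] * df
        return c, util_of(tag, ys) * df

    def walk(t, tag, ys, tx, risk, prob, cost, qaly, vf):
        if prob == 0.0:
            return
        if tag == "dead":
            totals[0] += prob * cost
            totals[1] += prob * qaly
            totals[2] += prob * vf
            return
        # screening
        if (policy.test is not None and t < h
                and policy.screening_schedule[t] > 0 and tag == "novf"
                and tx == 0 and risk == 1.0):
            rate = policy.screening_schedule[t]
            if rate > 0:
                scr_cost = policy.test.unit_cost * screen_df[t]
                walk_screened = [
                    (rate * f_pos, tx0, p_pos / inc if inc else 1.0),
                    (rate * (1 - f_pos), 0,
                     (p_neg / inc if inc else 1.0) if persist else 1.0),
                ]
                for p_branch, new_tx, new_risk in walk_screened:
                    _after_screen(t, "novf", ys, new_tx, new_risk,
                                  prob * p_branch, cost + scr_cost, qaly, vf)
                _after_screen(t, tag, ys, tx, risk, prob * (1 - rate),
                              cost, qaly, vf)
                return
        _after_screen(t, tag, ys, tx, risk, prob, cost, qaly, vf)

    def _after_screen(t, tag, ys, tx, risk, prob, cost, qaly, vf):
        if stage_accrual:
            dc, dq = state_reward(tag, ys, tx, state_df[t])
            cost, qaly = cost + dc, qaly + dq
        if t == h:
            totals[0] += prob * cost
            totals[1] += prob * qaly
            totals[2] += prob * vf
            return
        # transition probabilities (own arithmetic)
        bg = r.background_death_prob[min(t, len(r.background_death_prob) - 1)]
        if tag == "novf":
            p_frac = inc * risk * (rre if tx != 0 else 1.0)
            p_death = bg
        else:
            rrf = r.rr_refracture_by_year[min(ys, len(r.rr_refracture_by_year) - 1)]
            p_frac = inc * rrf * (rre if tx != 0 else 1.0)
            excess = r.post_vf_death_prob[min(ys + 1, len(r.post_vf_death_prob) - 1)]
            p_death = min(excess + bg, 1.0) \
                if params.options.postvf_mortality == "additive" else excess
        p_frac = min(p_frac, 1.0 - p_death)  # marginal allocation, capped
        next_tx = tx - 1 if tx > 0 else tx
        sec = (policy.test.sensitivity
               if policy.secondary_prevention and policy.test is not None else 0.0)
        d0 = r.post_vf_death_prob[0] if params.options.perifracture_mortality else 0.0

        def land(t2, tag2, ys2, tx2, risk2, p2, c2, q2, v2):
            if not stage_accrual and tag2 != "dead":
                dc, dq = state_reward(tag2, ys2, tx2, state_df[t2])
                c2, q2 = c2 + dc, q2 + dq
            if stage_accrual and t2 == h and tag2 != "dead":
                dc, dq = state_reward(tag2, ys2, tx2, state_df[h])
                c2, q2 = c2 + dc, q2 + dq
            if t2 == h or tag2 == "dead":
                totals[0] += p2 * c2
                totals[1] += p2 * q2
                totals[2] += p2 * v2
            else:
                walk(t2, tag2, ys2, tx2, risk2, p2, c2, q2, v2)

        # death branch
        land(t + 1, "dead", 0, 0, 1.0, prob * p_death, cost, qaly, vf)
        # fracture branch (with optional peri-fracture death and
        # sensitivity-gated secondary-prevention work-up)
        ec = lump * event_df[t] if event_lump else 0.0
        land(t + 1, "dead", 0, 0, 1.0, prob * p_frac * d0, cost + ec, qaly, vf + 1)
        p_live = prob * p_frac * (1 - d0)
        land(t + 1, "post", 0, -1, 1.0, p_live * sec, cost + ec, qaly, vf + 1)
        land(t + 1, "post", 0, next_tx, 1.0, p_live * (1 - sec),
             cost + ec, qaly, vf + 1)
        # stay branch
        p_stay = 1.0 - p_frac - p_death
        if tag == "novf":
            land(t + 1, "novf", 0, next_tx, risk if persist else 1.0,
                 prob * p_stay, cost, qaly, vf)
        else:
            land(t + 1, "post", min(ys + 1, h - 1), next_tx, 1.0,
                 prob * p_stay, cost, qaly, vf)

    walk(0, "novf", 0, 0, 1.0, 1.0, 0.0, 0.0, 0.0)
    scale = params.econ.cohort_size
    return totals[0] * scale, totals[1] * scale, totals[2] * scale


# ---------------------------------------------------------------------------
# Synthetic parameter fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("base", "perturbed", "degenerate_no_risk",
                 "perfect_test", "useless_test")


def generate_fixture(kind: str, sex: str, seed: int = 0) -> ModelParameters:
    """Synthetic parameter sets for testing every stage without downloads.

    ``base`` is the printed base case; ``perturbed`` jitters every registry
    parameter by up to +-10% within its support (seeded, reproducible);
    ``degenerate_no_risk`` zeroes all incidence and mortality;
    ``perfect_test`` sets both tests to sensitivity = specificity = 1;
    ``useless_test`` makes both tests uninformative (sens = 1 - spec).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    p = default_parameters(sex)
    if kind == "base":
        return p
    if kind == "perturbed":
        rng = np.random.default_rng(seed)
        for name in PARAMETER_REGISTRY:
            x = get_parameter(p, name)
            y = x * (1.0 + rng.uniform(-0.1, 0.1))
            if ("prob" in name or "sensitivity" in name or "specificity" in name
                    or "incidence" in name or "rate" in name or "adherence" in name
                    or "utilit" in name or "rr_treatment" in name):
                y = min(max(y, 0.0), 1.0)
            if "rr_refracture" in name:
                y = max(y, 1.0)
            set_parameter(p, name, y)
        return p
    if kind == "degenerate_no_risk":
        p.risks.annual_vf_incidence = 0.0
        p.risks.post_vf_death_prob = [0.0] * len(p.risks.post_vf_death_prob)
        p.risks.background_death_prob = [0.0] * len(p.risks.background_death_prob)
        return p
    if kind == "perfect_test":
        for test in (p.oqct, p.dxa):
            test.sensitivity = 1.0
            test.specificity = 1.0
        return p
    # useless_test: positive rate equals 1 - specificity regardless of outcome
    for test in (p.oqct, p.dxa):
        test.sensitivity = 1.0 - test.specificity
    return p
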