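"""Cohort engine: state space, transitions, accounting invariants."""

import pytest

from oqct_cea import (
    HealthState,
    ModelError,
    StateTag,
    ValidationError,
    build_state_space,
    discount,
    make_policy,
    run_cohort,
    transition_probabilities,
)
from oqct_cea.microsim_oracle import generate_fixture


def test_state_space_counts(female_params):
    # 1 untreated + duration treated + 2*horizon post-VF + dead
    assert len(build_state_space(female_params)) == 14
    female_params.risks.treatment_duration_years = 1
    assert len(build_state_space(female_params)) == 13
    female_params.risks.treatment_duration_years = 2
    female_params.econ.horizon_years = 1
    assert len(build_state_space(female_params)) == 6


def test_state_space_deterministic_order(params):
    assert build_state_space(params) == build_state_space(params)
    assert build_state_space(params)[-1].tag == StateTag.DEAD


def test_dead_state_carries_no_subindices():
    with pytest.raises(ModelError):
        HealthState(StateTag.DEAD, years_since_vf=2)


def test_transition_from_untreated_no_vf(female_params):
    """Fracture and death both apply at their printed probabilities."""
    out = transition_probabilities(
        HealthState(StateTag.NO_VF_UNTREATED), 1, female_params)
    assert out[HealthState(StateTag.DEAD)] == pytest.approx(0.009638)
    assert out[HealthState(StateTag.POST_VF, years_since_vf=0)] == pytest.approx(0.017)
    assert out[HealthState(StateTag.NO_VF_UNTREATED)] == pytest.approx(
        1 - 0.009638 - 0.017)
    assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)


def test_post_vf_death_probability_substitute_mode(female_params):
    """Under the substitute convention the year-1 post-VF probability is the
    total death probability one cycle after the fracture."""
    female_params.options.postvf_mortality = "substitute"
    out = transition_probabilities(
        HealthState(StateTag.POST_VF, years_since_vf=0), 2, female_params)
    assert out[HealthState(StateTag.DEAD)] == pytest.approx(0.103)


def test_post_vf_death_probability_additive_mode(female_params):
    out = transition_probabilities(
        HealthState(StateTag.POST_VF, years_since_vf=0), 2, female_params)
    assert out[HealthState(StateTag.DEAD)] == pytest.approx(0.103 + 0.010386)


def test_zero_risk_transition_is_identity(sex):
    p = generate_fixture("degenerate_no_risk", sex)
    state = HealthState(StateTag.NO_VF_UNTREATED)
    out = transition_probabilities(state, 1, p)
    assert out[state] == pytest.approx(1.0)
    assert out[HealthState(StateTag.DEAD)] == 0.0


def test_treatment_tunnel_progression(female_params):
    s1 = HealthState(StateTag.NO_VF_TREATED, years_on_treatment=1)
    out = transition_probabilities(s1, 1, female_params, 0.775)
    assert HealthState(StateTag.NO_VF_TREATED, years_on_treatment=2) in out
    s2 = HealthState(StateTag.NO_VF_TREATED, years_on_treatment=2)
    out = transition_probabilities(s2, 2, female_params, 0.775)
    assert HealthState(StateTag.NO_VF_UNTREATED) in out  # course over
    # fracturing in the final treatment year leaves treatment inactive
    assert out[HealthState(StateTag.POST_VF, years_since_vf=0)] > 0


def test_inconsistent_probabilities_raise(female_params):
    with pytest.raises(ModelError):
        transition_probabilities(
            HealthState(StateTag.NO_VF_UNTREATED), 1, female_params,
            treatment_active_fracture_rr=80.0)


def test_discount_examples():
    assert discount(100.0, 1, 0.0) == 100.0
    assert discount(100.0, 3, 0.03) == pytest.approx(100 / 1.03 ** 3)
    assert discount(57.0, 4, 0.0) == 57.0
    assert discount(100.0, 1, 0.03, timing="begin") == 100.0
    with pytest.raises(ValidationError):
        discount(100.0, 1, -0.01)


# ---------------------------------------------------------------------------
# run_cohort accounting
# ---------------------------------------------------------------------------


def test_riskless_undiscounted_qalys_end_of_cycle(sex):
    """With no events, no screening and no discounting, a person accrues
    horizon x utility QALYs under end-of-cycle accounting."""
    p = generate_fixture("degenerate_no_risk", sex)
    p.econ.discount_rate = 0.0
    p.options.cycle_accounting = "end"
    r = run_cohort(p, make_policy("no_screening", p))
    expected = 5 * p.utilities.base_utility * p.econ.cohort_size
    assert r.cumulative_discounted_qalys == pytest.approx(expected)


def test_riskless_discounted_qalys_closed_form(female_params):
    p = generate_fixture("degenerate_no_risk", "female")
    p.options.cycle_accounting = "end"
    geo = sum(0.84 / 1.03 ** t for t in range(1, 6))
    r = run_cohort(p, make_policy("no_screening", p))
    assert r.cumulative_discounted_qalys == pytest.approx(geo * 1000)

    p.options.cycle_accounting = "stage"
    stage = sum(0.84 / 1.03 ** t for t in range(0, 6))
    r = run_cohort(p, make_policy("no_screening", p))
    assert r.cumulative_discounted_qalys == pytest.approx(stage * 1000)

    p.options.cycle_accounting = "half_cycle"
    half = sum(0.84 / 1.03 ** (t - 0.5) for t in range(1, 6))
    r = run_cohort(p, make_policy("no_screening", p))
    assert r.cumulative_discounted_qalys == pytest.approx(half * 1000)


@pytest.mark.parametrize("kind", ["base", "perturbed", "perfect_test",
                                  "useless_test"])
def test_mass_conservation_and_monotone_death(sex, policy_name, kind):
    p = generate_fixture(kind, sex, seed=11)
    r = run_cohort(p, make_policy(policy_name, p))
    dead_prev = 0.0
    for row in r.trace:
        sv = row.state_vector_end
        assert sv.total() == pytest.approx(1.0, abs=1e-9)
        dead = sv[HealthState(StateTag.DEAD)]
        assert dead >= dead_prev - 1e-12
        dead_prev = dead


def test_zero_discount_rate_matches_undiscounted(sex, policy_name):
    p = generate_fixture("base", sex)
    p.econ.discount_rate = 0.0
    r = run_cohort(p, make_policy(policy_name, p))
    assert r.cumulative_discounted_cost == pytest.approx(
        r.cumulative_undiscounted_cost)
    assert r.cumulative_discounted_qalys == pytest.approx(
        r.cumulative_undiscounted_qalys)


def test_cumulative_fields_equal_trace_sums(params, policy):
    r = run_cohort(params, policy)
    assert sum(t.discounted_cost for t in r.trace) == pytest.approx(
        r.cumulative_discounted_cost, abs=1e-6)
    assert sum(t.discounted_qaly for t in r.trace) == pytest.approx(
        r.cumulative_discounted_qalys, abs=1e-6)
    assert sum(t.incident_vf_events for t in r.trace) == pytest.approx(
        r.total_vf_events, abs=1e-9)
    for t in r.trace:
        assert t.discounted_cost <= t.undiscounted_cost + 1e-9
        assert t.discounted_qaly <= t.undiscounted_qaly + 1e-9


@pytest.mark.parametrize("screen_name", ["dxa", "oqct"])
def test_uninformative_free_screening_equals_no_screening(sex, screen_name):
    """sensitivity 0, specificity 1, zero cost: screening does nothing."""
    p = generate_fixture("base", sex)
    for test in (p.oqct, p.dxa):
        test.sensitivity = 0.0
        test.specificity = 1.0
        test.unit_cost = 0.0
    ref = run_cohort(p, make_policy("no_screening", p))
    scr = run_cohort(p, make_policy(screen_name, p))
    assert scr.cumulative_discounted_cost == pytest.approx(
        ref.cumulative_discounted_cost, abs=1e-6)
    assert scr.cumulative_discounted_qalys == pytest.approx(
        ref.cumulative_discounted_qalys, abs=1e-9)
    assert scr.total_vf_events == pytest.approx(ref.total_vf_events, abs=1e-9)


def test_stronger_treatment_never_increases_fractures(sex):
    p = generate_fixture("base", sex)
    events = []
    for rr in (1.0, 0.8, 0.6, 0.4, 0.2, 0.05):
        p.risks.rr_treatment = rr
        events.append(run_cohort(p, make_policy("oqct", p)).total_vf_events)
    assert all(a >= b - 1e-9 for a, b in zip(events, events[1:]))


def test_trace_frame_exports(params, policy):
    frame = run_cohort(params, policy).trace_frame()
    assert len(frame) == params.econ.horizon_years
    assert {"cycle", "discounted_cost", "discounted_qaly", "vf_events",
            "deaths", "DEAD"} <= set(frame.columns)
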