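"""Tornado, cost-threshold search and probabilistic sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from oqct_cea import (
    ThresholdError,
    ValidationError,
    cost_threshold,
    make_policy,
    one_way_tornado,
    run_cohort,
    run_psa,
    sample_parameters,
)
from oqct_cea.parameters import DistributionSpec, get_parameter
from oqct_cea.sensitivity import _draw, _raw_icer


def test_tornado_entry_rederivable_by_full_runs(female_params):
    entries = one_way_tornado(female_params, ["risks.adherence"])
    (entry,) = entries
    assert (entry.low_value, entry.high_value) == (0.3, 0.7)
    for value, recorded in ((0.3, entry.icer_at_low), (0.7, entry.icer_at_high)):
        p = female_params.copy()
        p.risks.adherence = value
        a = run_cohort(p, make_policy("oqct", p))
        b = run_cohort(p, make_policy("dxa", p))
        expected = _raw_icer(
            a.cumulative_discounted_cost - b.cumulative_discounted_cost,
            a.cumulative_discounted_qalys - b.cumulative_discounted_qalys)
        assert recorded == pytest.approx(expected)
    assert entry.spread == pytest.approx(abs(entry.icer_at_high - entry.icer_at_low))


def test_tornado_leaves_base_case_untouched(female_params):
    before = female_params.copy()
    one_way_tornado(female_params, ["risks.adherence", "oqct.unit_cost"])
    assert female_params == before


def test_tornado_sorted_descending_and_zero_width_range(female_params):
    female_params.psa["oqct.unit_cost"] = DistributionSpec(
        "gamma", 82.61, 82.61, 82.61, range_printed=True)
    entries = one_way_tornado(
        female_params, ["oqct.unit_cost", "risks.adherence"])
    spreads = [e.spread for e in entries]
    assert spreads == sorted(spreads, reverse=True)
    flat = next(e for e in entries if e.parameter == "oqct.unit_cost")
    assert flat.spread == pytest.approx(0.0, abs=1e-9)


def test_tornado_range_outside_support_rejected(female_params):
    female_params.psa["risks.adherence"] = DistributionSpec(
        "beta", 0.5, -0.1, 0.7, range_printed=True)
    with pytest.raises(ValidationError):
        one_way_tornado(female_params, ["risks.adherence"])


def test_influential_parameters_rank_high(male_params):
    """Treatment adherence and fracture incidence are among the strongest
    drivers of the ICER in men."""
    entries = one_way_tornado(male_params)
    top = [e.parameter for e in entries[:5]]
    assert "risks.adherence" in top
    assert "risks.annual_vf_incidence" in top


def test_threshold_consistency(params):
    """Plugging the threshold cost back in meets the objective to tolerance."""
    comp = run_cohort(params, make_policy("dxa", params))
    for objective in ("icer_equals_wtp", "equal_total_cost"):
        c = cost_threshold(params, objective=objective, tol=0.5)
        p = params.copy()
        p.oqct.unit_cost = c
        res = run_cohort(p, make_policy("oqct", p))
        dc = res.cumulative_discounted_cost - comp.cumulative_discounted_cost
        dq = res.cumulative_discounted_qalys - comp.cumulative_discounted_qalys
        value = dc if objective == "equal_total_cost" else dc - p.econ.wtp_primary * dq
        # $0.5 on the unit cost moves total cost by <= $500 per 1,000 screened
        assert abs(value) < 600


def test_threshold_without_sign_change_reports_endpoints(female_params):
    with pytest.raises(ThresholdError, match="does not change sign"):
        cost_threshold(female_params, objective="equal_total_cost",
                       bracket=(0.0, 10.0))


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


def test_sample_parameters_deterministic_under_seed(params):
    a = sample_parameters(params, 123)
    b = sample_parameters(params, 123)
    c = sample_parameters(params, 124)
    assert a == b
    assert a != c


def test_fixed_and_zero_se_draw_equals_mean():
    rng = np.random.default_rng(0)
    assert _draw(DistributionSpec("fixed", 0.4), rng) == 0.4
    assert _draw(DistributionSpec("beta", 0.4, 0.4, 0.4, range_printed=True),
                 rng) == 0.4


def test_beta_draws_match_annotated_moments():
    spec = DistributionSpec("beta", 0.59, 0.5, 0.7, range_printed=True)
    rng = np.random.default_rng(7)
    draws = np.array([_draw(spec, rng) for _ in range(10_000)])
    assert ((draws > 0) & (draws < 1)).all()
    assert draws.mean() == pytest.approx(0.59, abs=0.005)
    assert draws.std() == pytest.approx(0.2 / 3.92, rel=0.1)


def test_gamma_cost_draws_nonnegative(params):
    rng = np.random.default_rng(3)
    for _ in range(200):
        q = sample_parameters(params, rng)
        assert q.costs.vf_cost_by_year[0] >= 0
        assert q.oqct.unit_cost >= 0
        assert 0 <= q.risks.adherence <= 1
        assert q.risks.rr_refracture_by_year[0] >= 1.0


def test_psa_seed_determinism(female_params):
    a = run_psa(female_params, 40, seed=9)
    b = run_psa(female_params, 40, seed=9)
    pd.testing.assert_frame_equal(a.samples, b.samples)
    pd.testing.assert_frame_equal(a.ceac, b.ceac)
    c = run_psa(female_params, 40, seed=10)
    assert not a.samples.equals(c.samples)


def test_degenerate_psa_reproduces_base_case(female_params):
    for spec in female_params.psa.values():
        spec.family = "fixed"
    res = run_psa(female_params, 10, seed=0)
    assert res.samples["delta_cost"].nunique() == 1
    assert res.samples["delta_qalys"].nunique() == 1
    assert res.fraction_acceptable in (0.0, 1.0)


def test_ceac_properties(female_params):
    res = run_psa(female_params, 250, seed=1,
                  wtp_grid=np.arange(0, 200_001, 20_000.0))
    probs = res.ceac[["p_no_screening", "p_dxa", "p_oqct"]]
    assert np.allclose(probs.sum(axis=1), 1.0)
    # oQCT gains QALYs in essentially all draws, so its acceptability is
    # non-decreasing in the willingness to pay
    p_oqct = res.ceac["p_oqct"].to_numpy()
    assert (np.diff(p_oqct) >= -1e-12).all()


def test_psa_requires_iterations(female_params):
    with pytest.raises(ValidationError):
        run_psa(female_params, 0, seed=0)
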