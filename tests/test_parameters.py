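"""Base-case inputs, config round-trips and validation."""

import math

import pytest

from oqct_cea import (
    ConfigError,
    ValidationError,
    default_parameters,
    load_parameters,
    save_parameters,
    validate,
)
from oqct_cea.parameters import (
    DistributionSpec,
    bundled_config_path,
    get_parameter,
)

# Every numeric base-case input cell, frozen from the published inputs.
_EXPECTED_SHARED = {
    "oqct.sensitivity": 0.59,
    "oqct.specificity": 0.81,
    "oqct.unit_cost": 82.61,
    "dxa.unit_cost": 111.19,
    "risks.rr_refracture_year1": 5.0,
    "risks.rr_refracture_later": 2.5,
    "risks.adherence": 0.5,
    "costs.vf_cost_year1": 24012.0,
    "costs.vf_cost_year2": 5958.0,
    "costs.vf_cost_year3": 4234.0,
    "costs.vf_cost_year4": 3033.0,
    "costs.vf_cost_year5": 2245.0,
    "costs.annual_treatment_cost": 100.0,
    "utilities.disutility_mult_first_year": 0.860,
    "utilities.disutility_mult_subsequent": 0.965,
}
_EXPECTED_BY_SEX = {
    "female": {
        "dxa.sensitivity": 0.565,
        "dxa.specificity": 0.688,
        "dxa.screening_rate": 0.095,
        "risks.annual_vf_incidence": 0.017,
        "risks.rr_treatment": 0.55,
        "utilities.base_utility": 0.84,
        **{f"risks.post_vf_death_prob[{j}]": v for j, v in enumerate(
            [0.129, 0.103, 0.083, 0.066, 0.053, 0.043])},
        **{f"risks.background_death_prob[{j}]": v for j, v in enumerate(
            [0.009638, 0.010386, 0.011235, 0.012237, 0.013393])},
    },
    "male": {
        "dxa.sensitivity": 0.215,
        "dxa.specificity": 0.967,
        "dxa.screening_rate": 0.017,
        "risks.annual_vf_incidence": 0.0051,
        "risks.rr_treatment": 0.44,
        "utilities.base_utility": 0.87,
        **{f"risks.post_vf_death_prob[{j}]": v for j, v in enumerate(
            [0.134, 0.107, 0.085, 0.068, 0.054, 0.043])},
        **{f"risks.background_death_prob[{j}]": v for j, v in enumerate(
            [0.016078, 0.017216, 0.018401, 0.019666, 0.021099])},
    },
}


def test_defaults_reproduce_every_input_cell(sex, params):
    expected = {**_EXPECTED_SHARED, **_EXPECTED_BY_SEX[sex]}
    for name, value in expected.items():
        assert get_parameter(params, name) == pytest.approx(value, abs=0), name


def test_default_structure(female_params, male_params):
    assert female_params.oqct.screening_rate_by_year == [1.0, 0, 0, 0, 0]
    assert male_params.dxa.screening_rate_by_year == [0.017] * 5
    assert female_params.econ.discount_rate == 0.03
    assert female_params.econ.wtp_primary == 70249
    assert female_params.econ.wtp_upper == 210746
    assert female_params.econ.cohort_size == 1000
    assert female_params.econ.horizon_years == 5
    assert female_params.econ.starting_age == 65
    assert male_params.risks.background_death_prob[0] == 0.016078


def test_base_case_is_valid(params):
    assert validate(params) == []


def test_roundtrip_yaml_and_json(params, tmp_path):
    for suffix in (".yaml", ".json"):
        path = tmp_path / f"cfg{suffix}"
        save_parameters(params, path)
        loaded = load_parameters(path)
        assert loaded == params


def test_bundled_config_matches_defaults(sex):
    loaded = load_parameters(bundled_config_path(), sex=sex)
    assert loaded == default_parameters(sex)


def test_unknown_key_rejected_by_name(params, tmp_path):
    import yaml
    from oqct_cea.parameters import _to_plain

    doc = _to_plain(params)
    doc["risks"]["bogus_rate"] = 0.5
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(doc))
    with pytest.raises(ConfigError, match="bogus_rate"):
        load_parameters(path)


def test_missing_key_named(params, tmp_path):
    import yaml
    from oqct_cea.parameters import _to_plain

    doc = _to_plain(params)
    del doc["risks"]["adherence"]
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(doc))
    with pytest.raises(ConfigError, match="adherence"):
        load_parameters(path)


def test_out_of_range_probability_rejected(params, tmp_path):
    params.oqct.sensitivity = 1.3
    path = tmp_path / "cfg.yaml"
    save_parameters(params, path)
    with pytest.raises(ValidationError, match="oqct.sensitivity"):
        load_parameters(path)


@pytest.mark.parametrize("mutate, field", [
    (lambda p: setattr(p.costs, "vf_cost_by_year",
                       sorted(p.costs.vf_cost_by_year)), "vf_cost_by_year"),
    (lambda p: setattr(p.oqct, "screening_rate_by_year", [1.0, 0, 0, 0]),
     "screening_rate_by_year"),
    (lambda p: setattr(p.risks, "rr_treatment", 0.0), "rr_treatment"),
    (lambda p: setattr(p.risks, "rr_refracture_by_year", [0.5, 2.5, 2.5, 2.5, 2.5]),
     "rr_refracture_by_year"),
])
def test_validate_reports_violation(female_params, mutate, field):
    mutate(female_params)
    violations = validate(female_params)
    assert len(violations) == 1
    assert field in violations[0].field


def test_printed_and_derived_ranges(female_params):
    psa = female_params.psa
    assert psa["oqct.sensitivity"].range_printed
    assert (psa["oqct.sensitivity"].range_low,
            psa["oqct.sensitivity"].range_high) == (0.5, 0.7)
    assert (psa["risks.adherence"].range_low,
            psa["risks.adherence"].range_high) == (0.3, 0.7)
    # no printed range: default +/-20% band, clipped to support
    spec = psa["utilities.base_utility"]
    assert not spec.range_printed
    assert spec.range_low == pytest.approx(0.8 * 0.84)
    assert spec.range_high == pytest.approx(min(1.0, 1.2 * 0.84))


def test_moment_matching_recovers_mean_and_se():
    spec = DistributionSpec("beta", 0.59, 0.5, 0.7, range_printed=True)
    a, b = spec.moment_match()
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert mean == pytest.approx(0.59)
    assert math.sqrt(var) == pytest.approx(0.2 / 3.92, rel=1e-6)

    gspec = DistributionSpec("gamma", 24012.0)
    shape, scale = gspec.moment_match()
    assert shape * scale == pytest.approx(24012.0)
    assert math.sqrt(shape) * scale == pytest.approx(2401.2)
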