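import pytest

from oqct_cea import default_parameters, make_policy


@pytest.fixture(params=["female", "male"])
def sex(request):
    return request.param


@pytest.fixture
def params(sex):
    return default_parameters(sex)


@pytest.fixture
def female_params():
    return default_parameters("female")


@pytest.fixture
def male_params():
    return default_parameters("male")


@pytest.fixture(params=["no_screening", "dxa", "oqct"])
def policy_name(request):
    return request.param


@pytest.fixture
def policy(params, policy_name):
    return make_policy(policy_name, params)
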