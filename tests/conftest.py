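import pytest

from modelreduce.model_core import load_drivers, parse_model_spec, simulate
from modelreduce.screening import screen_all
from modelreduce.synthetic import (
    ToyCropConfig,
    build_toy_crop_model,
    generate_observations,
    generate_weather,
)

#: Seed used by most fixture-driven tests; role-recovery checks sweep 0..4.
FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def toy_config():
    return ToyCropConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def toy_model(toy_config):
    return build_toy_crop_model(toy_config)


@pytest.fixture(scope="session")
def toy_spec(toy_model):
    return toy_model[0]


@pytest.fixture(scope="session")
def toy_truth(toy_model):
    return toy_model[1]


@pytest.fixture(scope="session")
def toy_weather(toy_config):
    return generate_weather(toy_config)


@pytest.fixture(scope="session")
def toy_drivers(toy_weather):
    return load_drivers(toy_weather)


@pytest.fixture(scope="session")
def toy_obs(toy_spec, toy_drivers, toy_config, toy_truth):
    return generate_observations(toy_spec, toy_drivers, toy_config, toy_truth)


@pytest.fixture(scope="session")
def full_traj(toy_spec, toy_drivers):
    return simulate(toy_spec, toy_drivers)


@pytest.fixture(scope="session")
def screening_rows(toy_spec, toy_drivers, toy_obs, toy_truth):
    return screen_all(toy_spec, toy_drivers, toy_obs, toy_truth.exclusions)


MINIMAL_SPEC = """
name: minimal
parameters: {r: 2.0}
drivers: []
outputs: [b]
variables:
  - name: b
    rule: "b + r"
"""


@pytest.fixture
def minimal_spec():
    return parse_model_spec(MINIMAL_SPEC)
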