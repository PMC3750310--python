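import pytest

from cadexpo.tables import ExposureConfig, load_default_food_table


@pytest.fixture(scope="session")
def food_records():
    return load_default_food_table()


@pytest.fixture(scope="session")
def config():
    return ExposureConfig()


@pytest.fixture(scope="session")
def records_by_name(food_records):
    return {r.food_name: r for r in food_records}
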