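import pytest

from rutfopt import as_ingredient_set, fixtures


@pytest.fixture(scope="session")
def ingredients():
    return fixtures.reference_ingredients()


@pytest.fixture(scope="session")
def ingset(ingredients):
    return as_ingredient_set(ingredients)


@pytest.fixture(scope="session")
def price_table():
    return fixtures.mali_price_table()


@pytest.fixture(scope="session")
def formulations():
    return fixtures.study_formulations()


@pytest.fixture(scope="session")
def measured():
    return fixtures.measured_products()


@pytest.fixture(scope="session")
def requirements():
    return fixtures.pregnancy_requirements()
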