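from decimal import Decimal

import pytest

from bmslca.allocation import allocated_burden, dairy_mass_balance
from bmslca.config import default_scenarios
from bmslca.production import cfp_production
from bmslca.recipe import default_ingredients

#: consumption country -> paired production country
PAIRINGS = {
    "United Kingdom": "France",
    "China": "New Zealand",
    "Brazil": "Brazil",
    "Vietnam": "France",
}

PRODUCTION_COUNTRIES = ("New Zealand", "United States", "Brazil", "France")


def assert_printed(value: float, printed: float) -> None:
    """Assert agreement with a published number at its printed precision.

    Tolerance is half a unit in the last printed digit (e.g. 7.1 -> 0.05,
    11 -> 0.5), i.e. the value would print identically.
    """
    exponent = Decimal(str(printed)).as_tuple().exponent
    tol = 0.5 * 10.0 ** exponent
    assert abs(value - printed) <= tol + 1e-12, (
        f"{value:.6g} does not round to the printed {printed}"
    )


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def ingredients():
    return default_ingredients()


@pytest.fixture(scope="session")
def baseline_tree():
    from bmslca.recipe import BASELINE_RECIPE

    return dairy_mass_balance(BASELINE_RECIPE)


@pytest.fixture(scope="session")
def baseline_burden(baseline_tree):
    return allocated_burden(baseline_tree, "dry_mass")


@pytest.fixture(scope="session")
def production_results(scenarios):
    return {name: cfp_production(scenarios[name]) for name in PRODUCTION_COUNTRIES}
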