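import pytest

from nutricea import EconParams, load_cohort_table, packaged_cohort_path


@pytest.fixture(scope="session")
def tables():
    """The packaged Zambian ART cohort, all four BMI strata."""
    return load_cohort_table(packaged_cohort_path())


@pytest.fixture(scope="session")
def severe(tables):
    """Severe-malnutrition stratum (BMI <16.0 kg/m^2)."""
    return tables["<16.0"]


@pytest.fixture(scope="session")
def econ():
    """Base-case economic parameters ($556/yr ART, $6118 lifetime, 7.3 DALYs)."""
    return EconParams()
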