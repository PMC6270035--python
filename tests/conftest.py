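import pytest

from andromass import table1_fixture
from andromass.simulate import TABLE1_COMPOUNDS


@pytest.fixture(scope="session")
def fixture_spectra():
    return table1_fixture()


@pytest.fixture(scope="session")
def fixture_types():
    """Published family assignment ('Diterpene'/'Flavone') per compound."""
    return {cid: row["type"] for cid, row in TABLE1_COMPOUNDS.items()}


FAMILY = {
    "diterpene_monomer": "Diterpene",
    "diterpene_glucoside": "Diterpene",
    "bis_diterpene": "Diterpene",
    "flavone_aglycone": "Flavone",
    "flavone_O_glycoside": "Flavone",
    "unknown": "unknown",
}
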