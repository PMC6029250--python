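import pytest

from rxnmetric import generate_fixtures, parse_molecule, parse_reaction


@pytest.fixture(scope="session")
def fixture_set():
    return generate_fixtures(seed=7, n_per_family=3)


@pytest.fixture(scope="session")
def fixture_reactions(fixture_set):
    return fixture_set.as_reactions()


@pytest.fixture
def methanol():
    return parse_molecule("[CH3:1][OH:2]")


@pytest.fixture
def ethanol():
    return parse_molecule("CCO")


@pytest.fixture
def ester_hydrolysis():
    return parse_reaction(
        "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]"
        ">>[CH3:1][C:2](=[O:3])[OH:6].[OH:4][CH3:5]",
        id="ester",
    )
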