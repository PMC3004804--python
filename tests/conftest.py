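import pytest

from cytobayes import LabelledSet, MoleculeRecord
from cytobayes import simulate


def make_record(cid, feats, **desc):
    return MoleculeRecord(id=cid, features=frozenset(feats), descriptors=desc)


@pytest.fixture
def toy_training():
    """2 actives sharing feature 1, 2 inactives sharing feature 2; feature 9
    present everywhere (uninformative)."""
    records = [
        make_record("a1", {1, 9}),
        make_record("a2", {1, 9}),
        make_record("i1", {2, 9}),
        make_record("i2", {2, 9}),
    ]
    labels = LabelledSet({"a1": True, "a2": True, "i1": False, "i2": False})
    return records, labels


@pytest.fixture(scope="session")
def universe():
    return simulate.generate_universe()


@pytest.fixture(scope="session")
def default_screen(universe):
    return simulate.default_assay(universe)


@pytest.fixture(scope="session")
def chain_panel():
    return simulate.scenario_chain(seed=0)


@pytest.fixture(scope="session")
def followup_scenario():
    return simulate.default_followup_scenario(seed=0)


@pytest.fixture(scope="session")
def panel_scenario():
    return simulate.default_panels(seed=0)
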