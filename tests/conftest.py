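import pytest

from pathdyn import FixtureSpec, make_catalogue, make_fixture, make_regime_suite


@pytest.fixture(scope="session")
def decay_fx():
    return make_fixture(FixtureSpec(motif="decay"))


@pytest.fixture(scope="session")
def reversible_fx():
    return make_fixture(FixtureSpec(motif="reversible_pair"))


@pytest.fixture(scope="session")
def cascade_fx():
    return make_fixture(FixtureSpec(motif="linear_cascade", n_tiers=3))


@pytest.fixture(scope="session")
def receptor_fx():
    return make_fixture(FixtureSpec(motif="receptor_inhibitor"))


@pytest.fixture(scope="session")
def crosstalk_fx():
    return make_fixture(FixtureSpec(motif="crosstalk_shared_phosphatase"))


@pytest.fixture(scope="session")
def receptor_suite(receptor_fx):
    return make_regime_suite(receptor_fx)


@pytest.fixture(scope="session")
def receptor_catalogue(receptor_fx):
    return make_catalogue(receptor_fx)
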