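import pytest

from pbkpred.fixtures import FixtureSpec, make_fixture, sample_pb_string
from pbkpred.pentadb import build_db
from pbkpred.scoring import build_table


@pytest.fixture(scope="session")
def world():
    """Three families of three chains (master + 100% and 70% homologues)."""
    spec = FixtureSpec(
        n_families=3,
        chains_per_family=3,
        chain_length=60,
        identity_schedule=(100.0, 70.0),
        dihedral_noise_sigma=0.0,
        seed=7,
    )
    return make_fixture(spec)


@pytest.fixture(scope="session")
def world_db(world):
    db = build_db(world.db_triples(), world.tier_table)
    yield db
    db.close()


@pytest.fixture(scope="session")
def pb_corpus(world):
    return [c.pb_truth for c in world.chains] + [
        sample_pb_string(200, seed=s) for s in range(20)
    ]


@pytest.fixture(scope="session")
def tripb_table(pb_corpus):
    return build_table(pb_corpus, 3, "odds")


@pytest.fixture(scope="session")
def pentapb_table(pb_corpus):
    return build_table(pb_corpus, 5, "odds")
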