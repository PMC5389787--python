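import pytest

from linkstore import Principal, Service
from linkstore.fixtures import FixtureConfig

VIOLATION_RATES = {
    "missing donor": 0.3,
    "inconsistent biosample term": 0.3,
    "insufficient read depth": 0.3,
}


@pytest.fixture
def service():
    """Empty in-memory service with the packaged schema set."""
    return Service()


@pytest.fixture
def loaded():
    """Service preloaded with a small seeded fixture graph and indexed."""
    svc = Service()
    svc.load_fixture(FixtureConfig(seed=1, n_experiments=5,
                                   violation_rates=VIOLATION_RATES))
    svc.reindex()
    return svc


@pytest.fixture
def admin():
    return Principal("wrangler", "admin")


@pytest.fixture
def base():
    return Principal("public", "base")


@pytest.fixture
def consortium():
    return Principal("member", "consortium", project_scope="ENCODE")


def make_submitter(service, lab_name="lab-0", project="ENCODE"):
    _, lab_uuid = service.store.resolve_identifier(lab_name)
    return Principal("submitter-0", "submitter",
                     lab_groups=frozenset([lab_uuid]),
                     project_scope=project)


def full_rebuild(service):
    """From-scratch reindex oracle: a fresh indexer over the same store."""
    from linkstore.indexing import Indexer

    indexer = Indexer(service.store, service.renderer)
    indexer.run_index_pass()
    return indexer


def assert_index_equal(incremental, rebuilt):
    """Record-for-record content equality (bodies, dependency sets, audits).

    ``indexed_tid`` legitimately differs: an incrementally maintained record
    keeps its older tid while the body is still current.
    """
    assert set(incremental.records) == set(rebuilt.records)
    for uid, record in incremental.records.items():
        other = rebuilt.records[uid]
        assert record.body == other.body, f"body mismatch for {uid}"
        assert record.embedded_uuids == other.embedded_uuids, uid
        assert record.linked_uuids == other.linked_uuids, uid
        assert record.audit == other.audit, uid
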