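import pytest

from xtalsearch.fixtures import FixtureSpec, build_fixture_db, catalog_molecules
from xtalsearch.store import Database, build_database, load_entries_tsv


@pytest.fixture(scope="session")
def catalog():
    return catalog_molecules()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default fixture set written to disk (entries TSV + SDF/CIF + manifest)."""
    out = tmp_path_factory.mktemp("fixtures")
    entries, _ = build_fixture_db(FixtureSpec(), out)
    return out, entries


@pytest.fixture(scope="session")
def fixture_db(fixture_dir, tmp_path_factory):
    out, entries = fixture_dir
    db_path = tmp_path_factory.mktemp("db") / "fixture.sqlite"
    db = build_database(load_entries_tsv(out / "entries.tsv"), db_path)
    yield db
    db.close()


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    """refcode -> FixtureEntry for ground-truth lookups."""
    _, entries = fixture_dir
    return {fe.record.refcode: fe for fe in entries}
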