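"""Embedded relational store with precomputed search artifacts.

A single-file SQLite database holds entry metadata, serialized connectivity
graphs, per-connectivity fingerprints and screens, raw + reduced cells, and
an inverted token index over the text fields (lowercased, split on
non-alphanumeric characters, positions kept for phrase queries).  Everything
derived is computed once at build time; searches only read.

The schema is documented in docs/SCHEMA.md.
"""

from __future__ import annotations

import json
import logging
import re
import sqlite3
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .cell import ReducedCell, UnitCell, niggli_reduce
from .chem import Atom, Bond, EntryRecord, MoleculeGraph, strip_hydrogens
from .fingerprint import FP_WIDTH, MAX_PATH_ATOMS, BitFingerprint, fingerprint
from .substructure import EntryScreens

__all__ = [
    "SCHEMA_VERSION",
    "TEXT_FIELDS",
    "NUMERIC_FIELDS",
    "DATE_FIELDS",
    "StoreConfig",
    "Database",
    "FieldQuery",
    "CompositeQuery",
    "build_database",
    "tokenize",
    "text_search",
    "run_composite",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

TEXT_FIELDS = (
    "authors",
    "journal",
    "compound_name",
    "synonyms",
    "habit",
    "bioactivity",
    "phase_transitions",
    "polymorphism",
)
NUMERIC_FIELDS = ("year", "volume", "first_page")
DATE_FIELDS = ("date_added", "date_modified")

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on any non-alphanumeric run, drop empties.

    Order is preserved so phrase queries can verify positions.
    """
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


@dataclass(frozen=True)
class StoreConfig:
    fingerprint_width: int = FP_WIDTH
    max_path_atoms: int = MAX_PATH_ATOMS
    strip_hydrogens: bool = True


_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE entries (
    refcode TEXT PRIMARY KEY,
    authors TEXT, journal TEXT, compound_name TEXT, synonyms TEXT,
    habit TEXT, bioactivity TEXT, phase_transitions TEXT, polymorphism TEXT,
    year INTEGER, volume INTEGER, first_page INTEGER,
    date_added TEXT, date_modified TEXT
);
CREATE TABLE connectivities (
    refcode TEXT NOT NULL REFERENCES entries(refcode),
    conn_index INTEGER NOT NULL,
    graph TEXT NOT NULL,
    PRIMARY KEY (refcode, conn_index)
);
CREATE TABLE fingerprints (
    refcode TEXT NOT NULL,
    conn_index INTEGER NOT NULL,
    fp BLOB NOT NULL,
    PRIMARY KEY (refcode, conn_index)
);
CREATE TABLE screens (
    refcode TEXT NOT NULL,
    conn_index INTEGER NOT NULL,
    elements TEXT NOT NULL,
    max_assembly INTEGER NOT NULL,
    PRIMARY KEY (refcode, conn_index)
);
CREATE TABLE cells (
    refcode TEXT PRIMARY KEY,
    a REAL, b REAL, c REAL, alpha REAL, beta REAL, gamma REAL,
    ra REAL, rb REAL, rc REAL, ralpha REAL, rbeta REAL, rgamma REAL,
    niggli_type TEXT
);
CREATE TABLE postings (
    field TEXT NOT NULL,
    token TEXT NOT NULL,
    refcode TEXT NOT NULL,
    positions TEXT NOT NULL,
    PRIMARY KEY (field, token, refcode)
);
CREATE INDEX idx_postings_token ON postings (token);
CREATE INDEX idx_entries_year ON entries (year);
CREATE INDEX idx_entries_date_added ON entries (date_added);
CREATE INDEX idx_entries_date_modified ON entries (date_modified);
"""


def _graph_to_json(mol: MoleculeGraph) -> str:
    return json.dumps(
        {
            "name": mol.name,
            "atoms": [[a.element, a.formal_charge] for a in mol.atoms],
            "bonds": [[b.a, b.b, b.order] for b in mol.bonds],
        },
        separators=(",", ":"),
        sort_keys=True,
    )


def _graph_from_json(blob: str) -> MoleculeGraph:
    data = json.loads(blob)
    atoms = [Atom(i, el, ch) for i, (el, ch) in enumerate(data["atoms"])]
    bonds = [Bond(a, b, order) for a, b, order in data["bonds"]]
    return MoleculeGraph(atoms, bonds, data.get("name", ""))


class Database:
    """Read handle over a built database file."""

    def __init__(self, connection: sqlite3.Connection):
        self._conn = connection
        self.config = StoreConfig(
            fingerprint_width=int(self._meta("fingerprint_width")),
            max_path_atoms=int(self._meta("max_path_atoms")),
            strip_hydrogens=self._meta("strip_hydrogens") == "1",
        )

    @classmethod
    def open(cls, path: Union[str, Path]) -> "Database":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"database file not found: {path}")
        conn = sqlite3.connect(str(path))
        return cls(conn)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Database":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _meta(self, key: str) -> str:
        row = self._conn.execute("SELECT value FROM meta WHERE key = ?", (key,)).fetchone()
        if row is None:
            raise KeyError(f"missing meta key {key!r}")
        return row[0]

    # ------------------------------------------------------------------
    # iteration helpers used by the search engines
    # ------------------------------------------------------------------
    def refcodes(self) -> list[str]:
        return [r for (r,) in self._conn.execute("SELECT refcode FROM entries ORDER BY refcode")]

    def n_entries(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM entries").fetchone()[0]

    def iter_fingerprints(self) -> Iterator[tuple[str, int, BitFingerprint]]:
        width = self.config.fingerprint_width
        cursor = self._conn.execute(
            "SELECT refcode, conn_index, fp FROM fingerprints ORDER BY refcode, conn_index"
        )
        for refcode, conn_index, blob in cursor:
            yield refcode, conn_index, BitFingerprint.from_bytes(blob, width)

    def iter_connectivities(self) -> Iterator[tuple[str, int, MoleculeGraph]]:
        cursor = self._conn.execute(
            "SELECT refcode, conn_index, graph FROM connectivities ORDER BY refcode, conn_index"
        )
        for refcode, conn_index, blob in cursor:
            yield refcode, conn_index, _graph_from_json(blob)

    def iter_connectivities_with_screens(
        self,
    ) -> Iterator[tuple[str, int, MoleculeGraph, EntryScreens]]:
        width = self.config.fingerprint_width
        cursor = self._conn.execute(
            """SELECT c.refcode, c.conn_index, c.graph, s.elements, s.max_assembly, f.fp
               FROM connectivities c
               JOIN screens s ON s.refcode = c.refcode AND s.conn_index = c.conn_index
               JOIN fingerprints f ON f.refcode = c.refcode AND f.conn_index = c.conn_index
               ORDER BY c.refcode, c.conn_index"""
        )
        for refcode, conn_index, graph, elements, max_assembly, blob in cursor:
            screens = EntryScreens(
                elements=Counter(json.loads(elements)),
                fingerprint=BitFingerprint.from_bytes(blob, width),
                max_assembly_size=max_assembly,
            )
            yield refcode, conn_index, _graph_from_json(graph), screens

    def iter_reduced_cells(self) -> Iterator[tuple[str, ReducedCell]]:
        cursor = self._conn.execute(
            """SELECT refcode, ra, rb, rc, ralpha, rbeta, rgamma, niggli_type
               FROM cells WHERE ra IS NOT NULL ORDER BY refcode"""
        )
        for refcode, ra, rb, rc, ralpha, rbeta, rgamma, ntype in cursor:
            yield refcode, ReducedCell(ra, rb, rc, ralpha, rbeta, rgamma, ntype)

    def entry_field(self, refcode: str, field: str) -> Optional[str]:
        if field not in TEXT_FIELDS + NUMERIC_FIELDS + DATE_FIELDS:
            raise ValueError(f"unknown field {field!r}")
        row = self._conn.execute(
            f"SELECT {field} FROM entries WHERE refcode = ?", (refcode,)
        ).fetchone()
        return None if row is None else row[0]


# ---------------------------------------------------------------------------
# Build
# ---------------------------------------------------------------------------

def build_database(
    entries: Iterable[EntryRecord],
    out_path: Union[str, Path],
    config: StoreConfig = StoreConfig(),
) -> Database:
    """Build the database file with every derived artifact precomputed.

    Raises on duplicate refcodes; entries with neither molecule nor cell are
    stored metadata-only with a warning.
    """
    out_path = Path(out_path)
    if out_path.exists():
        out_path.unlink()
    conn = sqlite3.connect(str(out_path))
    conn.executescript(_SCHEMA)
    meta = {
        "schema_version": str(SCHEMA_VERSION),
        "fingerprint_width": str(config.fingerprint_width),
        "max_path_atoms": str(config.max_path_atoms),
        "strip_hydrogens": "1" if config.strip_hydrogens else "0",
    }
    conn.executemany("INSERT INTO meta VALUES (?, ?)", sorted(meta.items()))

    seen: set[str] = set()
    # insertion order fixed by refcode for deterministic rebuilds
    for entry in sorted(entries, key=lambda e: e.refcode):
        if entry.refcode in seen:
            conn.close()
            out_path.unlink(missing_ok=True)
            raise ValueError(f"duplicate refcode {entry.refcode}")
        seen.add(entry.refcode)
        if not entry.connectivities and entry.cell is None:
            logger.warning("entry %s has neither molecule nor cell; stored metadata-only", entry.refcode)
        conn.execute(
            """INSERT INTO entries VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?)""",
            (
                entry.refcode,
                entry.authors,
                entry.journal,
                entry.compound_name,
                entry.synonyms,
                entry.habit,
                entry.bioactivity,
                entry.phase_transitions,
                entry.polymorphism,
                entry.year,
                entry.volume,
                entry.first_page,
                entry.date_added,
                entry.date_modified,
            ),
        )
        for conn_index, mol in enumerate(entry.connectivities):
            if config.strip_hydrogens:
                mol = strip_hydrogens(mol)
            fp = fingerprint(mol, config.fingerprint_width, config.max_path_atoms)
            conn.execute(
                "INSERT INTO connectivities VALUES (?,?,?)",
                (entry.refcode, conn_index, _graph_to_json(mol)),
            )
            conn.execute(
                "INSERT INTO fingerprints VALUES (?,?,?)",
                (entry.refcode, conn_index, fp.to_bytes()),
            )
            conn.execute(
                "INSERT INTO screens VALUES (?,?,?,?)",
                (
                    entry.refcode,
                    conn_index,
                    json.dumps(mol.element_counts(), sort_keys=True),
                    mol.ring_info.max_assembly_size,
                ),
            )
        if entry.cell is not None:
            cell: UnitCell = entry.cell
            reduced, _ = niggli_reduce(cell)
            conn.execute(
                "INSERT INTO cells VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                (entry.refcode, *cell.parameters(), *reduced.parameters(), reduced.niggli_type),
            )
        # inverted index with positions
        for field in TEXT_FIELDS:
            value = getattr(entry, field)
            if not value:
                continue
            positions: dict[str, list[int]] = {}
            for pos, token in enumerate(tokenize(value)):
                positions.setdefault(token, []).append(pos)
            for token in sorted(positions):
                conn.execute(
                    "INSERT INTO postings VALUES (?,?,?,?)",
                    (field, token, entry.refcode, json.dumps(positions[token])),
                )
    conn.commit()
    return Database(conn)


# ---------------------------------------------------------------------------
# Text / numeric / date search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldQuery:
    """One predicate over a single field.

    kinds:
        "term"    - token or phrase match on a text field (or "all_text")
        "defined" - text field is non-null and non-empty
        "eq"      - numeric equality
        "range"   - numeric or date range, inclusive; either bound optional
    """

    field: str
    kind: str
    value: Optional[Union[str, int]] = None
    low: Optional[Union[str, int]] = None
    high: Optional[Union[str, int]] = None

    def __post_init__(self) -> None:
        valid = TEXT_FIELDS + NUMERIC_FIELDS + DATE_FIELDS + ("all_text",)
        if self.field not in valid:
            raise ValueError(f"unknown field {self.field!r}")
        if self.kind not in ("term", "defined", "eq", "range"):
            raise ValueError(f"unknown predicate kind {self.kind!r}")
        if self.kind == "term" and self.field not in TEXT_FIELDS + ("all_text",):
            raise ValueError(f"term predicate needs a text field, got {self.field!r}")
        if self.kind in ("eq", "range") and self.field not in NUMERIC_FIELDS + DATE_FIELDS:
            raise ValueError(f"{self.kind} predicate needs a numeric/date field")


@dataclass(frozen=True)
class CompositeQuery:
    items: tuple[FieldQuery, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("composite query needs at least one item")


def _phrase_hits(db: Database, field: str, tokens: list[str]) -> set[str]:
    """Posting-list lookup; multi-token phrases verified by positions."""
    per_token: list[dict[str, list[int]]] = []
    for token in tokens:
        rows = db._conn.execute(
            "SELECT refcode, positions FROM postings WHERE field = ? AND token = ?",
            (field, token),
        ).fetchall()
        per_token.append({refcode: json.loads(positions) for refcode, positions in rows})
        if not rows:
            return set()
    if len(tokens) == 1:
        return set(per_token[0])
    shared = set(per_token[0])
    for postings in per_token[1:]:
        shared &= set(postings)
    hits = set()
    for refcode in shared:
        starts = set(per_token[0][refcode])
        for offset, postings in enumerate(per_token[1:], start=1):
            starts = {p for p in starts if p + offset in set(postings[refcode])}
            if not starts:
                break
        if starts:
            hits.add(refcode)
    return hits


def text_search(db: Database, field: str, term: str) -> set[str]:
    """Token or phrase search on one text field, or "all_text" for the union
    of all text fields.  Resolved via the inverted index."""
    if field != "all_text" and field not in TEXT_FIELDS:
        raise ValueError(f"unknown text field {field!r}")
    tokens = tokenize(term)
    if not tokens:
        return set()
    fields = TEXT_FIELDS if field == "all_text" else (field,)
    hits: set[str] = set()
    for f in fields:
        hits |= _phrase_hits(db, f, tokens)
    return hits


def _run_field_query(db: Database, item: FieldQuery) -> set[str]:
    if item.kind == "term":
        return text_search(db, item.field, str(item.value))
    if item.kind == "defined":
        rows = db._conn.execute(
            f"SELECT refcode FROM entries WHERE {item.field} IS NOT NULL AND {item.field} != ''"
        ).fetchall()
        return {r for (r,) in rows}
    if item.kind == "eq":
        rows = db._conn.execute(
            f"SELECT refcode FROM entries WHERE {item.field} = ?", (item.value,)
        ).fetchall()
        return {r for (r,) in rows}
    # range, inclusive both ends; ISO date strings compare lexicographically
    clauses, args = [f"{item.field} IS NOT NULL"], []
    if item.low is not None:
        clauses.append(f"{item.field} >= ?")
        args.append(item.low)
    if item.high is not None:
        clauses.append(f"{item.field} <= ?")
        args.append(item.high)
    rows = db._conn.execute(
        f"SELECT refcode FROM entries WHERE {' AND '.join(clauses)}", args
    ).fetchall()
    return {r for (r,) in rows}


def load_entries_tsv(path: Union[str, Path]) -> list[EntryRecord]:
    """Read build input: a UTF-8 TSV with a header row, SDF/CIF paths
    relative to the TSV's directory."""
    import csv

    from .chem import read_cif_cell, read_sdf

    path = Path(path)
    base = path.parent
    entries: list[EntryRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            def get(key: str) -> Optional[str]:
                value = (row.get(key) or "").strip()
                return value or None

            connectivities: list[MoleculeGraph] = []
            if get("sdf"):
                with open(base / row["sdf"].strip()) as sf:
                    connectivities = [mol for mol, _ in read_sdf(sf)]
            cell = None
            if get("cif"):
                with open(base / row["cif"].strip()) as cf:
                    cell = read_cif_cell(cf)
            entries.append(
                EntryRecord(
                    refcode=row["refcode"].strip(),
                    connectivities=connectivities,
                    cell=cell,
                    authors=get("authors"),
                    journal=get("journal"),
                    compound_name=get("compound_name"),
                    synonyms=get("synonyms"),
                    habit=get("habit"),
                    bioactivity=get("bioactivity"),
                    phase_transitions=get("phase_transitions"),
                    polymorphism=get("polymorphism"),
                    year=int(get("year")) if get("year") else None,
                    volume=int(get("volume")) if get("volume") else None,
                    first_page=int(get("first_page")) if get("first_page") else None,
                    date_added=get("date_added"),
                    date_modified=get("date_modified"),
                )
            )
    return entries


def run_composite(db: Database, query: CompositeQuery) -> set[str]:
    """AND-conjunction: intersection of the per-item result sets."""
    result: Optional[set[str]] = None
    for item in query.items:
        hits = _run_field_query(db, item)
        result = hits if result is None else result & hits
        if not result:
            return set()
    assert result is not None
    return result
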