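# Database schema

A built database is a single SQLite file. All derived artifacts are
precomputed at build time; searches only read. Schema version: 1.

## Tables

### `meta`
| column | type | notes |
|---|---|---|
| key | TEXT PK | `schema_version`, `fingerprint_width`, `max_path_atoms`, `strip_hydrogens` |
| value | TEXT | |

`simsearch`/`subsearch` refuse to run when the requested fingerprint
settings differ from the stored ones.

### `entries`
One row per entry. `refcode` (TEXT, primary key, uppercase) plus the text
fields `authors`, `journal`, `compound_name`, `synonyms`, `habit`,
`bioactivity`, `phase_transitions`, `polymorphism` (all nullable TEXT),
numeric fields `year`, `volume`, `first_page` (nullable INTEGER), and
`date_added`, `date_modified` (nullable TEXT, ISO-8601, so lexicographic
comparison is chronological). Indexed on `year`, `date_added`,
`date_modified`.

### `connectivities`
| column | type | notes |
|---|---|---|
| refcode | TEXT | FK to entries |
| conn_index | INTEGER | 0-based within the entry |
| graph | TEXT | JSON: `{"name", "atoms": [[element, charge], ...], "bonds": [[a, b, order], ...]}` |

Primary key `(refcode, conn_index)`. Graphs are hydrogen-suppressed unless
the database was built with `--keep-hydrogens`.

### `fingerprints`
`(refcode, conn_index)` primary key; `fp` BLOB of
`fingerprint_width / 8` bytes (255 bytes for the default 2040 bits),
little-endian bit order. One row per connectivity.

### `screens`
`(refcode, conn_index)` primary key; `elements` TEXT (JSON object mapping
element symbol to count) and `max_assembly` INTEGER (atom count of the
largest fused/linked ring assembly, 0 for acyclic).

### `cells`
One row per entry with a cell: raw parameters `a..gamma`, Niggli-reduced
parameters `ra..rgamma`, and `niggli_type` (`I` when all reduced angles are
< 90 degrees, else `II`). Lengths in Angstrom, angles in degrees.

### `postings`
Inverted text index: `(field, token, refcode)` primary key with `positions`
TEXT (JSON array of 0-based token positions within the field, enabling
phrase verification). Tokens are lowercased and split on any
non-alphanumeric character; no stemming, no stop words. Indexed on `token`.

## Determinism

Entries are inserted ordered by refcode and tokens in sorted order, so a
rebuild from the same inputs produces an identical logical dump
(`iterdump`) and identical query results.
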