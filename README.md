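# xtalsearch

Search engines for a local database of small-molecule crystal-structure
entries, built from SDF/CIF input or synthetic fixtures:

- **2D substructure search** — query compilation from an annotated linear
  notation, sound necessary-condition screens (element multiset, path
  fingerprint bits, largest ring-assembly size) and a breadth-first
  backtracking subgraph matcher with smallest-ring-size constraints.
- **Molecular similarity search** — 2040-bit path fingerprints (all bonded
  paths of up to ten atoms, element/charge/bond-order typed), scored with
  Tanimoto or Dice coefficients.
- **Text/numeric search** — tokenized inverted index over the entry text
  fields (authors, journal, compound name, synonyms, habit, bioactivity,
  phase transitions, polymorphism) plus numeric/date fields, composable
  into AND-conjunctions.
- **Reduced-cell search** — Krivy–Gruber Niggli reduction with stabilized
  comparisons and angle-aware matching through nearly-Buerger related-cell
  sets (a lengths-only mode is available for comparison and always returns
  a superset).

Everything derived (fingerprints, screens, ring info, reduced cells, token
postings) is precomputed into a single-file SQLite database at build time
(schema: `docs/SCHEMA.md`).

## CLI

```sh
# generate the synthetic fixture set (entries TSV + SDF/CIF + manifest)
xtalsearch fixtures --out fixtures/ --seed 0

# build the database (precomputes all search artifacts)
xtalsearch build --entries fixtures/entries.tsv --out db.sqlite

# similarity search (linear notation or @file.sdf queries)
xtalsearch simsearch --db db.sqlite --query "C1=CC=CC=C1" \
    --coeff tanimoto --top-k 10 --min-coeff 0.2

# substructure search
xtalsearch subsearch --db db.sqlite --query "C={ring:6-6}N" --count-matches

# reduced-cell search
xtalsearch cellsearch --db db.sqlite --cell "5.2,7.3,9.1,75,80,85" \
    --rel-length 0.01 --abs-angle 1.0
xtalsearch cellsearch --db db.sqlite --cif sample.cif --lengths-only

# text/numeric/date search with AND composition
xtalsearch textsearch --db db.sqlite --field habit --term needle \
    --and "phase_transitions:defined" --and "date_added:2020-01-01.."
```

Outputs are TSV on stdout (or `--out FILE`); progress counts go to stderr.
Exit codes: 0 success, 1 data error, 2 usage error. A TOML file passed via
`xtalsearch --config settings.toml <command>` can override defaults
(`fingerprint_width`, `max_path_atoms`, `top_k`, `rel_length`, `abs_angle`,
`log_level`).

### Query notation

Molecules use a SMILES subset: organic-subset symbols (B, C, N, O, P, S, F,
Cl, Br, I), bracket atoms with charges (`[N+]`, `[O-]`, `[Fe+2]`), bond
symbols `-` `=` `#`, branches `(...)` and ring-closure digits. Kekulé
structures only (no aromatic lowercase), hydrogen-suppressed throughout.

Substructure queries extend this with:

| syntax | meaning |
|---|---|
| `*` | wildcard atom (any element, any charge) |
| `~` | any-order bond |
| `C{charge:+1}`, `C{charge:any}` | charge constraint (bare atoms are neutral) |
| `C{ring:5-6}` / `C{ring:6}` / `C{ring:6-}` / `C{ring:-8}` | smallest-ring-size range / exact / min / max |
| `C{ring:acyclic}` | atom in no ring |
| `C={ring:6-6}C` | constraint on the bond (after the bond symbol) |

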