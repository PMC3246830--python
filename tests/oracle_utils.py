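"""Independent oracles used by the test suite.

These deliberately avoid the production code paths they check: shortest
cycles by neighbor-pair BFS with the vertex removed, lattice shortest
vectors by bounded integer enumeration, text search by linear scan.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

from xtalsearch.chem import MoleculeGraph
from xtalsearch.store import DATE_FIELDS, NUMERIC_FIELDS, TEXT_FIELDS, Database, FieldQuery, tokenize


def shortest_cycle_through_atom(mol: MoleculeGraph, v: int):
    """Min cycle length through v: for each neighbor pair (x, y), shortest
    x..y path avoiding v, plus the two incident edges."""
    best = None
    neighbors = sorted(mol.adjacency[v])
    for x, y in itertools.combinations(neighbors, 2):
        dist = {x: 0}
        queue = deque([x])
        while queue:
            u = queue.popleft()
            if u == y:
                break
            for w in mol.adjacency[u]:
                if w != v and w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        if y in dist:
            length = dist[y] + 2
            if best is None or length < best:
                best = length
    return best


def lattice_shortest_norms(metric: np.ndarray, bound: int = 3) -> list[float]:
    """Sorted norms of all nonzero lattice vectors with coefficients in
    [-bound, bound]."""
    norms = []
    rng = range(-bound, bound + 1)
    for n1, n2, n3 in itertools.product(rng, rng, rng):
        if (n1, n2, n3) == (0, 0, 0):
            continue
        v = np.array([n1, n2, n3])
        norms.append(float(np.sqrt(v @ metric @ v)))
    return sorted(norms)


def niggli_main_conditions_hold(reduced, tol: float = 1e-6) -> bool:
    """a<=b<=c and |cos| bounds of the main Niggli conditions."""
    import math

    a, b, c, alpha, beta, gamma = reduced.parameters()
    if not (a <= b + tol and b <= c + tol):
        return False
    xi = 2 * b * c * math.cos(math.radians(alpha))
    eta = 2 * a * c * math.cos(math.radians(beta))
    zeta = 2 * a * b * math.cos(math.radians(gamma))
    return (
        abs(xi) <= b * b + tol
        and abs(eta) <= a * a + tol
        and abs(zeta) <= a * a + tol
    )


def scan_entry_fields(db: Database) -> list[dict]:
    rows = db._conn.execute(
        "SELECT refcode, " + ", ".join(TEXT_FIELDS + NUMERIC_FIELDS + DATE_FIELDS) + " FROM entries"
    ).fetchall()
    keys = ("refcode",) + TEXT_FIELDS + NUMERIC_FIELDS + DATE_FIELDS
    return [dict(zip(keys, row)) for row in rows]


def linear_scan_term(db: Database, field: str, term: str) -> set[str]:
    """Full-scan equivalent of text_search (token/phrase, all_text union)."""
    wanted = tokenize(term)
    fields = TEXT_FIELDS if field == "all_text" else (field,)
    hits = set()
    for row in scan_entry_fields(db):
        for f in fields:
            value = row[f]
            if not value:
                continue
            tokens = tokenize(value)
            for start in range(len(tokens) - len(wanted) + 1):
                if tokens[start : start + len(wanted)] == wanted:
                    hits.add(row["refcode"])
                    break
    return hits


def linear_scan_query(db: Database, item: FieldQuery) -> set[str]:
    """Full-scan equivalent of a single FieldQuery."""
    if item.kind == "term":
        return linear_scan_term(db, item.field, str(item.value))
    hits = set()
    for row in scan_entry_fields(db):
        value = row[item.field]
        if item.kind == "defined":
            if value is not None and value != "":
                hits.add(row["refcode"])
        elif item.kind == "eq":
            if value == item.value:
                hits.add(row["refcode"])
        else:  # range
            if value is None:
                continue
            if item.low is not None and value < item.low:
                continue
            if item.high is not None and value > item.high:
                continue
            hits.add(row["refcode"])
    return hits
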