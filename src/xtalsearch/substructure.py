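"""2D substructure search.

Pipeline: compile an annotated linear-notation query into a query graph plus
necessary-condition screens (element multiset, definite path-feature bits,
largest ring-assembly size); screen out connectivities that cannot match;
then run a breadth-first backtracking subgraph matcher (monomorphism with
per-atom/per-bond predicates, most-constrained-first assignment).

Query annotation syntax (on top of the linear notation):
    *                wildcard atom (any element, any charge)
    ~                any-order bond
    X{charge:+1}     formal-charge constraint (bare atoms are neutral)
    X{ring:5-6}      smallest ring containing the atom within [5, 6]
    X{ring:6}        smallest ring exactly 6;  {ring:6-} min;  {ring:-8} max
    X{ring:acyclic}  atom must not lie in any ring
Bond annotations follow the bond symbol, e.g. "C={ring:6-6}C" constrains
the double bond to lie in a six-membered ring (write the single-bond symbol
explicitly to annotate a single bond: "C-{ring:acyclic}C").
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .chem import MoleculeGraph, PERIODIC_TABLE, ParseError, _tokenize_notation
from .fingerprint import BitFingerprint, FP_WIDTH, MAX_PATH_ATOMS, _canonical_feature, atom_token, bond_token, feature_bit

__all__ = [
    "QueryAtom",
    "QueryBond",
    "SubstructureQuery",
    "MatchResult",
    "compile_query",
    "screen_pass",
    "match",
    "substructure_search",
]

logger = logging.getLogger(__name__)


@dataclass
class RingConstraint:
    """Constraint on the smallest ring containing an atom or bond."""

    acyclic: bool = False
    min: Optional[int] = None
    max: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min is not None and self.min < 3:
            raise ValueError("ring size minimum must be >= 3")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError(f"contradictory ring constraint: min {self.min} > max {self.max}")

    def accepts(self, smallest_ring_size: Optional[int]) -> bool:
        if self.acyclic:
            return smallest_ring_size is None
        if self.min is None and self.max is None:
            return True
        if smallest_ring_size is None:
            return False
        if self.min is not None and smallest_ring_size < self.min:
            return False
        if self.max is not None and smallest_ring_size > self.max:
            return False
        return True

    @property
    def is_trivial(self) -> bool:
        return not self.acyclic and self.min is None and self.max is None


def _parse_ring_annotation(value: str) -> RingConstraint:
    value = value.strip()
    if value == "acyclic":
        return RingConstraint(acyclic=True)
    if "-" in value:
        lo, _, hi = value.partition("-")
        return RingConstraint(
            min=int(lo) if lo.strip() else None,
            max=int(hi) if hi.strip() else None,
        )
    exact = int(value)
    return RingConstraint(min=exact, max=exact)


@dataclass
class QueryAtom:
    index: int
    element: Optional[str]  # None = wildcard
    charge: Optional[int]  # None = unconstrained
    ring: RingConstraint = field(default_factory=RingConstraint)


@dataclass
class QueryBond:
    a: int
    b: int
    order: Optional[int]  # None = any
    ring: RingConstraint = field(default_factory=RingConstraint)


@dataclass
class EntryScreens:
    """Precomputed per-connectivity screen data."""

    elements: Counter
    fingerprint: BitFingerprint
    max_assembly_size: int


class SubstructureQuery:
    """Compiled query graph with derived screens."""

    def __init__(
        self,
        atoms: list[QueryAtom],
        bonds: list[QueryBond],
        width: int = FP_WIDTH,
        max_path_atoms: int = MAX_PATH_ATOMS,
    ):
        self.atoms = atoms
        self.bonds = bonds
        self.adjacency: list[dict[int, QueryBond]] = [dict() for _ in atoms]
        for bond in bonds:
            self.adjacency[bond.a][bond.b] = bond
            self.adjacency[bond.b][bond.a] = bond
        self._check_connected()
        # --- screens, all derived at compile time ---
        self.element_screen = Counter(a.element for a in atoms if a.element is not None)
        self.feature_bits = self._definite_feature_bits(width, max_path_atoms)
        struct = self._structural_graph()
        self.has_ring = struct.n_bonds >= struct.n_atoms
        self.max_assembly_size = struct.ring_info.max_assembly_size if self.has_ring else 0
        self._struct = struct

    def _check_connected(self) -> None:
        if not self.atoms:
            raise ParseError("empty query")
        seen = {0}
        frontier = [0]
        while frontier:
            u = frontier.pop()
            for v in self.adjacency[u]:
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        if len(seen) != len(self.atoms):
            raise ParseError("disconnected query (single-fragment queries only)")

    def _structural_graph(self) -> MoleculeGraph:
        """Plain graph with query structure, for ring analysis only."""
        from .chem import Atom, Bond

        atoms = [Atom(i, "C", 0) for i in range(len(self.atoms))]
        bonds = [Bond(b.a, b.b, 1) for b in self.bonds]
        return MoleculeGraph(atoms, bonds, "query")

    def _definite_feature_bits(self, width: int, max_path_atoms: int) -> BitFingerprint:
        """Bits of path features whose atoms are all non-wildcard with fixed
        charge and whose bonds all have definite order.  Any true match must
        set all of these bits, so they form a sound screen."""
        definite_atom = [
            a.element is not None and a.charge is not None for a in self.atoms
        ]
        tokens_of = [
            atom_token(a.element, a.charge) if definite_atom[i] else None
            for i, a in enumerate(self.atoms)
        ]
        features: set[str] = {t for t in tokens_of if t is not None}

        def extend(path: list[int], tokens: list[str], visited: set[int]) -> None:
            tip = path[-1]
            for nxt, bond in self.adjacency[tip].items():
                if nxt in visited or not definite_atom[nxt] or bond.order is None:
                    continue
                tokens.append(bond_token(bond.order))
                tokens.append(tokens_of[nxt])
                features.add(_canonical_feature(tokens))
                if len(path) + 1 < max_path_atoms:
                    path.append(nxt)
                    visited.add(nxt)
                    extend(path, tokens, visited)
                    visited.remove(nxt)
                    path.pop()
                tokens.pop()
                tokens.pop()

        for start in range(len(self.atoms)):
            if definite_atom[start]:
                extend([start], [tokens_of[start]], {start})
        return BitFingerprint.from_features(features, width)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class MatchResult:
    refcode: str
    conn_index: int
    mappings: list[tuple[int, ...]]  # query atom i -> mapping[i] target atom

    @property
    def n_mappings(self) -> int:
        return len(self.mappings)


def compile_query(
    spec: str, width: int = FP_WIDTH, max_path_atoms: int = MAX_PATH_ATOMS
) -> SubstructureQuery:
    """Compile annotated linear notation into a SubstructureQuery."""
    raw_atoms, raw_bonds = _tokenize_notation(spec, allow_query=True)
    atoms: list[QueryAtom] = []
    for i, raw in enumerate(raw_atoms):
        charge = raw.charge
        ring = RingConstraint()
        for key, value in raw.annotations.items():
            if key == "ring":
                try:
                    ring = _parse_ring_annotation(value)
                except ValueError as exc:
                    raise ParseError(f"bad ring annotation {{ring:{value}}}: {exc}")
            elif key == "charge":
                if value == "any":
                    charge = None
                else:
                    try:
                        charge = int(value)
                    except ValueError:
                        raise ParseError(f"bad charge annotation {{charge:{value}}}")
            else:
                raise ParseError(f"unknown annotation key {key!r}")
        if raw.element is not None and raw.element not in PERIODIC_TABLE:
            raise ParseError(f"unknown element symbol {raw.element!r}")
        atoms.append(QueryAtom(i, raw.element, charge, ring))
    bonds: list[QueryBond] = []
    for raw in raw_bonds:
        ring = RingConstraint()
        for key, value in raw.annotations.items():
            if key == "ring":
                try:
                    ring = _parse_ring_annotation(value)
                except ValueError as exc:
                    raise ParseError(f"bad ring annotation {{ring:{value}}}: {exc}")
            else:
                raise ParseError(f"unknown bond annotation key {key!r}")
        bonds.append(QueryBond(raw.a, raw.b, raw.order, ring))
    return SubstructureQuery(atoms, bonds, width, max_path_atoms)


def screen_pass(query: SubstructureQuery, screens: EntryScreens) -> bool:
    """Sound necessary condition: False only if no match can possibly exist."""
    for element, needed in query.element_screen.items():
        if screens.elements.get(element, 0) < needed:
            return False
    if not screens.fingerprint.contains(query.feature_bits):
        return False
    if query.has_ring and query.max_assembly_size > screens.max_assembly_size:
        return False
    return True


def entry_screens_for(mol: MoleculeGraph, fp: BitFingerprint) -> EntryScreens:
    """Build the per-connectivity screen record (used at db build time)."""
    return EntryScreens(
        elements=Counter(mol.element_counts()),
        fingerprint=fp,
        max_assembly_size=mol.ring_info.max_assembly_size,
    )


def _atom_compatible(qa: QueryAtom, mol: MoleculeGraph, t: int) -> bool:
    atom = mol.atoms[t]
    if qa.element is not None and atom.element != qa.element:
        return False
    if qa.charge is not None and atom.formal_charge != qa.charge:
        return False
    return qa.ring.accepts(atom.smallest_ring_size)


def _bond_compatible(qb: QueryBond, mol: MoleculeGraph, ta: int, tb: int) -> bool:
    bond = mol.bond_between(ta, tb)
    if bond is None:
        return False
    if qb.order is not None and bond.order != qb.order:
        return False
    return qb.ring.accepts(bond.smallest_ring_size)


def match(
    query: SubstructureQuery, mol: MoleculeGraph, find_all: bool = True
) -> list[tuple[int, ...]]:
    """Breadth-first candidate-list subgraph matching (monomorphism).

    Initial candidate lists are filtered by element/charge/degree/ring
    predicates, then iteratively refined: a candidate survives only while
    every neighboring query atom retains a compatible adjacent candidate.
    Assignment is backtracking, most-constrained query atom first.
    """
    mol.ring_info  # ensure smallest-ring sizes are populated
    nq = query.n_atoms
    if nq > mol.n_atoms:
        return []

    candidates: list[set[int]] = []
    for qa in query.atoms:
        qdeg = len(query.adjacency[qa.index])
        cands = {
            t
            for t in range(mol.n_atoms)
            if mol.atoms[t].degree >= qdeg and _atom_compatible(qa, mol, t)
        }
        if not cands:
            return []
        candidates.append(cands)

    # breadth-first refinement to a fixpoint
    changed = True
    while changed:
        changed = False
        for qi in range(nq):
            doomed: list[int] = []
            for t in candidates[qi]:
                for qj, qbond in query.adjacency[qi].items():
                    if not any(
                        u != t and _bond_compatible(qbond, mol, t, u)
                        for u in candidates[qj]
                        if mol.bond_between(t, u) is not None
                    ):
                        doomed.append(t)
                        break
            if doomed:
                candidates[qi].difference_update(doomed)
                if not candidates[qi]:
                    return []
                changed = True

    order = sorted(range(nq), key=lambda qi: (len(candidates[qi]), qi))
    position = {qi: k for k, qi in enumerate(order)}
    mappings: list[tuple[int, ...]] = []
    assignment: dict[int, int] = {}
    used: set[int] = set()

    def backtrack(level: int) -> bool:
        if level == nq:
            mapping = tuple(assignment[qi] for qi in range(nq))
            mappings.append(mapping)
            return not find_all
        qi = order[level]
        for t in sorted(candidates[qi]):
            if t in used:
                continue
            ok = True
            for qj, qbond in query.adjacency[qi].items():
                if position[qj] < level and not _bond_compatible(qbond, mol, t, assignment[qj]):
                    ok = False
                    break
            if not ok:
                continue
            assignment[qi] = t
            used.add(t)
            if backtrack(level + 1):
                return True
            used.discard(t)
            del assignment[qi]
        return False

    backtrack(0)
    return mappings


def substructure_search(
    query: SubstructureQuery,
    db,
    find_all: bool = True,
    use_screens: bool = True,
) -> list[MatchResult]:
    """Screen then match every connectivity in the database.

    Disabling screens never changes the hit set, only the amount of graph
    matching performed.  Results are ordered by refcode then connectivity.
    """
    results: list[MatchResult] = []
    n_screened_out = 0
    n_matched = 0
    n_total = 0
    for refcode, conn_index, mol, screens in db.iter_connectivities_with_screens():
        n_total += 1
        if use_screens and not screen_pass(query, screens):
            n_screened_out += 1
            continue
        mappings = match(query, mol, find_all=find_all)
        if mappings:
            n_matched += 1
            results.append(MatchResult(refcode, conn_index, mappings))
    logger.info(
        "substructure search: %d connectivities, %d screened out, %d matched",
        n_total,
        n_screened_out,
        n_matched,
    )
    results.sort(key=lambda r: (r.refcode, r.conn_index))
    return results
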