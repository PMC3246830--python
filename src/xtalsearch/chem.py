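"""Chemical data model: molecule graphs, ring perception, and file readers.

Molecules are hydrogen-suppressed simple graphs with typed atoms (element,
formal charge) and typed bonds (order 1-3).  Ring perception provides a
deterministic smallest set of smallest rings (SSSR), per-atom/per-bond
smallest-ring sizes, and fused-ring assemblies.

Readers: V2000 SDF/MOL (plus a writer for fixtures), a linear notation
(SMILES subset, Kekulé only), and minimal CIF cell extraction.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

__all__ = [
    "Atom",
    "Bond",
    "MoleculeGraph",
    "RingInfo",
    "EntryRecord",
    "ParseError",
    "PERIODIC_TABLE",
    "read_sdf",
    "write_sdf",
    "parse_linear",
    "read_cif_cell",
    "compute_ring_info",
    "strip_hydrogens",
]

# IUPAC element symbols, H through Og.
PERIODIC_TABLE = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


class ParseError(ValueError):
    """Raised for malformed molecule/CIF input; carries a location."""

    def __init__(self, message: str, line: Optional[int] = None, offset: Optional[int] = None):
        loc = ""
        if line is not None:
            loc = f" (line {line})"
        elif offset is not None:
            loc = f" (offset {offset})"
        super().__init__(message + loc)
        self.line = line
        self.offset = offset


@dataclass
class Atom:
    index: int
    element: str
    formal_charge: int = 0
    degree: int = 0  # derived
    smallest_ring_size: Optional[int] = None  # derived

    def __post_init__(self) -> None:
        if self.element not in PERIODIC_TABLE:
            raise ParseError(f"unknown element symbol {self.element!r}")


@dataclass
class Bond:
    a: int
    b: int
    order: int  # 1, 2 or 3
    smallest_ring_size: Optional[int] = None  # derived

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("bond endpoints must differ")
        if self.order not in (1, 2, 3):
            raise ValueError(f"bond order must be 1, 2 or 3, got {self.order}")

    @property
    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class RingInfo:
    rings: list[tuple[int, ...]]
    assemblies: list[frozenset[int]]  # atom sets of fused/linked ring systems
    atom_ring_size: list[Optional[int]]
    bond_ring_size: list[Optional[int]]

    @property
    def max_assembly_size(self) -> int:
        return max((len(a) for a in self.assemblies), default=0)


class MoleculeGraph:
    """A connected, simple, undirected chemical graph.

    Atom order is meaningful (indices are stable); ring information is
    computed on demand and cached.
    """

    def __init__(self, atoms: Iterable[Atom], bonds: Iterable[Bond], name: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.bonds: list[Bond] = list(bonds)
        self.name = name
        self._ring_info: Optional[RingInfo] = None
        n = len(self.atoms)
        seen_pairs: set[tuple[int, int]] = set()
        self.adjacency: list[dict[int, Bond]] = [dict() for _ in range(n)]
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(f"bond endpoint out of range: {bond.a}-{bond.b}")
            if bond.key in seen_pairs:
                raise ValueError(f"duplicate bond {bond.key}")
            seen_pairs.add(bond.key)
            self.adjacency[bond.a][bond.b] = bond
            self.adjacency[bond.b][bond.a] = bond
        for i, atom in enumerate(self.atoms):
            atom.index = i
            atom.degree = len(self.adjacency[i])
        if n > 1 and not self._is_connected():
            raise ValueError("MoleculeGraph must be connected (split components first)")

    def _is_connected(self) -> bool:
        if not self.atoms:
            return True
        seen = {0}
        queue = deque([0])
        while queue:
            u = queue.popleft()
            for v in self.adjacency[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return len(seen) == len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self.adjacency[i])

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        return self.adjacency[i].get(j)

    @property
    def ring_info(self) -> RingInfo:
        if self._ring_info is None:
            self._ring_info = compute_ring_info(self)
        return self._ring_info

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for atom in self.atoms:
            counts[atom.element] = counts.get(atom.element, 0) + 1
        return counts

    def __repr__(self) -> str:  # pragma: no cover
        return f"MoleculeGraph({self.name or 'unnamed'}: {self.n_atoms} atoms, {self.n_bonds} bonds)"


@dataclass
class EntryRecord:
    """One database entry: identifier, structures and searchable metadata."""

    refcode: str
    connectivities: list[MoleculeGraph] = field(default_factory=list)
    cell: Optional["object"] = None  # UnitCell; typed loosely to avoid a cycle
    authors: Optional[str] = None
    journal: Optional[str] = None
    compound_name: Optional[str] = None
    synonyms: Optional[str] = None
    habit: Optional[str] = None
    bioactivity: Optional[str] = None
    phase_transitions: Optional[str] = None
    polymorphism: Optional[str] = None
    year: Optional[int] = None
    volume: Optional[int] = None
    first_page: Optional[int] = None
    date_added: Optional[str] = None  # ISO-8601
    date_modified: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.refcode:
            raise ValueError("refcode must be non-empty")
        self.refcode = self.refcode.upper()


# ---------------------------------------------------------------------------
# Ring perception
# ---------------------------------------------------------------------------

def _shortest_cycle_through_bond(mol: MoleculeGraph, bond: Bond) -> Optional[int]:
    """Length (atom count) of the shortest cycle containing *bond*, by BFS
    from one endpoint to the other with the bond itself removed."""
    a, b = bond.a, bond.b
    dist = {a: 0}
    queue = deque([a])
    while queue:
        u = queue.popleft()
        for v in mol.adjacency[u]:
            if u == a and v == b:
                continue  # the removed bond
            if v not in dist:
                dist[v] = dist[u] + 1
                if v == b:
                    return dist[v] + 1
                queue.append(v)
    return None


def _bfs_tree(mol: MoleculeGraph, root: int) -> tuple[dict[int, int], dict[int, int]]:
    """Deterministic BFS (ascending neighbor order): distances and parents."""
    dist = {root: 0}
    parent = {root: -1}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in sorted(mol.adjacency[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                queue.append(v)
    return dist, parent


def _path_to_root(parent: dict[int, int], v: int) -> list[int]:
    path = [v]
    while parent[path[-1]] != -1:
        path.append(parent[path[-1]])
    return path


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    """Canonical rotation/reflection: start at min atom, smaller direction."""
    n = len(cycle)
    i = cycle.index(min(cycle))
    fwd = tuple(cycle[(i + k) % n] for k in range(n))
    rev = tuple(cycle[(i - k) % n] for k in range(n))
    return min(fwd, rev)


def compute_ring_info(mol: MoleculeGraph) -> RingInfo:
    """Ring perception: deterministic SSSR, smallest-ring sizes, assemblies.

    SSSR candidates come from the Horton set (shortest cycles through every
    (vertex, edge) pair), sorted by (size, atom tuple) and greedily selected
    under GF(2) independence of their edge-incidence vectors.  Per-bond
    smallest ring sizes are computed independently by BFS per bond.
    """
    n_rings_needed = mol.n_bonds - mol.n_atoms + 1 if mol.n_atoms else 0
    bond_index = {bond.key: k for k, bond in enumerate(mol.bonds)}

    bond_ring_size: list[Optional[int]] = [
        _shortest_cycle_through_bond(mol, bond) for bond in mol.bonds
    ]
    atom_ring_size: list[Optional[int]] = [None] * mol.n_atoms
    for bond, size in zip(mol.bonds, bond_ring_size):
        for endpoint in (bond.a, bond.b):
            current = atom_ring_size[endpoint]
            if size is not None and (current is None or size < current):
                atom_ring_size[endpoint] = size

    rings: list[tuple[int, ...]] = []
    if n_rings_needed > 0:
        # Horton candidate set.
        candidates: set[tuple[int, ...]] = set()
        trees = {v: _bfs_tree(mol, v) for v in range(mol.n_atoms)}
        for v in range(mol.n_atoms):
            dist, parent = trees[v]
            for bond in mol.bonds:
                x, y = bond.a, bond.b
                if x not in dist or y not in dist:
                    continue
                px = _path_to_root(parent, x)
                py = _path_to_root(parent, y)
                if set(px) & set(py) != {v}:
                    continue  # paths must meet only at v
                cycle = px[::-1] + py[:-1]
                # cycle: v..x, then y..(child of v); edge x-y closes it
                if len(cycle) < 3 or len(set(cycle)) != len(cycle):
                    continue
                candidates.add(_canonical_cycle(cycle))

        def edge_mask(cycle: tuple[int, ...]) -> int:
            mask = 0
            for i, a in enumerate(cycle):
                b = cycle[(i + 1) % len(cycle)]
                key = (a, b) if a < b else (b, a)
                k = bond_index.get(key)
                if k is None:
                    return -1
                mask |= 1 << k
            return mask

        ordered = sorted(candidates, key=lambda c: (len(c), c))
        basis: list[int] = []
        for cycle in ordered:
            mask = edge_mask(cycle)
            if mask < 0:
                continue
            residue = mask
            for b in basis:
                residue = min(residue, residue ^ b)
            if residue:
                basis.append(mask)
                basis.sort(reverse=True)
                rings.append(cycle)
                if len(rings) == n_rings_needed:
                    break
        if len(rings) != n_rings_needed:  # pragma: no cover - Horton set spans
            raise RuntimeError("ring perception failed to span the cycle space")

    # Assemblies: rings sharing at least one atom are fused/linked together.
    parent_of = list(range(len(rings)))

    def find(i: int) -> int:
        while parent_of[i] != i:
            parent_of[i] = parent_of[parent_of[i]]
            i = parent_of[i]
        return i

    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if set(rings[i]) & set(rings[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent_of[ri] = rj
    groups: dict[int, set[int]] = {}
    for i, ring in enumerate(rings):
        groups.setdefault(find(i), set()).update(ring)
    assemblies = sorted((frozenset(g) for g in groups.values()), key=lambda s: (len(s), sorted(s)))

    for atom, size in zip(mol.atoms, atom_ring_size):
        atom.smallest_ring_size = size
    for bond, size in zip(mol.bonds, bond_ring_size):
        bond.smallest_ring_size = size
    return RingInfo(rings, assemblies, atom_ring_size, bond_ring_size)


# ---------------------------------------------------------------------------
# Component splitting / hydrogen suppression
# ---------------------------------------------------------------------------

def _split_components(atoms: list[Atom], bonds: list[Bond], name: str) -> list[MoleculeGraph]:
    n = len(atoms)
    adj: list[list[int]] = [[] for _ in range(n)]
    for bond in bonds:
        adj[bond.a].append(bond.b)
        adj[bond.b].append(bond.a)
    seen: set[int] = set()
    components: list[list[int]] = []
    for start in range(n):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    queue.append(v)
        components.append(sorted(comp))
    result = []
    for ci, comp in enumerate(components):
        remap = {old: new for new, old in enumerate(comp)}
        comp_atoms = [
            Atom(remap[i], atoms[i].element, atoms[i].formal_charge) for i in comp
        ]
        comp_bonds = [
            Bond(remap[b.a], remap[b.b], b.order)
            for b in bonds
            if b.a in remap and b.b in remap
        ]
        comp_name = name if len(components) == 1 else f"{name}.{ci + 1}"
        result.append(MoleculeGraph(comp_atoms, comp_bonds, comp_name))
    return result


def strip_hydrogens(mol: MoleculeGraph) -> MoleculeGraph:
    """Remove terminal explicit hydrogens (degree <= 1, neutral).

    Returns *mol* unchanged if nothing is removable or if the whole molecule
    is hydrogen (H2 and bare H are kept as read).
    """
    drop = {
        a.index
        for a in mol.atoms
        if a.element == "H" and a.degree <= 1 and a.formal_charge == 0
    }
    if not drop or len(drop) == len(mol.atoms):
        return mol
    keep = [a for a in mol.atoms if a.index not in drop]
    remap = {a.index: i for i, a in enumerate(keep)}
    atoms = [Atom(remap[a.index], a.element, a.formal_charge) for a in keep]
    bonds = [
        Bond(remap[b.a], remap[b.b], b.order)
        for b in mol.bonds
        if b.a not in drop and b.b not in drop
    ]
    return MoleculeGraph(atoms, bonds, mol.name)


# ---------------------------------------------------------------------------
# SDF / MOL V2000
# ---------------------------------------------------------------------------

def read_sdf(stream: IO[str]) -> list[tuple[MoleculeGraph, dict[str, str]]]:
    """Read V2000 SDF records; one (connectivity, properties) pair per
    connected component, components of the same record sharing properties."""
    results: list[tuple[MoleculeGraph, dict[str, str]]] = []
    lines = stream.read().splitlines()
    pos = 0
    while pos < len(lines):
        # skip blank padding between records
        while pos < len(lines) and not lines[pos].strip():
            pos += 1
        if pos >= len(lines):
            break
        record_start = pos
        end = pos
        while end < len(lines) and lines[end].strip() != "$$$$":
            end += 1
        record = lines[record_start:end]
        pos = end + 1
        if not any(line.strip() for line in record):
            continue
        results.extend(_parse_mol_record(record, record_start))
    return results


def _parse_mol_record(
    record: list[str], base_line: int
) -> list[tuple[MoleculeGraph, dict[str, str]]]:
    if len(record) < 4:
        raise ParseError("truncated MOL record", line=base_line + 1)
    name = record[0].strip()
    counts_line = record[3]
    counts_lineno = base_line + 4
    try:
        n_atoms = int(counts_line[0:3])
        n_bonds = int(counts_line[3:6])
    except (ValueError, IndexError):
        raise ParseError(f"malformed counts line {counts_line!r}", line=counts_lineno)
    if n_atoms < 0 or n_bonds < 0:
        raise ParseError(f"malformed counts line {counts_line!r}", line=counts_lineno)

    atom_lines = record[4 : 4 + n_atoms]
    bond_lines = record[4 + n_atoms : 4 + n_atoms + n_bonds]
    if len(atom_lines) != n_atoms or len(bond_lines) != n_bonds:
        raise ParseError("record shorter than counts line promises", line=counts_lineno)

    atoms: list[Atom] = []
    for i, line in enumerate(atom_lines):
        lineno = base_line + 5 + i
        element = line[31:34].strip()
        if not element:
            parts = line.split()
            if len(parts) >= 4:
                element = parts[3]
        if element not in PERIODIC_TABLE:
            raise ParseError(f"unknown element symbol {element!r}", line=lineno)
        atoms.append(Atom(i, element, 0))

    bonds: list[Bond] = []
    for i, line in enumerate(bond_lines):
        lineno = base_line + 5 + n_atoms + i
        try:
            a = int(line[0:3])
            b = int(line[3:6])
            order = int(line[6:9])
        except (ValueError, IndexError):
            raise ParseError(f"malformed bond line {line!r}", line=lineno)
        if not (1 <= a <= n_atoms) or not (1 <= b <= n_atoms):
            raise ParseError(
                f"bond references atom {max(a, b)} of {n_atoms}", line=lineno
            )
        if order not in (1, 2, 3):
            raise ParseError(f"unsupported bond order {order}", line=lineno)
        bonds.append(Bond(a - 1, b - 1, order))

    idx = 4 + n_atoms + n_bonds
    properties: dict[str, str] = {}
    while idx < len(record):
        line = record[idx]
        if line.startswith("M  CHG"):
            fields = line.split()
            try:
                count = int(fields[2])
                pairs = [(int(fields[3 + 2 * k]), int(fields[4 + 2 * k])) for k in range(count)]
            except (ValueError, IndexError):
                raise ParseError(f"malformed M CHG line {line!r}", line=base_line + idx + 1)
            for atom_no, charge in pairs:
                if not (1 <= atom_no <= n_atoms):
                    raise ParseError(
                        f"M CHG references atom {atom_no} of {n_atoms}",
                        line=base_line + idx + 1,
                    )
                atoms[atom_no - 1].formal_charge = charge
        elif line.startswith("M  END"):
            idx += 1
            break
        idx += 1

    # data items: > <tag> followed by value lines until a blank line
    while idx < len(record):
        line = record[idx]
        if line.startswith(">"):
            m = re.search(r"<([^>]+)>", line)
            tag = m.group(1) if m else line.lstrip("> ").strip()
            values = []
            idx += 1
            while idx < len(record) and record[idx].strip():
                values.append(record[idx])
                idx += 1
            properties[tag] = "\n".join(values)
        else:
            idx += 1

    mols = _split_components(atoms, bonds, name)
    return [(mol, properties) for mol in mols]


def write_sdf(
    records: Iterable[tuple[MoleculeGraph, dict[str, str]]], stream: IO[str]
) -> None:
    """Write V2000 SDF (zero coordinates; charges as M CHG). Fixture-quality
    writer that round-trips everything read_sdf reads."""
    for mol, properties in records:
        stream.write(f"{mol.name}\n  xtalsearch\n\n")
        stream.write(f"{mol.n_atoms:3d}{mol.n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000\n")
        for atom in mol.atoms:
            stream.write(
                f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {atom.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0\n"
            )
        for bond in mol.bonds:
            stream.write(f"{bond.a + 1:3d}{bond.b + 1:3d}{bond.order:3d}  0\n")
        charged = [a for a in mol.atoms if a.formal_charge]
        for start in range(0, len(charged), 8):
            chunk = charged[start : start + 8]
            parts = "".join(f" {a.index + 1:3d} {a.formal_charge:3d}" for a in chunk)
            stream.write(f"M  CHG{len(chunk):3d}{parts}\n")
        stream.write("M  END\n")
        for tag, value in properties.items():
            stream.write(f"> <{tag}>\n{value}\n\n")
        stream.write("$$$$\n")


# ---------------------------------------------------------------------------
# Linear notation (SMILES subset)
# ---------------------------------------------------------------------------

_ORGANIC_SUBSET = ("Cl", "Br", "B", "C", "N", "O", "P", "S", "F", "I")
_BOND_ORDERS = {"-": 1, "=": 2, "#": 3}


@dataclass
class _RawAtom:
    element: Optional[str]  # None for wildcard '*'
    charge: Optional[int]  # None = unconstrained (wildcard atoms only)
    annotations: dict[str, str] = field(default_factory=dict)


@dataclass
class _RawBond:
    a: int
    b: int
    order: Optional[int]  # None = any-order '~'
    annotations: dict[str, str] = field(default_factory=dict)


def _tokenize_notation(s: str, allow_query: bool) -> tuple[list[_RawAtom], list[_RawBond]]:
    atoms: list[_RawAtom] = []
    bonds: list[_RawBond] = []
    bond_pairs: set[tuple[int, int]] = set()
    stack: list[int] = []
    prev: Optional[int] = None
    pending_order: Optional[int] = 1  # 1 unless a bond symbol intervenes
    pending_any = False
    pending_bond_ann: dict[str, str] = {}
    ring_open: dict[str, tuple[int, Optional[int], bool]] = {}
    i = 0

    def add_bond(a: int, b: int, order: Optional[int], offset: int) -> _RawBond:
        nonlocal pending_bond_ann
        if a == b:
            raise ParseError("ring closure to same atom", offset=offset)
        key = (min(a, b), max(a, b))
        if key in bond_pairs:
            raise ParseError("duplicate bond", offset=offset)
        bond_pairs.add(key)
        bond = _RawBond(a, b, order, pending_bond_ann)
        pending_bond_ann = {}
        bonds.append(bond)
        return bond

    def read_annotations(i: int, target: dict[str, str]) -> int:
        while i < len(s) and s[i] == "{":
            if not allow_query:
                raise ParseError("constraint annotations are query-only", offset=i)
            end = s.find("}", i)
            if end < 0:
                raise ParseError("unterminated '{' annotation", offset=i)
            body = s[i + 1 : end]
            if ":" not in body:
                raise ParseError(f"malformed annotation {{{body}}}", offset=i)
            key, _, value = body.partition(":")
            target[key.strip()] = value.strip()
            i = end + 1
        return i

    while i < len(s):
        ch = s[i]
        if ch.isspace():
            i += 1
            continue
        if ch in _BOND_ORDERS:
            pending_order = _BOND_ORDERS[ch]
            i = read_annotations(i + 1, pending_bond_ann)
            continue
        if ch == "~":
            if not allow_query:
                raise ParseError("'~' any-order bond is query-only", offset=i)
            pending_order = None
            pending_any = True
            i = read_annotations(i + 1, pending_bond_ann)
            continue
        if ch == "(":
            if prev is None:
                raise ParseError("branch before any atom", offset=i)
            stack.append(prev)
            i += 1
            continue
        if ch == ")":
            if not stack:
                raise ParseError("unmatched ')'", offset=i)
            prev = stack.pop()
            i += 1
            continue
        if ch.isdigit():
            if prev is None:
                raise ParseError("ring closure digit before any atom", offset=i)
            order = pending_order if (pending_any or pending_order != 1) else 1
            explicit = pending_any or pending_order != 1
            if ch in ring_open:
                open_atom, open_order, open_explicit = ring_open.pop(ch)
                if explicit and open_explicit and order != open_order:
                    raise ParseError("conflicting ring-closure bond orders", offset=i)
                final = order if explicit else (open_order if open_explicit else 1)
                add_bond(open_atom, prev, final, i)
            else:
                ring_open[ch] = (prev, order, explicit)
            pending_order, pending_any = 1, False
            i += 1
            continue
        if ch == "*":
            if not allow_query:
                raise ParseError("'*' wildcard atom is query-only", offset=i)
            atom = _RawAtom(None, None)
            i += 1
            i = read_annotations(i, atom.annotations)
            atoms.append(atom)
            idx = len(atoms) - 1
            if prev is not None:
                add_bond(prev, idx, pending_order, i)
            prev = idx
            pending_order, pending_any = 1, False
            continue
        if ch == "[":
            end = s.find("]", i)
            if end < 0:
                raise ParseError("unterminated '['", offset=i)
            body = s[i + 1 : end]
            m = re.fullmatch(r"([A-Z][a-z]?)(\+{1,2}|-{1,2}|[+-]\d+)?", body)
            if not m:
                raise ParseError(f"unsupported bracket atom [{body}]", offset=i)
            element, charge_str = m.group(1), m.group(2)
            if element not in PERIODIC_TABLE:
                raise ParseError(f"unknown element symbol {element!r}", offset=i)
            charge = 0
            if charge_str:
                if charge_str in ("+", "++", "-", "--"):
                    charge = charge_str.count("+") - charge_str.count("-")
                else:
                    charge = int(charge_str)
            atom = _RawAtom(element, charge)
            i = end + 1
            i = read_annotations(i, atom.annotations)
            atoms.append(atom)
            idx = len(atoms) - 1
            if prev is not None:
                add_bond(prev, idx, pending_order, i)
            prev = idx
            pending_order, pending_any = 1, False
            continue
        matched = None
        for symbol in _ORGANIC_SUBSET:
            if s.startswith(symbol, i):
                matched = symbol
                break
        if matched is None:
            raise ParseError(f"unsupported token {ch!r}", offset=i)
        atom = _RawAtom(matched, 0)
        i += len(matched)
        i = read_annotations(i, atom.annotations)
        atoms.append(atom)
        idx = len(atoms) - 1
        if prev is not None:
            add_bond(prev, idx, pending_order, i)
        prev = idx
        pending_order, pending_any = 1, False

    if stack:
        raise ParseError("unmatched '('", offset=len(s))
    if ring_open:
        digit = sorted(ring_open)[0]
        raise ParseError(f"unclosed ring digit {digit!r}", offset=len(s))
    if not atoms:
        raise ParseError("empty notation", offset=0)
    return atoms, bonds


def parse_linear(notation: str, name: str = "") -> MoleculeGraph:
    """Parse the plain (non-query) linear notation into a MoleculeGraph.

    Hydrogen-suppressed model: implicit hydrogens are never added.
    """
    raw_atoms, raw_bonds = _tokenize_notation(notation, allow_query=False)
    atoms = [Atom(i, a.element, a.charge or 0) for i, a in enumerate(raw_atoms)]
    bonds = [Bond(b.a, b.b, b.order or 1) for b in raw_bonds]
    return MoleculeGraph(atoms, bonds, name or notation)


# ---------------------------------------------------------------------------
# Minimal CIF cell extraction
# ---------------------------------------------------------------------------

_CELL_TAGS = (
    "_cell_length_a",
    "_cell_length_b",
    "_cell_length_c",
    "_cell_angle_alpha",
    "_cell_angle_beta",
    "_cell_angle_gamma",
)


def read_cif_cell(stream: IO[str]):
    """Extract the six cell parameters from minimal CIF text.

    Parenthesized standard uncertainties are stripped.  Returns a UnitCell.
    """
    from .cell import UnitCell

    values: dict[str, float] = {}
    for line in stream:
        parts = line.split()
        if len(parts) >= 2 and parts[0] in _CELL_TAGS:
            raw = parts[1]
            m = re.fullmatch(r"([-+]?[0-9]*\.?[0-9]+)(\([0-9]+\))?", raw)
            if not m:
                raise ParseError(f"unparseable value {raw!r} for {parts[0]}")
            values[parts[0]] = float(m.group(1))
    for tag in _CELL_TAGS:
        if tag not in values:
            raise ParseError(f"missing {tag}")
    return UnitCell(
        values["_cell_length_a"],
        values["_cell_length_b"],
        values["_cell_length_c"],
        values["_cell_angle_alpha"],
        values["_cell_angle_beta"],
        values["_cell_angle_gamma"],
    )
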