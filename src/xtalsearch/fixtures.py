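"""Deterministic synthetic fixtures: molecules, cells and a complete
fixture database with a ground-truth manifest.

Everything is generated from a seed - no downloads, no binary assets.  The
molecule catalog carries the worked similarity/substructure properties
(hexane vs cyclohexane, halogenated benzenes, a macrocycle, three drug-like
benzimidazole-sulfinyl analogs plus unrelated decoys).
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cell import UnitCell
from .chem import Atom, Bond, EntryRecord, MoleculeGraph, parse_linear, write_sdf
from .substructure import SubstructureQuery, compile_query

__all__ = [
    "FixtureSpec",
    "CATALOG",
    "PROBE_QUERIES",
    "catalog_molecules",
    "random_molecules",
    "random_cells",
    "random_unimodular",
    "scramble_cell",
    "brute_force_match",
    "build_fixture_db",
]

# Linear notations for the named catalog (Kekulé, hydrogen-suppressed).
_SULFINYL_CORE = "C1=CC=C2C(=C1)NC(=N2)S(=O)C"
CATALOG: dict[str, str] = {
    "hexane": "CCCCCC",
    "cyclohexane": "C1CCCCC1",
    "benzene": "C1=CC=CC=C1",
    "naphthalene": "C1=CC=C2C=CC=CC2=C1",
    "spirodecane": "C12(CCCC1)CCCCC2",
    "chlorobenzene": "ClC1=CC=CC=C1",
    "fluorobenzene": "FC1=CC=CC=C1",
    "pyridine": "C1=CC=CC=N1",
    "macrocycle12": "C1CCCCCCCCCCC1",
    "c20": "C" * 20,
    "toluene": "CC1=CC=CC=C1",
    "phenol": "OC1=CC=CC=C1",
    # benzimidazole-sulfinyl drug-like analogs (shared scaffold, varied tail)
    "pantoprazole_analog": _SULFINYL_CORE + "C1=CC=C(OC)C=N1",
    "omeprazole_analog": _SULFINYL_CORE + "C1=CC=C(C)C=N1",
    "lansoprazole_analog": _SULFINYL_CORE + "C1=CC=C(CC(F)(F)F)C=N1",
    # unrelated decoys
    "decoy_ester": "CC(=O)OC1=CC=CC=C1C(=O)O",
    "decoy_alcohol": "OC1CCCCC1",
    "decoy_amine": "NC(CC1=CC=CC=C1)C(=O)O",
    "decoy_ketone": "O=C1CCCCC1",
    "decoy_ether": "CCOCC1=CC=CC=C1",
}

DRUG_ANALOGS = ("pantoprazole_analog", "omeprazole_analog", "lansoprazole_analog")
DECOYS = tuple(n for n in CATALOG if n.startswith("decoy_"))

# probe substructures recorded in the fixture manifest (annotated notation)
PROBE_QUERIES: dict[str, str] = {
    "chloro": "Cl",
    "fluoro": "F",
    "imine": "C=N",
    "sulfinyl": "S=O",
    "hydroxy": "O",
    "ring6": "C{ring:6-6}",
    "acyclic_n": "N{ring:acyclic}",
}


def catalog_molecules() -> dict[str, MoleculeGraph]:
    """The fixed named molecule set, parsed fresh on every call."""
    return {name: parse_linear(notation, name) for name, notation in CATALOG.items()}


@dataclass
class FixtureSpec:
    seed: int = 0
    n_entries: int = 20
    # random-molecule recipe
    n_atoms_min: int = 4
    n_atoms_max: int = 12
    ring_probability: float = 0.3
    charge_probability: float = 0.05
    elements: tuple[str, ...] = ("C", "C", "C", "C", "N", "O", "S", "Cl", "F")
    # random-cell recipe
    length_range: tuple[float, float] = (4.0, 12.0)
    angle_range: tuple[float, float] = (70.0, 110.0)
    habits: tuple[str, ...] = ("needle", "plate", "block", "prism")

    def __post_init__(self) -> None:
        if self.n_atoms_min < 1 or self.n_atoms_max < self.n_atoms_min:
            raise ValueError("invalid n_atoms range")
        if not 0 <= self.ring_probability <= 1:
            raise ValueError("ring_probability must be in [0, 1]")
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")


def random_molecules(spec: FixtureSpec, n: Optional[int] = None) -> list[MoleculeGraph]:
    """Seeded random connected molecules: random spanning tree plus
    ring-closure edges at the given probability."""
    rng = random.Random(spec.seed)
    mols = []
    for mi in range(n if n is not None else spec.n_entries):
        n_atoms = rng.randint(spec.n_atoms_min, spec.n_atoms_max)
        atoms = []
        for i in range(n_atoms):
            element = rng.choice(spec.elements)
            charge = 0
            if rng.random() < spec.charge_probability:
                charge = rng.choice((-1, 1))
            atoms.append(Atom(i, element, charge))
        pairs = set()
        bonds = []
        for i in range(1, n_atoms):
            j = rng.randrange(i)
            order = rng.choices((1, 2, 3), weights=(70, 25, 5))[0]
            bonds.append(Bond(j, i, order))
            pairs.add((j, i))
        if n_atoms >= 3 and rng.random() < spec.ring_probability:
            for _ in range(4):  # a few attempts to place a closure
                i, j = rng.sample(range(n_atoms), 2)
                key = (min(i, j), max(i, j))
                if key not in pairs:
                    bonds.append(Bond(key[0], key[1], 1))
                    pairs.add(key)
                    break
        mols.append(MoleculeGraph(atoms, bonds, f"random{mi}"))
    return mols


def random_unimodular(rng: random.Random, lo: int = -2, hi: int = 2) -> np.ndarray:
    """Random integer matrix with entries in [lo, hi] and det +-1."""
    while True:
        m = np.array([[rng.randint(lo, hi) for _ in range(3)] for _ in range(3)])
        if round(float(np.linalg.det(m))) in (-1, 1):
            return m


def scramble_cell(cell: UnitCell, rng: random.Random) -> UnitCell:
    """Same lattice in a random unimodular basis."""
    return cell.transformed(random_unimodular(rng))


def random_cells(
    spec: FixtureSpec,
    n: Optional[int] = None,
    near_boundary: bool = False,
) -> list[UnitCell]:
    """Seeded valid unit cells.  With near_boundary=True, cells are emitted
    with one angle at 89.9 degrees to sit near a reduction boundary."""
    rng = random.Random(spec.seed + 1)
    lo, hi = spec.length_range
    alo, ahi = spec.angle_range
    cells: list[UnitCell] = []
    target = n if n is not None else spec.n_entries
    while len(cells) < target:
        lengths = sorted(rng.uniform(lo, hi) for _ in range(3))
        angles = [rng.uniform(alo, ahi) for _ in range(3)]
        if near_boundary:
            # two angles on the 90-degree reduction boundary: the reduced
            # cell then has nearby Buerger variants on the other side
            keep = rng.randrange(3)
            for k in range(3):
                if k != keep:
                    angles[k] = 89.9
            angles[keep] = rng.uniform(80.0, 88.0)
        try:
            cells.append(UnitCell(*lengths, *angles))
        except ValueError:
            continue  # non-positive-definite draw; resample
    return cells


# ---------------------------------------------------------------------------
# Exhaustive matcher (independent oracle for the backtracking matcher)
# ---------------------------------------------------------------------------

def brute_force_match(query: SubstructureQuery, mol: MoleculeGraph) -> list[tuple[int, ...]]:
    """All injective adjacency/predicate-preserving mappings by plain
    depth-first enumeration in query-index order.  No screens, no candidate
    refinement - deliberately independent of the production matcher."""
    mol.ring_info
    nq = query.n_atoms
    mappings: list[tuple[int, ...]] = []

    def atom_ok(qi: int, t: int) -> bool:
        qa = query.atoms[qi]
        atom = mol.atoms[t]
        if qa.element is not None and atom.element != qa.element:
            return False
        if qa.charge is not None and atom.formal_charge != qa.charge:
            return False
        return qa.ring.accepts(atom.smallest_ring_size)

    def bonds_ok(qi: int, t: int, partial: list[int]) -> bool:
        for qj, qbond in query.adjacency[qi].items():
            if qj >= qi:
                continue
            bond = mol.bond_between(t, partial[qj])
            if bond is None:
                return False
            if qbond.order is not None and bond.order != qbond.order:
                return False
            if not qbond.ring.accepts(bond.smallest_ring_size):
                return False
        return True

    def recurse(qi: int, partial: list[int], used: set[int]) -> None:
        if qi == nq:
            mappings.append(tuple(partial))
            return
        for t in range(mol.n_atoms):
            if t in used or not atom_ok(qi, t) or not bonds_ok(qi, t, partial):
                continue
            partial.append(t)
            used.add(t)
            recurse(qi + 1, partial, used)
            used.discard(t)
            partial.pop()

    recurse(0, [], set())
    return mappings


# ---------------------------------------------------------------------------
# Fixture database
# ---------------------------------------------------------------------------

_AUTHORS = (
    "A. Archer; B. Builder",
    "C. Crystal",
    "D. Diffraction; E. Ewald",
    "F. Fourier",
)
_JOURNALS = ("J.Fixt.Chem.", "Acta Fixture", "Cryst.Test.Comm.")


@dataclass
class FixtureEntry:
    record: EntryRecord
    name: str
    notation: str
    lattice_group: str
    contains: list[str] = field(default_factory=list)


def _base_lattices(rng: random.Random) -> dict[str, UnitCell]:
    """Nearly-reduced base lattices, including an angle-decoy pair that
    shares reduced lengths but differs in angles by ~5 degrees."""
    return {
        "L0": UnitCell(5.2, 7.3, 9.1, 75.0, 80.0, 85.0),
        "L0_decoy": UnitCell(5.2, 7.3, 9.1, 80.0, 85.0, 89.0),
        "L1": UnitCell(6.1, 6.9, 11.4, 72.0, 78.0, 88.0),
    }


def build_fixture_db(
    spec: FixtureSpec = FixtureSpec(), out_dir: Optional[Path] = None
) -> tuple[list[FixtureEntry], Optional[Path]]:
    """Build the default fixture entry set (catalog molecules, assigned
    metadata, lattices with scrambled-basis duplicates and an angle decoy)
    and optionally write it to disk as entries.tsv + SDF/CIF + manifest.tsv.

    Ground truth in the manifest: probe substructures verified by the
    exhaustive matcher, habit/bioactivity/dates as assigned, and the lattice
    identity group of every cell.
    """
    rng = random.Random(spec.seed)
    names = list(CATALOG)
    mols = catalog_molecules()
    if spec.n_entries <= len(names):
        names = names[: spec.n_entries]
    else:
        # random extras are appended under generated names
        for mol in random_molecules(spec, spec.n_entries - len(names)):
            names.append(mol.name)
            mols[mol.name] = mol

    lattices = _base_lattices(rng)
    probes = {pname: compile_query(q) for pname, q in PROBE_QUERIES.items()}

    # deterministic metadata assignment
    needle_names = set(names[0:8:2])  # 4 entries with needle habit
    phase_names = set(names[2:13:3])  # overlaps needle on index 2
    bioactive = {
        "pantoprazole_analog": "anti-ulcerative",
        "omeprazole_analog": "anti-ulcerative",
        "lansoprazole_analog": "anti-ulcerative",
        "benzene": "antibacterial (fixture)",
        "pyridine": "antibacterial (fixture)",
    }
    synonyms = {
        "pantoprazole_analog": "5-methoxy-2H-benzimidazole fixture analog",
        "benzene": "cyclohexatriene",
        "phenol": "hydroxybenzene; carbolic acid",
    }
    compound_names = {
        name: name.replace("_", "-") for name in names
    }
    compound_names["pantoprazole_analog"] = "2-(pyridinylmethylsulfinyl)-benzimidazole-analog"

    entries: list[FixtureEntry] = []
    for i, name in enumerate(names):
        refcode = f"FIX{i:03d}"
        mol = mols[name]
        # lattice assignment: entry 0 owns L0, entry 5 is L0 scrambled,
        # entry 1 is the angle decoy, entry 7 is the decoy scrambled.
        if name == names[0]:
            group, cell = "L0", lattices["L0"]
        elif i == 5:
            group, cell = "L0", scramble_cell(lattices["L0"], rng)
        elif i == 1:
            group, cell = "L0_decoy", lattices["L0_decoy"]
        elif i == 7:
            group, cell = "L0_decoy", scramble_cell(lattices["L0_decoy"], rng)
        elif i == 9:
            group, cell = "L1", lattices["L1"]
        else:
            group = f"U{i}"
            lengths = sorted(rng.uniform(*spec.length_range) for _ in range(3))
            while True:
                angles = [rng.uniform(70.0, 110.0) for _ in range(3)]
                try:
                    cell = UnitCell(*lengths, *angles)
                    break
                except ValueError:
                    continue
        year = 2000 + (i * 7) % 24
        date_added = f"20{19 + i % 6:02d}-{1 + i % 12:02d}-{1 + (i * 3) % 28:02d}"
        date_modified = f"20{20 + i % 5:02d}-{1 + (i * 5) % 12:02d}-{1 + (i * 11) % 28:02d}"
        record = EntryRecord(
            refcode=refcode,
            connectivities=[mol],
            cell=cell,
            authors=_AUTHORS[i % len(_AUTHORS)],
            journal=_JOURNALS[i % len(_JOURNALS)],
            compound_name=compound_names[name],
            synonyms=synonyms.get(name),
            habit=("needle" if name in needle_names else spec.habits[1 + i % (len(spec.habits) - 1)]),
            bioactivity=bioactive.get(name),
            phase_transitions=("reversible transition at 150 K" if name in phase_names else None),
            polymorphism=("two known polymorphs" if i % 7 == 3 else None),
            year=year,
            volume=100 + i,
            first_page=1000 + 13 * i,
            date_added=date_added,
            date_modified=max(date_added, date_modified),
        )
        contains = sorted(
            pname for pname, probe in probes.items() if brute_force_match(probe, mol)
        )
        entries.append(FixtureEntry(record, name, CATALOG.get(name, ""), group, contains))

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "sdf").mkdir(parents=True, exist_ok=True)
        (out_dir / "cif").mkdir(parents=True, exist_ok=True)
        header = [
            "refcode", "sdf", "cif", "authors", "journal", "compound_name",
            "synonyms", "habit", "bioactivity", "phase_transitions",
            "polymorphism", "year", "volume", "first_page", "date_added",
            "date_modified",
        ]
        with open(out_dir / "entries.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            for fe in entries:
                r = fe.record
                sdf_rel = f"sdf/{r.refcode}.sdf"
                cif_rel = f"cif/{r.refcode}.cif"
                with open(out_dir / sdf_rel, "w") as sf:
                    write_sdf([(mols[fe.name], {"name": fe.name})], sf)
                cell = r.cell
                with open(out_dir / cif_rel, "w") as cf:
                    cf.write(f"data_{r.refcode}\n")
                    for tag, value in zip(
                        (
                            "_cell_length_a", "_cell_length_b", "_cell_length_c",
                            "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma",
                        ),
                        cell.parameters(),
                    ):
                        cf.write(f"{tag} {value:.6f}\n")
                writer.writerow(
                    [
                        r.refcode, sdf_rel, cif_rel,
                        r.authors or "", r.journal or "", r.compound_name or "",
                        r.synonyms or "", r.habit or "", r.bioactivity or "",
                        r.phase_transitions or "", r.polymorphism or "",
                        r.year or "", r.volume or "", r.first_page or "",
                        r.date_added or "", r.date_modified or "",
                    ]
                )
        with open(out_dir / "manifest.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["refcode", "name", "notation", "habit", "bioactivity",
                 "phase_transitions", "date_added", "lattice_group", "contains"]
            )
            for fe in entries:
                r = fe.record
                writer.writerow(
                    [r.refcode, fe.name, fe.notation, r.habit or "",
                     r.bioactivity or "", r.phase_transitions or "",
                     r.date_added or "", fe.lattice_group, ",".join(fe.contains)]
                )
    return entries, out_dir
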