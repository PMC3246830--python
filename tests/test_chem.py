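import io
import random

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from xtalsearch.chem import (
    Atom,
    Bond,
    MoleculeGraph,
    ParseError,
    compute_ring_info,
    parse_linear,
    read_cif_cell,
    read_sdf,
    strip_hydrogens,
    write_sdf,
)
from xtalsearch.fixtures import FixtureSpec, random_molecules

from oracle_utils import shortest_cycle_through_atom

BENZENE_SDF = """benzene
  test

  6  6  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
M  END
$$$$
"""


class TestReadSdf:
    def test_benzene_record(self):
        records = read_sdf(io.StringIO(BENZENE_SDF))
        assert len(records) == 1
        mol, props = records[0]
        assert mol.n_atoms == 6
        assert mol.n_bonds == 6
        assert sorted(b.order for b in mol.bonds) == [1, 1, 1, 2, 2, 2]
        assert props == {}

    def test_empty_stream(self):
        assert read_sdf(io.StringIO("")) == []

    def test_bond_out_of_range_names_line(self):
        bad = BENZENE_SDF.replace("  6  1  1  0", "  7  1  1  0")
        with pytest.raises(ParseError, match=r"atom 7 of 6.*line 16"):
            read_sdf(io.StringIO(bad))

    def test_unknown_element(self):
        bad = BENZENE_SDF.replace(" C   0  0  0  0  0  0  0  0  0  0  0  0\n  1", " Xx  0  0  0  0  0  0  0  0  0  0  0  0\n  1")
        with pytest.raises(ParseError, match="Xx"):
            read_sdf(io.StringIO(bad))

    def test_malformed_counts_line(self):
        bad = BENZENE_SDF.replace("  6  6  0", "  x  6  0")
        with pytest.raises(ParseError, match="counts line"):
            read_sdf(io.StringIO(bad))

    def test_multi_component_split_shares_properties(self):
        two_frags = """salt
  test

  3  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 Na  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  CHG  2   2  -1   3   1
M  END
> <origin>
fixture

$$$$
"""
        records = read_sdf(io.StringIO(two_frags))
        assert len(records) == 2
        (mol1, p1), (mol2, p2) = records
        assert p1 == p2 == {"origin": "fixture"}
        assert {mol1.n_atoms, mol2.n_atoms} == {1, 2}
        charges = sorted(a.formal_charge for r in records for a in r[0].atoms)
        assert charges == [-1, 0, 1]

    def test_round_trip(self):
        mol = parse_linear("CC(=O)[O-]", name="acetate")
        buf = io.StringIO()
        write_sdf([(mol, {"tag": "value"})], buf)
        buf.seek(0)
        (back, props), = read_sdf(buf)
        assert back.n_atoms == mol.n_atoms
        assert back.n_bonds == mol.n_bonds
        assert [a.element for a in back.atoms] == [a.element for a in mol.atoms]
        assert [a.formal_charge for a in back.atoms] == [a.formal_charge for a in mol.atoms]
        assert sorted((b.key, b.order) for b in back.bonds) == sorted(
            (b.key, b.order) for b in mol.bonds
        )
        assert props == {"tag": "value"}


class TestParseLinear:
    def test_hexane(self):
        mol = parse_linear("CCCCCC")
        assert mol.n_atoms == 6
        assert mol.n_bonds == 5
        assert all(b.order == 1 for b in mol.bonds)
        assert len(mol.ring_info.rings) == 0

    def test_cyclohexane(self):
        mol = parse_linear("C1CCCCC1")
        assert mol.n_atoms == 6
        assert mol.n_bonds == 6
        assert [len(r) for r in mol.ring_info.rings] == [6]

    def test_benzene_kekule(self):
        mol = parse_linear("C1=CC=CC=C1")
        assert sorted(b.order for b in mol.bonds) == [1, 1, 1, 2, 2, 2]
        assert [len(r) for r in mol.ring_info.rings] == [6]

    def test_charges(self):
        mol = parse_linear("[N+](C)(C)C")
        assert mol.atoms[0].formal_charge == 1
        assert parse_linear("[O-2]").atoms[0].formal_charge == -2

    def test_branching(self):
        mol = parse_linear("CC(C)(C)C")
        assert mol.atoms[1].degree == 4

    @pytest.mark.parametrize(
        "bad,message",
        [
            ("C(C", "unmatched"),
            ("C)C", "unmatched"),
            ("C1CC", "unclosed ring digit"),
            ("Cx", "unsupported token"),
            ("C*C", "query-only"),
            ("C~C", "query-only"),
            ("", "empty"),
        ],
    )
    def test_errors_with_offset(self, bad, message):
        with pytest.raises(ParseError, match=message):
            parse_linear(bad)

    def test_no_implicit_hydrogens(self):
        assert parse_linear("C").n_atoms == 1

    @given(st.integers(min_value=1, max_value=30))
    def test_linear_alkane_chain(self, n):
        mol = parse_linear("C" * n)
        assert mol.n_atoms == n
        assert mol.n_bonds == n - 1


class TestReadCifCell:
    def test_su_stripped(self):
        cif = "\n".join(
            f"{tag} {value}"
            for tag, value in [
                ("_cell_length_a", "5.0(1)"),
                ("_cell_length_b", "5.0"),
                ("_cell_length_c", "5.0(12)"),
                ("_cell_angle_alpha", "90"),
                ("_cell_angle_beta", "90.0"),
                ("_cell_angle_gamma", "90"),
            ]
        )
        cell = read_cif_cell(io.StringIO(cif))
        assert cell.parameters() == (5.0, 5.0, 5.0, 90.0, 90.0, 90.0)

    def test_missing_tag(self):
        cif = "_cell_length_a 5\n_cell_length_b 5\n_cell_length_c 5\n_cell_angle_alpha 90\n_cell_angle_gamma 90\n"
        with pytest.raises(ParseError, match="missing _cell_angle_beta"):
            read_cif_cell(io.StringIO(cif))

    def test_exact_values(self):
        cif = (
            "data_x\n_cell_length_a 3.1\n_cell_length_b 4.2\n_cell_length_c 5.3\n"
            "_cell_angle_alpha 80\n_cell_angle_beta 85\n_cell_angle_gamma 95\n"
        )
        assert read_cif_cell(io.StringIO(cif)).parameters() == (3.1, 4.2, 5.3, 80.0, 85.0, 95.0)


class TestRingInfo:
    def test_hexane_acyclic(self):
        info = parse_linear("CCCCCC").ring_info
        assert info.rings == []
        assert all(s is None for s in info.atom_ring_size)

    def test_naphthalene(self, catalog):
        mol = catalog["naphthalene"]
        info = mol.ring_info
        assert len(info.rings) == 2
        assert [len(a) for a in info.assemblies] == [10]
        # every atom, including the two fusion atoms, is in a 6-ring
        assert info.atom_ring_size == [6] * 10
        for v in range(10):
            assert shortest_cycle_through_atom(mol, v) == 6

    def test_spiro(self, catalog):
        mol = catalog["spirodecane"]
        info = mol.ring_info
        assert sorted(len(r) for r in info.rings) == [5, 6]
        assert [len(a) for a in info.assemblies] == [10]  # linked via spiro atom
        spiro_atom = next(i for i in range(10) if mol.atoms[i].degree == 4)
        assert info.atom_ring_size[spiro_atom] == 5
        for v in range(10):
            assert info.atom_ring_size[v] == shortest_cycle_through_atom(mol, v)

    def test_sssr_count_matches_cyclomatic(self, catalog):
        for mol in catalog.values():
            info = mol.ring_info
            assert len(info.rings) == mol.n_bonds - mol.n_atoms + 1

    def test_sssr_count_matches_networkx(self, catalog):
        for mol in catalog.values():
            g = nx.Graph((b.a, b.b) for b in mol.bonds)
            g.add_nodes_from(range(mol.n_atoms))
            basis = nx.minimum_cycle_basis(g)
            info = mol.ring_info
            assert len(info.rings) == len(basis)
            assert sorted(len(r) for r in info.rings) == sorted(len(c) for c in basis)

    def test_atom_ring_sizes_vs_oracle_random(self):
        spec = FixtureSpec(seed=11, n_atoms_min=4, n_atoms_max=14, ring_probability=0.8)
        for mol in random_molecules(spec, n=40):
            info = compute_ring_info(mol)
            for v in range(mol.n_atoms):
                assert info.atom_ring_size[v] == shortest_cycle_through_atom(mol, v)

    def test_deterministic(self, catalog):
        for mol in catalog.values():
            a = compute_ring_info(mol)
            b = compute_ring_info(mol)
            assert a.rings == b.rings
            assert a.assemblies == b.assemblies


class TestGraphValidation:
    def test_disconnected_rejected(self):
        atoms = [Atom(0, "C"), Atom(1, "C")]
        with pytest.raises(ValueError, match="connected"):
            MoleculeGraph(atoms, [])

    def test_self_bond_rejected(self):
        with pytest.raises(ValueError):
            Bond(1, 1, 1)

    def test_duplicate_bond_rejected(self):
        atoms = [Atom(0, "C"), Atom(1, "C")]
        with pytest.raises(ValueError, match="duplicate"):
            MoleculeGraph(atoms, [Bond(0, 1, 1), Bond(1, 0, 2)])

    def test_degree_derived(self):
        mol = parse_linear("CC(C)C")
        assert [a.degree for a in mol.atoms] == [1, 3, 1, 1]


class TestStripHydrogens:
    def test_terminal_h_removed(self):
        atoms = [Atom(0, "C"), Atom(1, "H"), Atom(2, "H"), Atom(3, "O")]
        bonds = [Bond(0, 1, 1), Bond(0, 2, 1), Bond(0, 3, 2)]
        mol = strip_hydrogens(MoleculeGraph(atoms, bonds))
        assert [a.element for a in mol.atoms] == ["C", "O"]
        assert mol.n_bonds == 1
        assert mol.bonds[0].order == 2

    def test_all_h_molecule_kept(self):
        mol = MoleculeGraph([Atom(0, "H"), Atom(1, "H")], [Bond(0, 1, 1)])
        assert strip_hydrogens(mol).n_atoms == 2

    def test_random_molecule_stability(self):
        rng = random.Random(5)
        for mol in random_molecules(FixtureSpec(seed=5), n=10):
            stripped = strip_hydrogens(mol)
            assert stripped.n_atoms == mol.n_atoms  # no H in the alphabet
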