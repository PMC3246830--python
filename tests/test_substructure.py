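import random
from collections import Counter

import pytest

from xtalsearch.chem import Atom, Bond, MoleculeGraph, ParseError, parse_linear
from xtalsearch.fingerprint import feature_bit, fingerprint
from xtalsearch.fixtures import (
    CATALOG,
    FixtureSpec,
    brute_force_match,
    random_molecules,
)
from xtalsearch.substructure import (
    QueryAtom,
    QueryBond,
    RingConstraint,
    SubstructureQuery,
    compile_query,
    entry_screens_for,
    match,
    screen_pass,
    substructure_search,
)


def _screens_for(mol: MoleculeGraph):
    return entry_screens_for(mol, fingerprint(mol))


class TestCompileQuery:
    def test_cn_bond(self):
        q = compile_query("C=N")
        assert q.n_atoms == 2
        assert q.element_screen == Counter({"C": 1, "N": 1})
        assert q.feature_bits.bits >> feature_bit("C=N") & 1

    def test_single_chlorine(self):
        q = compile_query("Cl")
        assert q.n_atoms == 1
        assert q.element_screen == Counter({"Cl": 1})

    def test_ring_range_annotation(self):
        q = compile_query("C{ring:6-6}1CCCCC1")
        assert q.atoms[0].ring.min == 6
        assert q.atoms[0].ring.max == 6
        assert q.atoms[1].ring.is_trivial

    def test_ring_annotation_forms(self):
        assert compile_query("C{ring:5}").atoms[0].ring.min == 5
        assert compile_query("C{ring:5-}").atoms[0].ring.max is None
        assert compile_query("C{ring:-8}").atoms[0].ring.max == 8
        assert compile_query("C{ring:acyclic}").atoms[0].ring.acyclic

    def test_contradictory_ring_range(self):
        with pytest.raises((ParseError, ValueError), match="min 7 > max 5"):
            compile_query("C{ring:7-5}")

    def test_disconnected_query_rejected(self):
        with pytest.raises(ParseError, match="disconnected"):
            SubstructureQuery([QueryAtom(0, "C", 0), QueryAtom(1, "C", 0)], [])

    def test_wildcards_not_screened(self):
        q = compile_query("*~*")
        assert q.element_screen == Counter()
        assert q.feature_bits.bits == 0

    def test_bare_atom_is_neutral(self):
        assert compile_query("N").atoms[0].charge == 0

    def test_charge_annotations(self):
        assert compile_query("[N+]").atoms[0].charge == 1
        assert compile_query("N{charge:-1}").atoms[0].charge == -1
        assert compile_query("N{charge:any}").atoms[0].charge is None

    def test_bond_ring_annotation(self):
        q = compile_query("C={ring:6-6}C")
        assert q.bonds[0].ring.min == 6
        assert q.atoms[1].ring.is_trivial

    def test_bond_ring_annotation_matching(self, catalog):
        q = compile_query("C={ring:6-6}C")
        assert len(match(q, catalog["benzene"])) == 6
        assert match(q, parse_linear("C=C")) == []


class TestScreenPass:
    def test_chlorine_vs_hexane(self, catalog):
        assert not screen_pass(compile_query("Cl"), _screens_for(catalog["hexane"]))

    def test_macrocycle_assembly_screen(self, catalog):
        q = compile_query("C1CCCCCCCCCCC1")  # 12-ring query
        for name in ("cyclohexane", "naphthalene", "spirodecane"):
            assert not screen_pass(q, _screens_for(catalog[name]))
        assert screen_pass(q, _screens_for(catalog["macrocycle12"]))

    def test_exact_match_passes(self, catalog):
        for name in ("benzene", "pyridine", "decoy_ester"):
            q = compile_query(CATALOG[name])
            assert screen_pass(q, _screens_for(catalog[name]))

    def test_soundness_random_pairs(self):
        spec = FixtureSpec(seed=31, n_atoms_min=3, n_atoms_max=9, ring_probability=0.5)
        mols = random_molecules(spec, n=40)
        rng = random.Random(31)
        for _ in range(200):
            target = rng.choice(mols)
            query_mol = rng.choice(mols)
            q = _query_from_molecule(query_mol)
            if brute_force_match(q, target):
                assert screen_pass(q, _screens_for(target))


def _query_from_molecule(mol: MoleculeGraph) -> SubstructureQuery:
    atoms = [QueryAtom(a.index, a.element, a.formal_charge) for a in mol.atoms]
    bonds = [QueryBond(b.a, b.b, b.order) for b in mol.bonds]
    return SubstructureQuery(atoms, bonds)


QUERY_SPECS = [
    "C",
    "Cl",
    "C=N",
    "CC",
    "C=C",
    "CCC",
    "C(C)C",
    "*~*",
    "*~*~*",
    "C{ring:6-6}",
    "C{ring:5-5}",
    "C{ring:acyclic}",
    "N{ring:acyclic}",
    "C{ring:6-6}C{ring:6-6}",
    "C1CCCCC1",
    "C1=CC=CC=C1",
    "*1~*~*~*~*~*1",
    "O",
    "S=O",
    "C=O",
]


class TestMatch:
    def test_cn_on_pyridine(self, catalog):
        assert len(match(compile_query("C=N"), catalog["pyridine"])) >= 1

    def test_ring_range_constraint(self, catalog):
        q = compile_query("C{ring:6-6}")
        cyclopentane = parse_linear("C1CCCC1")
        assert match(q, cyclopentane) == []
        assert len(match(q, catalog["benzene"])) == 6

    def test_acyclic_constraint(self, catalog):
        q = compile_query("C{ring:acyclic}")
        assert match(q, catalog["cyclohexane"]) == []
        assert len(match(q, catalog["hexane"])) == 6

    def test_monomorphism_embedding(self, catalog):
        # an acyclic chain query embeds into a ring unless constrained
        q = compile_query("CCC")
        assert len(match(q, catalog["cyclohexane"])) > 0

    def test_automorphic_duplicates_kept(self, catalog):
        q = compile_query("C1=CC=CC=C1")
        mappings = match(q, catalog["benzene"], find_all=True)
        assert len(mappings) == len(brute_force_match(q, catalog["benzene"]))
        assert len(mappings) == 6  # Kekulé benzene: 3 rotations x 2 reflections

    def test_existence_mode_stops_early(self, catalog):
        q = compile_query("C")
        assert len(match(q, catalog["hexane"], find_all=False)) == 1

    def test_charge_constraint(self):
        charged = parse_linear("[N+](C)C")
        neutral = parse_linear("N(C)C")
        q_plus = compile_query("[N+]")
        q_bare = compile_query("N")
        q_any = compile_query("N{charge:any}")
        assert len(match(q_plus, charged)) == 1
        assert match(q_plus, neutral) == []
        assert match(q_bare, charged) == []
        assert len(match(q_bare, neutral)) == 1
        assert len(match(q_any, charged)) == 1
        assert len(match(q_any, neutral)) == 1

    @pytest.mark.parametrize("query_spec", QUERY_SPECS)
    def test_equivalence_with_oracle_on_catalog(self, catalog, query_spec):
        q = compile_query(query_spec)
        for mol in catalog.values():
            if mol.n_atoms > 12:
                continue
            assert sorted(match(q, mol)) == sorted(brute_force_match(q, mol))

    def test_equivalence_with_oracle_on_random(self):
        spec = FixtureSpec(seed=77, n_atoms_min=3, n_atoms_max=10, ring_probability=0.6)
        mols = random_molecules(spec, n=25)
        queries = [compile_query(s) for s in QUERY_SPECS]
        for mol in mols:
            for q in queries:
                assert sorted(match(q, mol)) == sorted(brute_force_match(q, mol))

    def test_mappings_are_valid(self, catalog):
        for query_spec in QUERY_SPECS:
            q = compile_query(query_spec)
            for mol in catalog.values():
                for mapping in match(q, mol):
                    assert len(set(mapping)) == len(mapping)  # injective
                    for qa in q.atoms:
                        t = mapping[qa.index]
                        if qa.element is not None:
                            assert mol.atoms[t].element == qa.element
                        if qa.charge is not None:
                            assert mol.atoms[t].formal_charge == qa.charge
                        assert qa.ring.accepts(mol.atoms[t].smallest_ring_size)
                    for qb in q.bonds:
                        bond = mol.bond_between(mapping[qb.a], mapping[qb.b])
                        assert bond is not None
                        if qb.order is not None:
                            assert bond.order == qb.order
                        assert qb.ring.accepts(bond.smallest_ring_size)


class TestSubstructureSearch:
    def test_manifest_ground_truth(self, fixture_db, manifest):
        from xtalsearch.fixtures import PROBE_QUERIES

        for probe_name, probe_spec in PROBE_QUERIES.items():
            q = compile_query(probe_spec)
            hits = {r.refcode for r in substructure_search(q, fixture_db)}
            expected = {
                refcode for refcode, fe in manifest.items() if probe_name in fe.contains
            }
            assert hits == expected, probe_name

    def test_full_connectivity_query_hits_itself(self, fixture_db, manifest):
        q = compile_query(CATALOG["spirodecane"])
        hits = {r.refcode for r in substructure_search(q, fixture_db)}
        expected = {r for r, fe in manifest.items() if fe.name == "spirodecane"}
        assert expected <= hits

    def test_screens_never_change_results(self, fixture_db):
        for spec in QUERY_SPECS:
            q = compile_query(spec)
            with_screens = substructure_search(q, fixture_db, find_all=True)
            without = substructure_search(q, fixture_db, find_all=True, use_screens=False)
            assert [(r.refcode, r.conn_index, sorted(r.mappings)) for r in with_screens] == [
                (r.refcode, r.conn_index, sorted(r.mappings)) for r in without
            ]

    def test_hits_invariant_under_relabeling(self, catalog):
        from test_fingerprint import _relabel

        rng = random.Random(13)
        q = compile_query("C=N")
        for mol in catalog.values():
            expected = len(match(q, mol))
            assert len(match(q, _relabel(mol, rng))) == expected
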