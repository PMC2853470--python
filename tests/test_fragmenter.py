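"""Combinatorial bond disconnection: cleavage, redundancy, enumeration.

The enumeration is checked against an independent brute-force oracle
that recursively applies every cleavage event on networkx graphs.
"""

from collections import Counter
from itertools import combinations

import networkx as nx
import pytest

from fragrank.chem_core import Formula, formula_of, parse_structure
from fragrank.constants import MONOISOTOPIC_MASS
from fragrank.fragmenter import (
    BDETable,
    Fragment,
    FragmenterConfig,
    as_root_fragment,
    bde_of_bond,
    cleavable_bonds,
    cleave,
    enumerate_fragments,
    redundancy_key,
)


# ---------------------------------------------------------------------------
# independent oracle: recursive event application on networkx graphs


def _to_nx(molecule) -> nx.Graph:
    g = nx.Graph()
    for i, atom in enumerate(molecule.atoms):
        g.add_node(i, element=atom.element, h=atom.n_hydrogens)
    for b in molecule.bonds:
        g.add_edge(b.a, b.b)
    return g


def _node_mass(g: nx.Graph, nodes) -> float:
    return sum(
        MONOISOTOPIC_MASS[g.nodes[n]["element"]] + g.nodes[n]["h"] * MONOISOTOPIC_MASS["H"]
        for n in nodes
    )


def _node_formula(g: nx.Graph, nodes) -> Formula:
    counts: dict[str, int] = {}
    h = 0
    for n in nodes:
        el = g.nodes[n]["element"]
        counts[el] = counts.get(el, 0) + 1
        h += g.nodes[n]["h"]
    if h:
        counts["H"] = counts.get("H", 0) + h
    return Formula(counts)


def _oracle_events(g: nx.Graph):
    """Every cleavage event: one bridge, or one disconnecting ring pair."""
    bridges = {frozenset(e) for e in nx.bridges(g)}
    for e in g.edges():
        if frozenset(e) in bridges:
            yield (e,)
    ring = [e for e in g.edges() if frozenset(e) not in bridges]
    for e1, e2 in combinations(ring, 2):
        h = g.copy()
        h.remove_edge(*e1)
        h.remove_edge(*e2)
        if not nx.is_connected(h):
            yield (e1, e2)


def brute_force_subsets(molecule, depth: int, min_mass: float) -> set[frozenset]:
    """Atom subsets reachable by <= depth cleavage events, mass-filtered."""
    root = _to_nx(molecule)
    found: set[frozenset] = set()

    def recurse(g: nx.Graph, d: int):
        if d == depth:
            return
        for event in _oracle_events(g):
            h = g.copy()
            for e in event:
                h.remove_edge(*e)
            for comp in nx.connected_components(h):
                if _node_mass(root, comp) < min_mass:
                    continue
                key = frozenset(comp)
                sub = root.subgraph(comp).copy()
                # remove the event's edges in case both ends survive (they never do)
                if key not in found:
                    found.add(key)
                    recurse(sub, d + 1)
                else:
                    recurse(sub, d + 1)

    recurse(root, 0)
    return found


def brute_force_formula_multiset(molecule, depth: int, min_mass: float) -> Counter:
    root = _to_nx(molecule)
    return Counter(
        str(_node_formula(root, nodes))
        for nodes in brute_force_subsets(molecule, depth, min_mass)
    )


ORACLE_SMILES = [
    "CC", "CCC", "CCCC", "CC(C)C", "CCO", "CC=O", "CC(C)=O", "CC(N)C(=O)O",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "c1ccccc1", "Oc1ccccc1",
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "CC(=O)O", "NCC(=O)O", "COC",
    "CN(C)C", "OCC(O)CO",
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("depth", [1, 2])
    @pytest.mark.parametrize("smiles", ORACLE_SMILES)
    def test_formula_multisets_match_brute_force(self, smiles, depth):
        """atom_id-mode enumeration equals exhaustive event recursion."""
        mol = parse_structure(smiles, "smiles", id=smiles)
        assert len(mol.atoms) <= 8
        got = enumerate_fragments(
            mol, FragmenterConfig(max_depth=depth, min_mass=10.0, redundancy_mode="atom_id")
        )
        expected = brute_force_formula_multiset(mol, depth, 10.0)
        assert Counter(str(f.formula) for f in got) == expected

    @pytest.mark.parametrize("smiles", ["CCO", "C1CCCCC1", "Oc1ccccc1", "CC(N)C(=O)O"])
    def test_formula_mode_is_subset_of_atom_id_mode(self, smiles):
        mol = parse_structure(smiles, "smiles", id=smiles)
        by_formula = enumerate_fragments(
            mol, FragmenterConfig(max_depth=2, min_mass=10.0, redundancy_mode="molecular_formula")
        )
        by_atoms = enumerate_fragments(
            mol, FragmenterConfig(max_depth=2, min_mass=10.0, redundancy_mode="atom_id")
        )
        assert {f.formula for f in by_formula} <= {f.formula for f in by_atoms}


class TestCleavableBonds:
    def test_methane_has_none(self):
        assert cleavable_bonds(parse_structure("C", "smiles")) == []

    def test_propane_has_two(self, toy):
        assert len(cleavable_bonds(toy["propane"])) == 2

    def test_cyclohexane_all_ring(self, toy):
        mol = toy["cyclohexane"]
        bonds = cleavable_bonds(mol)
        assert len(bonds) == 6
        assert all(mol.bonds[k].in_ring for k in bonds)


class TestCleave:
    def test_propane_middle_bond(self, toy):
        root = as_root_fragment(toy["propane"])
        children = {}
        for k in cleavable_bonds(root):
            for child in cleave(root, k):
                children.setdefault(str(child.formula), child)
        assert set(children) == {"CH3", "C2H5"}
        assert all(c.depth == 1 for c in children.values())

    def test_cyclohexane_opposite_pair_gives_two_c3h6(self, toy):
        root = as_root_fragment(toy["cyclohexane"])
        # bonds 0-5 form the ring; an opposite pair splits 3+3
        kids = cleave(root, (0, 3))
        assert sorted(str(k.formula) for k in kids) == ["C3H6", "C3H6"]

    def test_cyclohexane_adjacent_pair_gives_c1_and_c5(self, toy):
        root = as_root_fragment(toy["cyclohexane"])
        kids = cleave(root, (0, 1))
        assert sorted(str(k.formula) for k in kids) == ["C5H10", "CH2"]

    def test_fused_ring_shared_pair_keeps_graph_connected(self):
        # two fused rings: removing two bonds of one ring leaves a detour
        mol = parse_structure("C1CC2CCC1C2", "smiles")
        root = as_root_fragment(mol)
        bridges_free = cleavable_bonds(root)
        found_empty = False
        for k1, k2 in combinations(bridges_free, 2):
            try:
                if cleave(root, (k1, k2)) == []:
                    found_empty = True
                    break
            except ValueError:
                continue
        assert found_empty

    def test_linear_cleave_of_ring_bond_rejected(self, toy):
        root = as_root_fragment(toy["cyclohexane"])
        with pytest.raises(ValueError, match="ring"):
            cleave(root, 0)

    def test_unknown_bond_rejected(self, toy):
        root = as_root_fragment(toy["propane"])
        with pytest.raises(ValueError):
            cleave(root, 99)


class TestRedundancyKey:
    def test_propane_methyl_ends(self, toy):
        root = as_root_fragment(toy["propane"])
        methyls = [
            child
            for k in cleavable_bonds(root)
            for child in cleave(root, k)
            if str(child.formula) == "CH3"
        ]
        assert len(methyls) == 2
        a, b = methyls
        assert redundancy_key(a, "atom_id") != redundancy_key(b, "atom_id")
        assert redundancy_key(a, "molecular_formula") == redundancy_key(b, "molecular_formula")
        assert redundancy_key(a, "isomorphism") == redundancy_key(b, "isomorphism")

    def test_unknown_mode_rejected(self, toy):
        root = as_root_fragment(toy["propane"])
        with pytest.raises(ValueError):
            redundancy_key(root, "hashing")


class TestEnumerate:
    def test_propane_depth1(self, toy):
        frags = enumerate_fragments(toy["propane"], FragmenterConfig(max_depth=1, min_mass=10))
        assert {str(f.formula) for f in frags} == {"C2H5", "CH3"}

    def test_cyclohexane_depth1(self, toy):
        frags = enumerate_fragments(toy["cyclohexane"], FragmenterConfig(max_depth=1, min_mass=10))
        assert {str(f.formula) for f in frags} == {"C5H10", "C4H8", "C3H6", "C2H4", "CH2"}

    def test_methane_yields_nothing(self):
        assert enumerate_fragments(parse_structure("C", "smiles")) == []

    @pytest.mark.parametrize("name", ["ethanol", "phenol", "alanine"])
    def test_depth_monotonicity(self, toy, name):
        d1 = enumerate_fragments(toy[name], FragmenterConfig(max_depth=1, min_mass=10))
        d2 = enumerate_fragments(toy[name], FragmenterConfig(max_depth=2, min_mass=10))
        assert {f.formula for f in d1} <= {f.formula for f in d2}

    @pytest.mark.parametrize("name", ["phenol", "glucose"])
    def test_raising_min_mass_never_adds_fragments(self, toy, name):
        low = enumerate_fragments(toy[name], FragmenterConfig(max_depth=2, min_mass=10))
        high = enumerate_fragments(toy[name], FragmenterConfig(max_depth=2, min_mass=40))
        assert {f.formula for f in high} <= {f.formula for f in low}
        assert len(high) <= len(low)
        assert all(f.neutral_mass >= 40 for f in high)

    def test_linear_cut_conserves_composition(self, toy):
        for name in ["ethanol", "alanine", "methionine"]:
            root = as_root_fragment(toy[name])
            parent_formula = formula_of(toy[name])
            bridges = [
                k for k in cleavable_bonds(root)
                if len(cleave(root, k)) == 2
            ]
            for k in bridges:
                a, b = cleave(root, k)
                assert a.formula + b.formula == parent_formula

    def test_deterministic_order(self, toy):
        a = enumerate_fragments(toy["naringenin"], FragmenterConfig(max_depth=2, min_mass=30))
        b = enumerate_fragments(toy["naringenin"], FragmenterConfig(max_depth=2, min_mass=30))
        assert [(f.atom_mask, f.broken_bonds) for f in a] == [
            (f.atom_mask, f.broken_bonds) for f in b
        ]

    def test_duplicate_keeps_lower_bde(self, toy):
        frags = enumerate_fragments(
            toy["cyclohexane"], FragmenterConfig(max_depth=2, min_mass=10)
        )
        c4 = next(f for f in frags if str(f.formula) == "C4H8")
        # one ring-pair cut (2 x C-C) is the cheapest route to any piece
        assert c4.bde == pytest.approx(2 * 348.0)


class TestBDETable:
    def test_lookup_is_symmetric(self):
        t = BDETable.default_table()
        assert t.lookup("C", "O", 1) == t.lookup("O", "C", 1)

    def test_single_vs_double_bond(self):
        t = BDETable.default_table()
        assert t.lookup("C", "C", 2) > t.lookup("C", "C", 1)

    def test_unlisted_pair_uses_default_and_warns(self, caplog):
        t = BDETable.default_table()
        with caplog.at_level("WARNING"):
            v = t.lookup("Si", "Si", 1)
        assert v == t.default
        assert "Si" in caplog.text
        caplog.clear()
        with caplog.at_level("WARNING"):
            t.lookup("Si", "Si", 1)  # second lookup stays quiet
        assert not caplog.records

    def test_bundled_cc_value(self, toy):
        t = BDETable.default_table()
        mol = toy["propane"]
        assert bde_of_bond(mol.bonds[0], t, mol) == 348.0

    def test_nonpositive_enthalpy_rejected(self):
        with pytest.raises(ValueError):
            BDETable({(frozenset(("C", "C")), 1): -1.0})
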