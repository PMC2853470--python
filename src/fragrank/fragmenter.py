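"""Breadth-first combinatorial bond disconnection.

Fragments of a candidate are generated level by level: one cleavage event
(one acyclic bond, or one pair of ring bonds removed simultaneously) per
tree-depth level.  Hydrogens travel with their heavy atom; cut sites gain
no hydrogen.  Each fragment records the bonds broken on its path from the
root and the cumulative bond dissociation enthalpy (BDE) of those breaks,
which later serves as a plausibility penalty in scoring.

Atom subsets are held as integer bitmasks over the parent molecule's atom
indices, which keeps connectivity tests and subgraph bookkeeping cheap
even for fused ring systems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Union

from rdkit import Chem

from .chem_core import Bond, Formula, Molecule
from .constants import MONOISOTOPIC_MASS

logger = logging.getLogger(__name__)

__all__ = [
    "BDETable",
    "FragmenterConfig",
    "Fragment",
    "cleavable_bonds",
    "cleave",
    "redundancy_key",
    "enumerate_fragments",
    "bde_of_bond",
    "as_root_fragment",
    "fragment_to_smiles",
]

REDUNDANCY_MODES = ("isomorphism", "atom_id", "molecular_formula")

#: Fallback minimum fragment mass (Da) when no query peak list sets one.
DEFAULT_MIN_MASS = 30.0


class BDETable:
    """Standard bond dissociation enthalpies keyed by element pair and order.

    Pairs are unordered; an unlisted pair falls back to the table default
    (logged once per pair).
    """

    def __init__(self, entries: dict[tuple[frozenset, int], float], default: float = 348.0):
        for key, value in entries.items():
            if value <= 0:
                raise ValueError(f"non-positive enthalpy for {key}")
        self.entries = dict(entries)
        self.default = default
        self._warned: set = set()

    @classmethod
    def from_text(cls, text: str, default: float = 348.0) -> "BDETable":
        entries: dict[tuple[frozenset, int], float] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                e1, e2, order, value = line.split()
                entries[(frozenset((e1, e2)), int(order))] = float(value)
            except ValueError as exc:
                raise ValueError(f"bad bond-energy line {lineno}: {line!r}") from exc
        return cls(entries, default=default)

    @classmethod
    def default_table(cls) -> "BDETable":
        text = resources.files("fragrank.data").joinpath("bond_energies.tsv").read_text()
        return cls.from_text(text)

    def lookup(self, element_a: str, element_b: str, order: int) -> float:
        key = (frozenset((element_a, element_b)), order)
        if key in self.entries:
            return self.entries[key]
        if key not in self._warned:
            self._warned.add(key)
            logger.warning(
                "no bond enthalpy for %s-%s order %d; using default %.0f kJ/mol",
                element_a, element_b, order, self.default,
            )
        return self.default

    def max_value(self) -> float:
        return max(self.entries.values(), default=self.default)


@dataclass
class FragmenterConfig:
    """Knobs of the combinatorial fragmenter.

    ``min_mass`` of ``None`` means: take the smallest implied neutral mass
    of the query peak list, or 30 Da when fragmenting without a spectrum.
    """

    max_depth: int = 2
    min_mass: Optional[float] = None
    redundancy_mode: str = "molecular_formula"
    apply_rules_to_fragments: bool = False
    include_root: bool = False

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_mass is not None and self.min_mass <= 0:
            raise ValueError("min_mass must be > 0")
        if self.redundancy_mode not in REDUNDANCY_MODES:
            raise ValueError(
                f"unknown redundancy mode {self.redundancy_mode!r}; expected one of {REDUNDANCY_MODES}"
            )


class _Graph:
    """Bitmask-adjacency view of a molecule, shared by all its fragments."""

    __slots__ = ("molecule", "n", "adj", "bonds", "atom_mass", "elements", "bond_bits")

    def __init__(self, molecule: Molecule):
        self.molecule = molecule
        self.n = molecule.n_atoms
        self.adj = [0] * self.n
        self.bonds = list(molecule.bonds)
        for bond in self.bonds:
            self.adj[bond.a] |= 1 << bond.b
            self.adj[bond.b] |= 1 << bond.a
        h = MONOISOTOPIC_MASS["H"]
        self.atom_mass = [
            MONOISOTOPIC_MASS[a.element] + a.n_hydrogens * h for a in molecule.atoms
        ]
        self.elements = [a.element for a in molecule.atoms]
        self.bond_bits = [(1 << b.a) | (1 << b.b) for b in self.bonds]


@dataclass(frozen=True)
class Fragment:
    """A connected heavy-atom subgraph of a candidate, with provenance."""

    graph: _Graph = field(repr=False, compare=False)
    atom_mask: int
    broken_bonds: tuple[int, ...]
    bde: float
    depth: int
    loss_tag: Optional[str] = None

    @property
    def parent_id(self) -> str:
        return self.graph.molecule.id

    @property
    def atom_indices(self) -> tuple[int, ...]:
        mask, out, i = self.atom_mask, [], 0
        while mask:
            if mask & 1:
                out.append(i)
            mask >>= 1
            i += 1
        return tuple(out)

    @property
    def formula(self) -> Formula:
        counts: dict[str, int] = {}
        n_h = 0
        mol = self.graph.molecule
        for i in self.atom_indices:
            atom = mol.atoms[i]
            counts[atom.element] = counts.get(atom.element, 0) + 1
            n_h += atom.n_hydrogens
        if n_h:
            counts["H"] = counts.get("H", 0) + n_h
        return Formula(counts)

    @property
    def neutral_mass(self) -> float:
        am = self.graph.atom_mass
        return sum(am[i] for i in self.atom_indices)

    @property
    def net_charge(self) -> int:
        mol = self.graph.molecule
        return sum(mol.atoms[i].charge for i in self.atom_indices)

    def induced_bonds(self) -> list[int]:
        """Bond ids of the parent molecule present in this fragment."""
        mask = self.atom_mask
        broken = set(self.broken_bonds)
        return [
            k
            for k, bits in enumerate(self.graph.bond_bits)
            if (bits & mask) == bits and k not in broken
        ]

    def __repr__(self) -> str:
        return (
            f"Fragment({self.parent_id}, {self.formula}, depth={self.depth}, "
            f"bde={self.bde:.0f})"
        )


def as_root_fragment(molecule: Molecule, loss_tag: Optional[str] = None) -> Fragment:
    """Wrap an intact molecule as the depth-0 root of its fragmentation tree."""
    graph = _Graph(molecule)
    return Fragment(graph, (1 << graph.n) - 1, (), 0.0, 0, loss_tag=loss_tag)


# ---------------------------------------------------------------------------
# graph machinery


def _component(adj: list[int], mask: int, start_bit: int) -> int:
    """Connected component of ``start_bit`` within ``mask`` (bit BFS)."""
    comp = start_bit
    frontier = start_bit
    while frontier:
        nxt = 0
        f = frontier
        while f:
            low = f & -f
            nxt |= adj[low.bit_length() - 1]
            f ^= low
        nxt &= mask & ~comp
        comp |= nxt
        frontier = nxt
    return comp


def _bridges(fragment: Fragment, bond_ids: list[int]) -> set[int]:
    """Bridge bonds of the fragment's induced subgraph (iterative Tarjan)."""
    graph = fragment.graph
    nodes = fragment.atom_indices
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in nodes}
    for k in bond_ids:
        b = graph.bonds[k]
        adj[b.a].append((b.b, k))
        adj[b.b].append((b.a, k))
    disc: dict[int, int] = {}
    low: dict[int, int] = {}
    bridges: set[int] = set()
    timer = 0
    for root in nodes:
        if root in disc:
            continue
        stack: list[tuple[int, int, int]] = [(root, -1, 0)]  # node, via-bond, edge ptr
        disc[root] = low[root] = timer
        timer += 1
        while stack:
            node, via, ptr = stack[-1]
            if ptr < len(adj[node]):
                stack[-1] = (node, via, ptr + 1)
                nb, k = adj[node][ptr]
                if k == via:
                    continue
                if nb in disc:
                    low[node] = min(low[node], disc[nb])
                else:
                    disc[nb] = low[nb] = timer
                    timer += 1
                    stack.append((nb, k, 0))
            else:
                stack.pop()
                if stack:
                    parent = stack[-1][0]
                    low[parent] = min(low[parent], low[node])
                    if low[node] > disc[parent]:
                        bridges.add(via)
    return bridges


def cleavable_bonds(f: Union[Molecule, Fragment]) -> list[int]:
    """Bond ids between two heavy atoms of the (fragment) graph.

    Bonds to hydrogen can never appear: hydrogens are not graph nodes.
    """
    if isinstance(f, Molecule):
        f = as_root_fragment(f)
    return f.induced_bonds()


def _children(fragment: Fragment, removed: tuple[int, ...], step_bde: float) -> list[Fragment]:
    graph = fragment.graph
    mask = fragment.atom_mask
    # adjacency restricted to the fragment minus the removed bonds
    cut_adj = list(graph.adj)
    for k in removed:
        b = graph.bonds[k]
        cut_adj[b.a] &= ~(1 << b.b)
        cut_adj[b.b] &= ~(1 << b.a)
    first = graph.bonds[removed[0]]
    comp_a = _component(cut_adj, mask, 1 << first.a)
    if comp_a == mask:
        return []
    comp_b = mask & ~comp_a
    broken = fragment.broken_bonds + tuple(sorted(removed))
    bde = fragment.bde + step_bde
    depth = fragment.depth + 1
    return [
        Fragment(graph, comp, broken, bde, depth, loss_tag=fragment.loss_tag)
        for comp in (comp_a, comp_b)
    ]


def bde_of_bond(bond: Bond, table: BDETable, molecule: Molecule) -> float:
    """Dissociation enthalpy of one bond, by element pair and bond order."""
    return table.lookup(
        molecule.atoms[bond.a].element, molecule.atoms[bond.b].element, bond.order
    )


def cleave(
    f: Fragment,
    bonds: Union[int, tuple[int, int]],
    table: Optional[BDETable] = None,
) -> list[Fragment]:
    """Split a fragment at one acyclic bond or one ring-bond pair.

    An acyclic (bridge) bond yields the two resulting components; a
    ring-bond pair whose joint removal leaves the graph connected yields
    the empty list.  Children sit one tree-depth level below the parent
    and accumulate the enthalpy of every bond cut in this step.
    """
    if table is None:
        table = BDETable.default_table()
    present = set(f.induced_bonds())
    molecule = f.graph.molecule
    if isinstance(bonds, int):
        if bonds not in present:
            raise ValueError(f"bond {bonds} is not part of the fragment")
        bridges = _bridges(f, sorted(present))
        if bonds not in bridges:
            raise ValueError(f"bond {bonds} is in a ring; cleave it as a ring-bond pair")
        step = bde_of_bond(molecule.bonds[bonds], table, molecule)
        return _children(f, (bonds,), step)
    b1, b2 = bonds
    if b1 not in present or b2 not in present:
        raise ValueError(f"bond pair {bonds} is not part of the fragment")
    if b1 == b2:
        raise ValueError("ring cleavage needs two distinct bonds")
    bridges = _bridges(f, sorted(present))
    if b1 in bridges or b2 in bridges:
        raise ValueError(f"bond pair {bonds} contains a non-ring bond")
    step = bde_of_bond(molecule.bonds[b1], table, molecule) + bde_of_bond(
        molecule.bonds[b2], table, molecule
    )
    return _children(f, (b1, b2), step)


def _cleavage_events(fragment: Fragment, table: BDETable) -> list[tuple[tuple[int, ...], float]]:
    """All single cleavage events of a fragment, with their step enthalpy.

    An event is one bridge bond, or one unordered pair of ring (non-bridge)
    bonds whose joint removal disconnects the subgraph.  Ring pairs are not
    restricted to one perceived ring: a connectivity test decides validity,
    so fused systems are handled uniformly.
    """
    graph = fragment.graph
    molecule = graph.molecule
    bond_ids = fragment.induced_bonds()
    if not bond_ids:
        return []
    bridges = _bridges(fragment, bond_ids)
    events: list[tuple[tuple[int, ...], float]] = []
    for k in bond_ids:
        if k in bridges:
            events.append(((k,), bde_of_bond(molecule.bonds[k], table, molecule)))
    ring_bonds = [k for k in bond_ids if k not in bridges]
    ring_set = set(ring_bonds)
    for k1 in ring_bonds:
        # partners of k1: ring bonds that become bridges once k1 is removed
        new_bridges = _bridges(fragment, [k for k in bond_ids if k != k1])
        for k2 in new_bridges:
            if k2 in ring_set and k2 > k1:
                step = bde_of_bond(molecule.bonds[k1], table, molecule) + bde_of_bond(
                    molecule.bonds[k2], table, molecule
                )
                events.append(((k1, k2), step))
    return events


def redundancy_key(f: Fragment, mode: str):
    """Opaque duplicate-detection key under the named redundancy mode.

    ``molecular_formula`` conflates by elemental composition (cheapest,
    default), ``atom_id`` by the exact atom-index subset of the parent,
    ``isomorphism`` by canonical SMILES of the labelled subgraph.
    Among duplicates the fragment with the lower cumulative BDE is kept.
    """
    if mode == "molecular_formula":
        return f.formula
    if mode == "atom_id":
        return f.atom_mask
    if mode == "isomorphism":
        return fragment_to_smiles(f)
    raise ValueError(f"unknown redundancy mode {mode!r}; expected one of {REDUNDANCY_MODES}")


def fragment_to_smiles(f: Fragment) -> str:
    """Canonical SMILES of a fragment's heavy-atom subgraph.

    Open valences at cut sites are preserved as-is (no hydrogen is added),
    so the string is a faithful record of the subgraph, not necessarily a
    valence-complete molecule.
    """
    molecule = f.graph.molecule
    indices = f.atom_indices
    remap = {orig: k for k, orig in enumerate(indices)}
    rw = Chem.RWMol()
    for orig in indices:
        atom = molecule.atoms[orig]
        ra = Chem.Atom(atom.element)
        ra.SetFormalCharge(atom.charge)
        ra.SetNumExplicitHs(atom.n_hydrogens)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for k in f.induced_bonds():
        b = molecule.bonds[k]
        rw.AddBond(remap[b.a], remap[b.b], order_map[b.order])
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return Chem.MolToSmiles(mol)


def _sort_key(fragment: Fragment) -> tuple:
    return (-fragment.neutral_mass, str(fragment.formula), fragment.atom_mask)


def enumerate_fragments(
    candidate: Molecule,
    cfg: Optional[FragmenterConfig] = None,
    bde: Optional[BDETable] = None,
    min_mass: Optional[float] = None,
) -> list[Fragment]:
    """The fragmentation tree of a candidate, root excluded by default.

    Breadth-first: level d holds fragments reachable by exactly d cleavage
    events; generation stops at ``cfg.max_depth``.  Fragments lighter than
    the minimum mass are never created, and no two returned fragments share
    a redundancy key.  Output order is deterministic (mass descending,
    then formula / atom-subset key).
    """
    cfg = cfg or FragmenterConfig()
    bde = bde or BDETable.default_table()
    if min_mass is None:
        min_mass = cfg.min_mass if cfg.min_mass is not None else DEFAULT_MIN_MASS
    root = as_root_fragment(candidate)
    seen: dict = {}
    for _level in _levels(root, cfg, bde, min_mass, seen):
        pass
    result = list(seen.values())
    if cfg.include_root:
        result.append(root)
    result.sort(key=_sort_key)
    return result


def _levels(
    root: Fragment,
    cfg: FragmenterConfig,
    bde: BDETable,
    min_mass: float,
    seen: dict,
    extra_roots: Iterable[Fragment] = (),
):
    """Generate fragment levels breadth-first, deduplicating as we go.

    ``seen`` maps redundancy key -> retained fragment and is updated in
    place (lower cumulative BDE wins among duplicates).  Yields the list
    of newly retained fragments per depth level; a consumer may stop early.
    ``min_mass`` may be a callable re-evaluated as generation proceeds
    (the dynamic cutoff that rises when the lightest peak is explained).
    """
    queue = [root, *extra_roots]
    for _depth in range(cfg.max_depth):
        fresh: list[Fragment] = []
        for fragment in queue:
            floor = min_mass() if callable(min_mass) else min_mass
            if fragment.neutral_mass < floor:
                continue
            for removed, step in _cleavage_events(fragment, bde):
                for child in _children(fragment, removed, step):
                    if child.neutral_mass < floor:
                        continue
                    key = redundancy_key(child, cfg.redundancy_mode)
                    prev = seen.get(key)
                    if prev is None:
                        seen[key] = child
                        fresh.append(child)
                    elif child.bde < prev.bde:
                        # keep the energetically cheaper representative
                        seen[key] = child
                        for i, f in enumerate(fresh):
                            if redundancy_key(f, cfg.redundancy_mode) == key:
                                fresh[i] = child
                                break
        fresh.sort(key=_sort_key)
        yield fresh
        queue = fresh
        if not queue:
            break
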