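"""Neutral-loss rules for rearrangements that bond disconnection cannot reach.

A loss such as water is not a substructure: it forms when a hydroxyl group
and a hydrogen from a *different*, topologically nearby atom leave
together.  Each rule names a heavy-atom motif (the part split off), the
neutral-loss composition, and the maximum bond-path distance at which a
donor hydrogen may sit.  Applying a rule yields a derived structure whose
composition is the parent's minus the loss.

The motif registry maps the pattern names of the bundled rule table to
matcher functions on the heavy-atom graph; new motifs can be registered
to extend the rule file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional

from .chem_core import Atom, Bond, Formula, Molecule, formula_of, monoisotopic_mass

logger = logging.getLogger(__name__)

__all__ = [
    "NeutralLossRule",
    "default_rules",
    "load_rules",
    "find_loss_sites",
    "apply_rules",
    "MOTIF_REGISTRY",
]


@dataclass(frozen=True)
class NeutralLossRule:
    """One rearrangement rule.

    ``ion_modes`` limits applicability (e.g. formic acid loss is a
    positive-mode rule); ``max_distance`` bounds the bond-path distance
    between the motif's attachment atom and the hydrogen donor.
    """

    ion_modes: frozenset[str]
    exact_mass: float
    pattern: str
    loss_formula: Formula
    max_distance: int

    def __post_init__(self):
        if self.max_distance < 1:
            raise ValueError("max_distance must be >= 1")
        expected = monoisotopic_mass(self.loss_formula)
        if abs(expected - self.exact_mass) > 0.0005:
            raise ValueError(
                f"rule {self.pattern}: exact mass {self.exact_mass} does not match "
                f"loss formula {self.loss_formula} ({expected:.4f})"
            )


# ---------------------------------------------------------------------------
# motif matchers
#
# Each matcher returns (pattern_atom_indices, attachment_atom) occurrences.
# The pattern atoms are removed on application; their attached hydrogens
# must sum to (loss H count - 1), the donor supplying the final hydrogen.


def _adjacency(m: Molecule) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(m.n_atoms)}
    for b in m.bonds:
        adj[b.a].append(b.b)
        adj[b.b].append(b.a)
    return adj


def _match_hydroxyl(m: Molecule) -> list[tuple[tuple[int, ...], int]]:
    """-OH: terminal oxygen carrying exactly one hydrogen."""
    adj = _adjacency(m)
    out = []
    for i, atom in enumerate(m.atoms):
        if atom.element == "O" and atom.n_hydrogens == 1 and len(adj[i]) == 1:
            out.append(((i,), adj[i][0]))
    return out


def _match_amine(m: Molecule) -> list[tuple[tuple[int, ...], int]]:
    """-NH2: terminal nitrogen carrying two hydrogens."""
    adj = _adjacency(m)
    out = []
    for i, atom in enumerate(m.atoms):
        if atom.element == "N" and atom.n_hydrogens == 2 and len(adj[i]) == 1:
            out.append(((i,), adj[i][0]))
    return out


def _match_nitrile(m: Molecule) -> list[tuple[tuple[int, ...], int]]:
    """-CN: terminal bare nitrogen on a hydrogen-free carbon (HCN loss)."""
    adj = _adjacency(m)
    out = []
    for i, atom in enumerate(m.atoms):
        if atom.element != "N" or atom.n_hydrogens != 0 or len(adj[i]) != 1:
            continue
        c = adj[i][0]
        c_atom = m.atoms[c]
        if c_atom.element == "C" and c_atom.n_hydrogens == 0 and len(adj[c]) == 2:
            anchor = next(j for j in adj[c] if j != i)
            out.append(((c, i), anchor))
    return out


def _match_formyl(m: Molecule) -> list[tuple[tuple[int, ...], int]]:
    """-C(H)=O: aldehyde-like carbon with a bare terminal oxygen (CH2O loss)."""
    adj = _adjacency(m)
    out = []
    for i, atom in enumerate(m.atoms):
        if atom.element != "C" or atom.n_hydrogens != 1 or len(adj[i]) != 2:
            continue
        for o in adj[i]:
            o_atom = m.atoms[o]
            if o_atom.element == "O" and o_atom.n_hydrogens == 0 and len(adj[o]) == 1:
                anchor = next(j for j in adj[i] if j != o)
                out.append(((i, o), anchor))
                break
    return out


def _match_carboxyl(m: Molecule) -> list[tuple[tuple[int, ...], int]]:
    """-COOH: carbon bearing one bare and one hydroxyl oxygen (HCOOH loss)."""
    adj = _adjacency(m)
    out = []
    for i, atom in enumerate(m.atoms):
        if atom.element != "C" or atom.n_hydrogens != 0 or len(adj[i]) != 3:
            continue
        bare = [o for o in adj[i] if m.atoms[o].element == "O" and m.atoms[o].n_hydrogens == 0 and len(adj[o]) == 1]
        hydroxyl = [o for o in adj[i] if m.atoms[o].element == "O" and m.atoms[o].n_hydrogens == 1 and len(adj[o]) == 1]
        if bare and hydroxyl:
            anchor = next(j for j in adj[i] if j not in (bare[0], hydroxyl[0]))
            out.append(((i, bare[0], hydroxyl[0]), anchor))
    return out


#: pattern name (as used in the rule file) -> matcher on the heavy-atom graph
MOTIF_REGISTRY: dict[str, Callable[[Molecule], list[tuple[tuple[int, ...], int]]]] = {
    "OH": _match_hydroxyl,
    "NH2": _match_amine,
    "CN": _match_nitrile,
    "COH": _match_formyl,
    "COOH": _match_carboxyl,
}


# ---------------------------------------------------------------------------
# rule I/O


def load_rules(text: str) -> list[NeutralLossRule]:
    """Parse a rule table: ion_modes, exact mass, pattern, loss formula, distance."""
    rules = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            modes_s, mass_s, pattern, loss_s, dist_s = line.split()
        except ValueError as exc:
            raise ValueError(f"bad neutral-loss rule on line {lineno}: {line!r}") from exc
        modes = frozenset(
            {"+": "positive", "-": "negative"}[c] for c in modes_s
        )
        rules.append(
            NeutralLossRule(
                ion_modes=modes,
                exact_mass=float(mass_s),
                pattern=pattern,
                loss_formula=Formula.from_string(loss_s),
                max_distance=int(dist_s),
            )
        )
    return rules


def default_rules() -> list[NeutralLossRule]:
    """The bundled rule table: H2O, HCN, NH3, CH2O (both modes), HCOOH (+)."""
    text = resources.files("fragrank.data").joinpath("neutral_losses.tsv").read_text()
    return load_rules(text)


# ---------------------------------------------------------------------------
# application


def find_loss_sites(m: Molecule, r: NeutralLossRule) -> list[tuple[tuple[int, ...], int]]:
    """All (pattern atom set, donor atom) applications of one rule.

    A donor is a carbon bearing at least one hydrogen, outside the
    pattern, whose shortest bond-path distance from the pattern's
    attachment atom is at least 1 and at most the rule's maximum
    distance.  Only C-H hydrogens migrate in these rearrangements;
    abstracting an O-H or N-H hydrogen would leave an under-coordinated
    heteroatom rather than the observed closed-shell loss.
    """
    matcher = MOTIF_REGISTRY.get(r.pattern)
    if matcher is None:
        raise KeyError(f"no motif registered for pattern {r.pattern!r}")
    sites = []
    for pattern_atoms, attachment in matcher(m):
        for donor in range(m.n_atoms):
            if (
                donor in pattern_atoms
                or m.atoms[donor].element != "C"
                or m.atoms[donor].n_hydrogens < 1
            ):
                continue
            dist = m.shortest_path_length(attachment, donor)
            if dist is not None and 1 <= dist <= r.max_distance:
                sites.append((pattern_atoms, donor))
    return sites


def _remove_pattern(m: Molecule, pattern_atoms: tuple[int, ...], donor: int) -> Optional[Molecule]:
    """Copy of ``m`` with the pattern atoms and one donor hydrogen removed.

    Returns None when the removal disconnects the heavy-atom graph.
    """
    keep = [i for i in range(m.n_atoms) if i not in pattern_atoms]
    remap = {orig: k for k, orig in enumerate(keep)}
    atoms = []
    for orig in keep:
        a = m.atoms[orig]
        if orig == donor:
            a = Atom(a.element, a.charge, a.n_hydrogens - 1)
        atoms.append(a)
    bonds = [
        Bond(remap[b.a], remap[b.b], b.order, b.in_ring)
        for b in m.bonds
        if b.a in remap and b.b in remap
    ]
    derived = Molecule(atoms, bonds)
    if not derived.is_connected():
        return None
    return derived


def apply_rules(
    m: Molecule,
    rules: Optional[list[NeutralLossRule]] = None,
    ion_mode: str = "positive",
) -> list[Molecule]:
    """Derived structures of ``m`` under all applicable neutral-loss rules.

    One loss per derived structure; results are deduplicated by elemental
    composition, and removals that would disconnect the heavy-atom graph
    are skipped.
    """
    if rules is None:
        rules = default_rules()
    derived: list[Molecule] = []
    seen_formulas: set[Formula] = set()
    for rule in rules:
        if ion_mode not in rule.ion_modes:
            continue
        for pattern_atoms, donor in find_loss_sites(m, rule):
            child = _remove_pattern(m, pattern_atoms, donor)
            if child is None:
                logger.info(
                    "%s: skipping %s loss at atoms %s (would disconnect the graph)",
                    m.id, rule.loss_formula, pattern_atoms,
                )
                continue
            f = formula_of(child)
            if f in seen_formulas:
                continue
            seen_formulas.add(f)
            child.id = f"{m.id}|-{rule.loss_formula}"
            child.name = m.name
            child.derived_from = str(rule.loss_formula)
            derived.append(child)
    return derived
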