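"""Structure I/O, molecular graph model, monoisotopic mass, fingerprints.

The in-memory molecule is a heavy-atom graph: hydrogens are stored as
per-atom counts rather than explicit nodes, because individual hydrogens
never take part in combinatorial bond disconnection.  RDKit is used for
parsing and writing the standard formats (MDL mol/SDF, SMILES, InChI) and
for the connectivity fingerprint; all downstream graph work runs on the
plain :class:`Molecule` container.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs  # noqa: F401  (re-exported convenience)

from .constants import MONOISOTOPIC_MASS

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "Formula",
    "Molecule",
    "Atom",
    "Bond",
    "Fingerprint",
    "ParseError",
    "parse_structure",
    "parse_structures",
    "monoisotopic_mass",
    "formula_of",
    "fingerprint",
    "tanimoto",
    "molecule_to_smiles",
    "write_sdf",
]


class ParseError(ValueError):
    """Raised when a structure record cannot be parsed."""


class UnknownElementError(KeyError):
    """Raised when a formula contains an element without a bundled mass."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """An elemental composition: element symbol -> positive count.

    Equality is order-independent; hydrogens are an ordinary element here.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(counts)
        for el, n in items.items():
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el!r} must be a non-negative int, got {n!r}")
        self._counts: dict[str, int] = {el: n for el, n in items.items() if n > 0}

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse a plain Hill-style formula string like ``C15H12O5``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ParseError(f"cannot parse formula {text!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise ParseError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise ValueError(f"subtraction would make {el} negative")
        return Formula(counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        parts = []
        for el in ("C", "H"):
            if el in self._counts:
                n = self._counts[el]
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(self._counts):
            if el in ("C", "H"):
                continue
            n = self._counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"Formula({str(self)!r})"


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element symbol, formal charge, attached hydrogens."""

    element: str
    charge: int = 0
    n_hydrogens: int = 0


@dataclass(frozen=True)
class Bond:
    """A bond between two heavy atoms, by atom index.

    ``order`` is 1, 2 or 3 (aromatic systems are kekulized on input so
    every bond carries an integral order usable for enthalpy lookup).
    """

    a: int
    b: int
    order: int = 1
    in_ring: bool = False


class Molecule:
    """A connected heavy-atom molecular graph with a stable identifier."""

    def __init__(
        self,
        atoms: list[Atom],
        bonds: list[Bond],
        id: str = "",
        name: Optional[str] = None,
        rdmol: Optional[Chem.Mol] = None,
        derived_from: Optional[str] = None,
    ):
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        self.id = id
        self.name = name
        #: neutral-loss rule that produced this structure, if any
        self.derived_from = derived_from
        self._rdmol = rdmol

    # -- construction -------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, id: str = "", name: Optional[str] = None) -> "Molecule":
        mol = Chem.Mol(mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        Chem.GetSymmSSSR(mol)
        atoms = [
            Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in mol.GetAtoms()
        ]
        bonds = [
            Bond(
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                int(round(b.GetBondTypeAsDouble())),
                b.IsInRing(),
            )
            for b in mol.GetBonds()
        ]
        if name is None and mol.HasProp("_Name") and mol.GetProp("_Name"):
            name = mol.GetProp("_Name")
        return cls(atoms, bonds, id=id, name=name, rdmol=mol)

    def to_rdkit(self) -> Chem.Mol:
        """An RDKit molecule with explicit hydrogen counts.

        The result is cached; for molecules built directly from a graph it
        is reconstructed with fixed hydrogen counts (no implicit valence).
        """
        if self._rdmol is None:
            rw = Chem.RWMol()
            for atom in self.atoms:
                ra = Chem.Atom(atom.element)
                ra.SetFormalCharge(atom.charge)
                ra.SetNumExplicitHs(atom.n_hydrogens)
                ra.SetNoImplicit(True)
                rw.AddAtom(ra)
            order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
            for bond in self.bonds:
                rw.AddBond(bond.a, bond.b, order_map[bond.order])
            mol = rw.GetMol()
            try:
                Chem.SanitizeMol(mol)
            except Exception:  # radicals / exotic valence: keep an unsanitized graph
                mol.UpdatePropertyCache(strict=False)
                Chem.FastFindRings(mol)
            self._rdmol = mol
        return self._rdmol

    # -- graph queries -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a == idx:
                out.append(b.b)
            elif b.b == idx:
                out.append(b.a)
        return out

    def heavy_degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    def is_connected(self) -> bool:
        if not self.atoms:
            return True
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for b in self.bonds:
            adj[b.a].append(b.b)
            adj[b.b].append(b.a)
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == len(self.atoms)

    def shortest_path_length(self, a: int, b: int) -> Optional[int]:
        """Unweighted shortest bond-path length between two atoms."""
        if a == b:
            return 0
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for bd in self.bonds:
            adj[bd.a].append(bd.b)
            adj[bd.b].append(bd.a)
        dist = {a: 0}
        frontier = [a]
        while frontier:
            nxt = []
            for i in frontier:
                for j in adj[i]:
                    if j not in dist:
                        dist[j] = dist[i] + 1
                        if j == b:
                            return dist[j]
                        nxt.append(j)
            frontier = nxt
        return None

    def net_charge(self) -> int:
        return sum(a.charge for a in self.atoms)

    def __repr__(self) -> str:
        return f"Molecule(id={self.id!r}, formula={formula_of(self)})"


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary structural fingerprint."""

    bits: np.ndarray = field(compare=False)

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    def __len__(self) -> int:
        return len(self.bits)


# ---------------------------------------------------------------------------
# parsing / writing


def _rdkit_from_text(text: str, format: str) -> Chem.Mol:
    fmt = format.lower()
    if fmt in ("mol", "sdf"):
        mol = Chem.MolFromMolBlock(text, removeHs=True)
    elif fmt == "smiles":
        mol = Chem.MolFromSmiles(text.strip())
    elif fmt == "inchi":
        mol = Chem.MolFromInchi(text.strip())
    else:
        raise ParseError(f"unknown structure format {format!r}")
    if mol is None:
        head = text.strip().splitlines()[0][:60] if text.strip() else "<empty>"
        raise ParseError(f"could not parse {fmt} record starting {head!r}")
    return mol


def parse_structure(text: str, format: str, id: str = "", name: Optional[str] = None) -> Molecule:
    """Parse a single structure record (``sdf``/``mol``/``smiles``/``inchi``).

    Hydrogen counts are populated explicitly and ring membership perceived.
    A multi-record SDF is handled by :func:`parse_structures`.
    """
    if format.lower() == "sdf":
        mols = parse_structures(text, "sdf")
        if not mols:
            raise ParseError("SDF text contains no parseable record")
        mol = mols[0]
        if id:
            mol.id = id
        if name:
            mol.name = name
        return mol
    mol = _rdkit_from_text(text, format)
    return Molecule.from_rdkit(mol, id=id, name=name)


def parse_structures(text: str, format: str = "sdf") -> list[Molecule]:
    """Parse a multi-record SDF string into a list of molecules.

    Record ids are taken from the MDL title line when present, otherwise
    ``record-<k>``.  Unparseable records are skipped with a warning.
    """
    if format.lower() != "sdf":
        raise ParseError("parse_structures supports only multi-record SDF input")
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, removeHs=True)
    out: list[Molecule] = []
    for k, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unparseable SDF record %d", k + 1)
            continue
        rec_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record-{k + 1}"
        out.append(Molecule.from_rdkit(mol, id=rec_id))
    return out


def molecule_to_smiles(m: Molecule) -> str:
    """Canonical SMILES of a molecule (or of a fragment's rebuilt graph)."""
    mol = m.to_rdkit()
    return Chem.MolToSmiles(mol)


def write_sdf(molecules: Iterable[Molecule]) -> str:
    """Serialize molecules to a multi-record SDF string."""
    chunks = []
    for m in molecules:
        mol = Chem.Mol(m.to_rdkit())
        mol.SetProp("_Name", m.id)
        chunks.append(Chem.MolToMolBlock(mol, kekulize=True) + "$$$$\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# mass and composition


def monoisotopic_mass(f: Formula) -> float:
    """Monoisotopic (exact) mass of a composition, in Da.

    Sum over elements of count x mass of the most abundant isotope.
    """
    total = 0.0
    for el, n in f.items():
        try:
            total += n * MONOISOTOPIC_MASS[el]
        except KeyError:
            raise UnknownElementError(f"no monoisotopic mass for element {el!r}") from None
    return total


def formula_of(m) -> Formula:
    """Elemental composition of a molecule or fragment.

    Heavy atoms are counted from the graph; hydrogens from the per-atom
    attached-hydrogen counts.  Fragments expose a precomputed ``formula``.
    """
    if isinstance(m, Molecule):
        counts: dict[str, int] = {}
        n_h = 0
        for atom in m.atoms:
            counts[atom.element] = counts.get(atom.element, 0) + 1
            n_h += atom.n_hydrogens
        if n_h:
            counts["H"] = counts.get("H", 0) + n_h
        return Formula(counts)
    f = getattr(m, "formula", None)
    if f is not None:
        return f
    raise TypeError(f"cannot derive a formula from {type(m).__name__}")


# ---------------------------------------------------------------------------
# fingerprints


#: Fingerprint length (bits) for the default connectivity fingerprint.
FINGERPRINT_BITS = 2048


def fingerprint(m: Molecule, n_bits: int = FINGERPRINT_BITS) -> Fingerprint:
    """Connectivity-based, stereochemistry-insensitive path fingerprint.

    Stereoisomers map to identical bit vectors, which is what lets
    tied-rank structure clustering collapse them (similarity 1 >= 0.95).
    """
    fp = Chem.RDKFingerprint(m.to_rdkit(), fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return Fingerprint(arr.astype(bool))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| in [0, 1].

    Two all-zero fingerprints are defined as similarity 0 (with a warning):
    featureless inputs carry no evidence of structural identity.
    """
    if len(a) != len(b):
        raise ValueError("fingerprints have different lengths")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        logger.warning("tanimoto of two all-zero fingerprints; defining similarity 0")
        return 0.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union
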