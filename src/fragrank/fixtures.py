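"""Synthetic data: toy molecules, simulated spectra, decoy libraries.

Everything here is generated offline and deterministically, so the full
pipeline is testable without compound-database downloads.  The simulator
emits peaks at the protonated masses of a molecule's own in-silico
fragments (optionally mass-noised), which gives ground truth for
self-identification experiments; it does not attempt to model real
fragmentation intensities.  Decoys are constructed as random constitutional
isomers of the target (same elemental composition, rewired connectivity),
standing in for the many same-mass candidates a large compound database
returns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from rdkit import Chem

from .candidates import CandidateLibrary, library_from_molecules
from .chem_core import Atom, Bond, Molecule, formula_of, monoisotopic_mass, parse_structure
from .constants import PROTON_MASS
from .fragmenter import BDETable, FragmenterConfig, enumerate_fragments
from .rearrangements import apply_rules, default_rules
from .spectra import Peak, Spectrum

logger = logging.getLogger(__name__)

__all__ = ["TOY_MOLECULES", "SimulationConfig", "toy_molecule_set",
           "simulate_spectrum", "make_decoy_library"]


#: name, SMILES, formula, expected monoisotopic mass (Da).
#: Literature monoisotopic values, frozen here as fixture ground truth.
TOY_MOLECULES: list[tuple[str, str, str, float]] = [
    ("naringenin", "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c12", "C15H12O5", 272.0685),
    ("epicatechin", "Oc1cc(O)c2c(c1)O[C@@H](c1ccc(O)c(O)c1)[C@H](O)C2", "C15H14O6", 290.0790),
    ("ethanol", "CCO", "C2H6O", 46.0419),
    ("propane", "CCC", "C3H8", 44.0626),
    ("cyclohexane", "C1CCCCC1", "C6H12", 84.0939),
    ("benzene", "c1ccccc1", "C6H6", 78.0470),
    ("phenol", "Oc1ccccc1", "C6H6O", 94.0419),
    ("toluene", "Cc1ccccc1", "C7H8", 92.0626),
    ("pyridine", "c1ccncc1", "C5H5N", 79.0422),
    ("aniline", "Nc1ccccc1", "C6H7N", 93.0578),
    ("benzoic acid", "OC(=O)c1ccccc1", "C7H6O2", 122.0368),
    ("salicylic acid", "OC(=O)c1ccccc1O", "C7H6O3", 138.0317),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O", "C6H12O6", 180.0634),
    ("alanine", "CC(N)C(=O)O", "C3H7NO2", 89.0477),
    ("serine", "OCC(N)C(=O)O", "C3H7NO3", 105.0426),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "C8H10N4O2", 194.0804),
    ("acetone", "CC(C)=O", "C3H6O", 58.0419),
    ("acetic acid", "CC(=O)O", "C2H4O2", 60.0211),
    ("benzaldehyde", "O=Cc1ccccc1", "C7H6O", 106.0419),
    ("methionine", "CSCCC(N)C(=O)O", "C5H11NO2S", 149.0510),
    ("glycerol", "OCC(O)CO", "C3H8O3", 92.0473),
    ("vanillin", "COc1ccc(C=O)cc1O", "C8H8O3", 152.0473),
]


@dataclass
class SimulationConfig:
    """Conditions for one simulated identification experiment.

    Intensities are log-uniform over ``intensity_decades`` decades above
    ``intensity_floor``; mass noise is Gaussian with ``mass_noise_sigma``
    (0 by default: simulated peaks sit exactly on the fragment ion
    masses).  A fixed seed makes every output byte-identical.
    """

    seed: int = 0
    n_peaks: int = 6
    tree_depth: int = 2
    #: lower than the 30 Da matching default so that small fixture
    #: molecules (propane, ethanol) still yield a usable peak set
    min_fragment_mass: float = 14.0
    #: softness (kJ/mol) of the Boltzmann-like weight exp(-BDE/scale)
    #: used to sample fragments: collision-induced dissociation favours
    #: the energetically cheap cleavages, so the simulated peaks do too.
    #: Roughly two single-bond enthalpies by default.
    bde_softness: float = 700.0
    intensity_floor: float = 10.0
    intensity_decades: float = 2.0
    mass_noise_sigma: float = 0.0
    decoy_count: int = 100


def toy_molecule_set() -> list[Molecule]:
    """The curated fixture molecules, parsed, with names as ids."""
    return [parse_structure(smi, "smiles", id=name) for name, smi, _, _ in TOY_MOLECULES]


def simulate_spectrum(
    m: Molecule,
    cfg: SimulationConfig,
    bde: BDETable | None = None,
) -> Spectrum:
    """A positive-mode spectrum of k of the molecule's own fragments.

    Samples ``n_peaks`` distinct fragments from the enumeration at the
    configured depth and emits their protonated ion masses with random
    intensities.  The heaviest fragment is always included; the rest are
    drawn without replacement with probability proportional to
    ``exp(-BDE / bde_softness)``, mimicking the preference of
    collision-induced dissociation for energetically cheap cleavages.
    Molecules with fewer fragments than requested yield all of them,
    with a warning.
    """
    rng = np.random.default_rng(cfg.seed)
    fragments = enumerate_fragments(
        m,
        FragmenterConfig(max_depth=cfg.tree_depth, min_mass=cfg.min_fragment_mass),
        bde,
    )
    if not fragments:
        raise ValueError(f"{m.id}: no fragments above {cfg.min_fragment_mass} Da to simulate from")
    if len(fragments) < cfg.n_peaks:
        logger.warning(
            "%s: only %d fragments available for %d requested peaks",
            m.id, len(fragments), cfg.n_peaks,
        )
    k = min(cfg.n_peaks, len(fragments))
    # fragments are sorted by descending mass: index 0 is the heaviest
    rest = np.arange(1, len(fragments))
    weights = np.exp(-np.array([fragments[i].bde for i in rest]) / cfg.bde_softness)
    if weights.sum() == 0 or len(rest) == 0:
        drawn: list[int] = []
    else:
        drawn = rng.choice(
            rest, size=k - 1, replace=False, p=weights / weights.sum()
        ).tolist()
    chosen = [0] + sorted(int(i) for i in drawn)
    peaks = []
    for idx in chosen:
        mz = fragments[idx].neutral_mass + PROTON_MASS
        if cfg.mass_noise_sigma > 0:
            mz += rng.normal(0.0, cfg.mass_noise_sigma)
        intensity = cfg.intensity_floor * 10 ** rng.uniform(0.0, cfg.intensity_decades)
        peaks.append(Peak(mz, float(intensity)))
    precursor = monoisotopic_mass(formula_of(m)) + PROTON_MASS
    return Spectrum(peaks, ion_mode="positive", precursor_mz=precursor)


# ---------------------------------------------------------------------------
# decoy construction

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1}

#: A decoy may share at most this fraction of the target's in-silico
#: fragment evidence.  Beyond it the two structures look largely the
#: same to the matcher and the decoy is no usable negative control
#: (same-composition fragments are exactly what the score observes).
#: The overlap is measured in the score's own peak weighting (cubed
#: fragment mass), so sharing a few heavy compositions counts as much
#: as sharing many light ones.
MAX_SHARED_FRAGMENT_FRACTION = 0.5


def _canonical_smiles(mol: Molecule) -> str:
    """Aromaticity-normalized canonical SMILES for duplicate detection."""
    s = Chem.MolToSmiles(mol.to_rdkit())
    reparsed = Chem.MolFromSmiles(s)
    return Chem.MolToSmiles(reparsed) if reparsed is not None else s


def _random_isomer(elements: list[str], h_total: int, rng: np.random.Generator) -> Molecule | None:
    """One random connected graph with the given elemental composition.

    The bond-order sum is fixed by the hydrogen count
    (sum of valences - H) / 2; a random share of it is spent on double
    bonds so the decoy population mixes rings, branches and unsaturation
    like a real same-mass candidate list does.  Returns None when the
    composition admits no such graph or the randomized construction gets
    stuck (callers simply retry).
    """
    n = len(elements)
    if n < 2:
        return None
    try:
        val = [_VALENCE[e] for e in elements]
    except KeyError:
        return None
    order_sum2 = sum(val) - h_total  # twice the total bond order
    if order_sum2 % 2 or order_sum2 < 2 * (n - 1):
        return None
    total_order = order_sum2 // 2
    max_double = min(total_order - (n - 1), n // 2)
    n_double = int(rng.integers(0, max_double + 1)) if max_double > 0 else 0
    n_edges = total_order - n_double
    if n_edges < n - 1 or n_edges > n * (n - 1) // 2:
        return None
    order = rng.permutation(n)
    deg = [0] * n  # valence already consumed (bond orders)
    edges: set[tuple[int, int]] = set()
    placed = [int(order[0])]
    for raw in order[1:]:
        i = int(raw)
        open_sites = [
            p for p in placed
            if deg[p] < val[p] and not (elements[i] == "O" and elements[p] == "O")
        ]
        if not open_sites:
            return None
        p = open_sites[int(rng.integers(len(open_sites)))]
        edges.add((min(i, p), max(i, p)))
        deg[i] += 1
        deg[p] += 1
        placed.append(i)
    tries = 0
    while len(edges) < n_edges and tries < 50 * n_edges:
        tries += 1
        open_sites = [i for i in range(n) if deg[i] < val[i]]
        if len(open_sites) < 2:
            return None
        a, b = rng.choice(len(open_sites), size=2, replace=False)
        a, b = open_sites[int(a)], open_sites[int(b)]
        key = (min(a, b), max(a, b))
        if key in edges:
            continue
        # no peroxide-type linkages: O-O chains are not stable chemistry
        # and their weak bonds would distort the decoy energetics
        if elements[a] == "O" and elements[b] == "O":
            continue
        edges.add(key)
        deg[a] += 1
        deg[b] += 1
    if len(edges) < n_edges:
        return None
    bond_order = {e: 1 for e in sorted(edges)}
    tries = 0
    upgraded = 0
    while upgraded < n_double and tries < 50 * max(n_double, 1):
        tries += 1
        a, b = sorted(edges)[int(rng.integers(len(edges)))]
        if bond_order[(a, b)] == 1 and deg[a] < val[a] and deg[b] < val[b]:
            bond_order[(a, b)] = 2
            deg[a] += 1
            deg[b] += 1
            upgraded += 1
    if upgraded < n_double:
        return None
    atoms = [Atom(elements[i], 0, val[i] - deg[i]) for i in range(n)]
    g = nx.Graph(sorted(edges))
    bridge_set = set(frozenset(e) for e in nx.bridges(g))
    bonds = [
        Bond(a, b, bond_order[(a, b)], in_ring=frozenset((a, b)) not in bridge_set)
        for a, b in sorted(edges)
    ]
    return Molecule(atoms, bonds)


def _fragment_evidence(
    mol: Molecule,
    depth: int = 2,
    min_mass: float = 14.0,
    n_peaks: int = 6,
    bde_softness: float = 700.0,
) -> dict:
    """Formula -> expected scoring evidence of a molecule's fragments.

    Evidence of a fragment is its cubed neutral mass (the mass exponent
    of the peak weighting) times the probability that the simulator
    samples it: 1 for the heaviest fragment, roughly
    ``(n_peaks - 1) * exp(-BDE/softness) / Z`` for the rest.  Overlap
    between two of these maps therefore approximates how much of the
    target's simulated spectrum weight a decoy can also explain.
    """
    frags = enumerate_fragments(
        mol, FragmenterConfig(max_depth=depth, min_mass=min_mass)
    )
    if not frags:
        return {}
    weights = [float(np.exp(-f.bde / bde_softness)) for f in frags]
    z = sum(weights[1:]) or 1.0
    evidence: dict = {}
    for k, f in enumerate(frags):
        p = 1.0 if k == 0 else min(1.0, (n_peaks - 1) * weights[k] / z)
        evidence[f.formula] = max(evidence.get(f.formula, 0.0), f.neutral_mass ** 3 * p)
    return evidence


def _explainable_formulas(mol: Molecule, depth: int = 2, min_mass: float = 14.0) -> set:
    """Every fragment composition the matcher could reach for ``mol``.

    Includes the neutral-loss derived structures and their own trees,
    because matching works on that extended universe, not only on the
    plain bond-disconnection fragments.
    """
    cfg = FragmenterConfig(max_depth=depth, min_mass=min_mass)
    formulas = {f.formula for f in enumerate_fragments(mol, cfg)}
    for derived in apply_rules(mol, default_rules(), "positive"):
        formulas.add(formula_of(derived))
        formulas.update(f.formula for f in enumerate_fragments(derived, cfg))
    return formulas


def make_decoy_library(
    target: Molecule,
    n: int = 100,
    ppm: float = 10.0,
    seed: int = 0,
) -> CandidateLibrary:
    """The target plus up to ``n`` decoys inside its ppm mass window.

    Decoys come from two offline sources: fixture molecules whose mass
    falls in the window, and random constitutional isomers of the target
    (same composition, hence exactly the same mass).  Duplicate
    structures are removed by canonical SMILES.  A decoy whose in-silico
    fragment composition set subsumes the target's is rejected: such a
    structure is indistinguishable from the target at the level the
    score observes and is no usable negative control (the same hygiene
    decoy-database construction applies elsewhere in MS).  The record
    order is shuffled deterministically by the seed.  If fewer than
    ``n`` decoys can be constructed, the library is returned smaller,
    with a warning.
    """
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    rng = np.random.default_rng(seed)
    target_formula = formula_of(target)
    target_mass = monoisotopic_mass(target_formula)
    window = ppm * 1e-6 * target_mass
    seen = {_canonical_smiles(target)}
    decoys: list[Molecule] = []

    for name, smi, _, _ in TOY_MOLECULES:
        if len(decoys) >= n:
            break
        pool_mol = parse_structure(smi, "smiles", id=f"pool-{name}")
        if abs(monoisotopic_mass(formula_of(pool_mol)) - target_mass) > window:
            continue
        canon = _canonical_smiles(pool_mol)
        if canon in seen:
            continue
        seen.add(canon)
        decoys.append(pool_mol)

    target_evidence = _fragment_evidence(target)
    # the heaviest fragment composition appears in every simulated
    # spectrum, so a usable decoy must not be able to produce it
    heaviest_formula = max(
        target_evidence, key=lambda f: monoisotopic_mass(f), default=None
    )
    rest_total = sum(
        w for f, w in target_evidence.items() if f != heaviest_formula
    )
    elements = [a.element for a in target.atoms]
    h_total = target_formula.get("H", 0)
    attempts = 0
    max_attempts = 80 * n
    while len(decoys) < n and attempts < max_attempts:
        attempts += 1
        isomer = _random_isomer(elements, h_total, rng)
        if isomer is None:
            continue
        try:
            canon = _canonical_smiles(isomer)
        except Exception:
            continue
        if canon in seen:
            continue
        seen.add(canon)
        isomer_formulas = _explainable_formulas(isomer)
        if heaviest_formula in isomer_formulas:
            continue  # shares the guaranteed top peak: not a negative control
        shared = sum(
            weight
            for f, weight in target_evidence.items()
            if f in isomer_formulas and f != heaviest_formula
        )
        if rest_total and shared > MAX_SHARED_FRAGMENT_FRACTION * rest_total:
            continue  # not dissimilar enough to serve as a negative control
        isomer.id = f"decoy-{len(decoys) + 1}"
        decoys.append(isomer)

    if len(decoys) < n:
        logger.warning(
            "%s: constructed only %d of %d requested decoys", target.id, len(decoys), n
        )
    records = [target] + decoys
    perm = rng.permutation(len(records))
    shuffled = [records[int(i)] for i in perm]
    return library_from_molecules(shuffled, source=f"decoys[{target.id}]")
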