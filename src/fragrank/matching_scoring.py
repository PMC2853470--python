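"""Fragment-peak matching under a combined mass tolerance, and scoring.

Matching interleaves with breadth-first fragment generation: measured
peaks correspond to charged fragments, so a proton is added (positive
mode) or removed (negative mode) from each neutral fragment mass before
comparison.  Intrinsically charged fragments are matched at their as-is
mass, with a configurable enthalpy penalty added to their cumulative BDE.
Once the lightest unexplained peak is accounted for, the minimum-mass
cutoff rises, pruning the remaining enumeration.

The candidate score combines a weighted count of explained peaks (heavy,
intense peaks count more) with a bond-dissociation-energy penalty::

    S_i = w_i / max(w)  -  e_i / (2 * max(e))

where ``w_i = sum(intensity^m * mz^n)`` over the peaks candidate *i*
explains (m = 0.6, n = 3) and ``e_i`` is the arithmetic mean of the
dissociation enthalpies of all bonds cleaved for its explaining
fragments (a per-bond mean: candidates whose explanations rely on
strong bonds are penalized, independently of how many cuts they made).
The first term lies in [0, 1], the penalty in [0, 0.5], hence S in
[-0.5, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chem_core import Molecule
from .constants import PROTON_MASS
from .fragmenter import (
    BDETable,
    Fragment,
    FragmenterConfig,
    as_root_fragment,
    _levels,
)
from .rearrangements import NeutralLossRule, apply_rules
from .spectra import Peak, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "MatchParams",
    "ScoreParams",
    "FragmentPeakMatch",
    "CandidateScore",
    "MatchOutcome",
    "within_tolerance",
    "fragment_and_match",
    "peak_weight",
    "score_candidates",
    "score_spectrum",
]


@dataclass
class MatchParams:
    """Mass-tolerance and charge-handling parameters for matching."""

    mzabs: float = 0.01
    mzppm: float = 50.0
    ion_mode: str = "positive"
    proton_mass: float = PROTON_MASS
    #: enthalpy penalty (kJ/mol) for intrinsically charged fragments;
    #: None means "largest value of the BDE table in use".
    charge_penalty: Optional[float] = None

    def __post_init__(self):
        if self.mzabs < 0 or self.mzppm < 0:
            raise ValueError("mzabs and mzppm must be >= 0")
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"unknown ion mode {self.ion_mode!r}")

    def window(self, ion_mass: float) -> float:
        return self.mzabs + self.mzppm * 1e-6 * ion_mass


@dataclass
class ScoreParams:
    """Exponents of the weighted peak count (literature defaults)."""

    m: float = 0.6  # intensity exponent
    n: float = 3.0  # mass exponent


@dataclass(frozen=True)
class FragmentPeakMatch:
    """One explained peak: the fragment, the peak, and the mass error."""

    fragment: Fragment
    peak: Peak
    ion_mass: float
    error: float
    intrinsic_charge: bool = False
    #: cumulative BDE including any intrinsic-charge penalty
    effective_bde: float = 0.0


@dataclass
class MatchOutcome:
    """Matches plus the total number of fragments generated for a candidate."""

    matches: list[FragmentPeakMatch]
    total_fragments: int

    def __iter__(self):
        return iter((self.matches, self.total_fragments))


@dataclass
class CandidateScore:
    candidate_id: str
    matches: list[FragmentPeakMatch] = field(default_factory=list)
    weight: float = 0.0           # w_i, raw weighted peak count
    mean_bde: float = 0.0         # e_i, mean enthalpy per cleaved bond
    score: float = 0.0            # S_i after normalization
    explained_peaks: int = 0
    total_fragments: int = 0


def within_tolerance(peak_mz: float, ion_mass: float, p: MatchParams) -> bool:
    """True iff |peak - ion| <= mzabs + mzppm * 1e-6 * ion mass."""
    return abs(peak_mz - ion_mass) <= p.window(ion_mass)


def peak_weight(peak: Peak, s: Optional[ScoreParams] = None) -> float:
    """intensity^m * mz^n: heavy, intense peaks are more characteristic."""
    s = s or ScoreParams()
    return peak.intensity ** s.m * peak.mz ** s.n


def _ion_mass(fragment: Fragment, p: MatchParams) -> tuple[float, bool]:
    """(theoretical ion mass, intrinsic-charge flag) of a fragment."""
    if fragment.net_charge != 0:
        return fragment.neutral_mass, True
    if p.ion_mode == "positive":
        return fragment.neutral_mass + p.proton_mass, False
    return fragment.neutral_mass - p.proton_mass, False


def _implied_neutral(mz: float, p: MatchParams) -> float:
    """Smallest neutral fragment mass that could explain a peak at ``mz``.

    An intrinsically charged match needs no proton, so in positive mode
    the pessimistic bound is mz - proton - window.
    """
    base = mz - p.proton_mass if p.ion_mode == "positive" else mz
    return base - p.window(mz)


def fragment_and_match(
    candidate: Molecule,
    spectrum: Spectrum,
    fcfg: Optional[FragmenterConfig] = None,
    params: Optional[MatchParams] = None,
    rules: Optional[Sequence[NeutralLossRule]] = None,
    bde: Optional[BDETable] = None,
) -> MatchOutcome:
    """Generate fragments breadth-first and match them to the spectrum.

    Neutral-loss rules are applied to the intact candidate (and, when
    ``fcfg.apply_rules_to_fragments`` is set, to every generated
    fragment); derived structures enter the same queue at their parent's
    depth and share the redundancy pool.  Each measured peak is explained
    at most once, by the lowest-BDE fragment that reaches it first
    (shallower levels win).  ``total_fragments`` counts every generated
    fragment above the cutoff, including derived structures but not the
    intact candidate itself.
    """
    fcfg = fcfg or FragmenterConfig()
    params = params or MatchParams()
    bde = bde or BDETable.default_table()
    if rules is None:
        rules = []
    penalty = params.charge_penalty if params.charge_penalty is not None else bde.max_value()
    if not spectrum.peaks:
        logger.warning("empty spectrum: nothing to match for %s", candidate.id)
        return MatchOutcome([], 0)

    unexplained: dict[int, Peak] = dict(enumerate(spectrum.peaks))
    best: dict[int, FragmentPeakMatch] = {}

    def cutoff() -> float:
        if fcfg.min_mass is not None:
            return fcfg.min_mass
        if not unexplained:
            return float("inf")
        return min(_implied_neutral(p.mz, params) for p in unexplained.values())

    def match_level(fragments: Sequence[Fragment]) -> None:
        contenders: dict[int, list[tuple[float, float, float, Fragment]]] = {}
        for frag in fragments:
            ion, intrinsic = _ion_mass(frag, params)
            eff = frag.bde + (penalty if intrinsic else 0.0)
            for idx, peak in unexplained.items():
                if within_tolerance(peak.mz, ion, params):
                    contenders.setdefault(idx, []).append((eff, -frag.neutral_mass, ion, frag))
        for idx, cands in contenders.items():
            eff, _negmass, ion, frag = min(cands, key=lambda t: (t[0], t[1]))
            peak = unexplained.pop(idx)
            best[idx] = FragmentPeakMatch(
                fragment=frag,
                peak=peak,
                ion_mass=ion,
                error=peak.mz - ion,
                intrinsic_charge=frag.net_charge != 0,
                effective_bde=eff,
            )

    root = as_root_fragment(candidate)
    derived = [
        as_root_fragment(d, loss_tag=d.derived_from)
        for d in apply_rules(candidate, list(rules), params.ion_mode)
    ] if rules else []

    total = 0
    min_mass = cutoff()
    derived = [d for d in derived if d.neutral_mass >= min_mass]
    total += len(derived)
    # the intact candidate and its rule-derived variants can explain peaks
    match_level([root, *derived])

    seen: dict = {}
    level_gen = _levels(root, fcfg, bde, cutoff, seen, extra_roots=derived)
    for level in level_gen:
        floor = cutoff()  # rises as the lightest peaks get explained
        level = [f for f in level if f.neutral_mass >= floor]
        if fcfg.apply_rules_to_fragments and rules:
            extra = []
            for frag in level:
                sub = _fragment_as_molecule(frag)
                for d in apply_rules(sub, list(rules), params.ion_mode):
                    child = as_root_fragment(d, loss_tag=d.derived_from)
                    child = Fragment(
                        child.graph, child.atom_mask, child.broken_bonds,
                        frag.bde, frag.depth, loss_tag=d.derived_from,
                    )
                    if child.neutral_mass >= floor:
                        extra.append(child)
            total += len(extra)
            match_level(extra)
        total += len(level)
        match_level(level)
        if not unexplained:
            break

    matches = [best[idx] for idx in sorted(best)]
    return MatchOutcome(matches, total)


def _fragment_as_molecule(frag: Fragment) -> Molecule:
    """Standalone molecule view of a fragment's subgraph (for rule matching)."""
    from .chem_core import Bond as CBond

    parent = frag.graph.molecule
    indices = frag.atom_indices
    remap = {orig: k for k, orig in enumerate(indices)}
    broken = set(frag.broken_bonds)
    atoms = [parent.atoms[i] for i in indices]
    bonds = [
        CBond(remap[b.a], remap[b.b], b.order, b.in_ring)
        for k, b in enumerate(parent.bonds)
        if k not in broken and b.a in remap and b.b in remap
    ]
    return Molecule(atoms, bonds, id=f"{parent.id}#frag")


def score_candidates(raw: Sequence[tuple[float, float]]) -> list[float]:
    """Normalized scores from per-candidate (w_i, e_i) pairs.

    w is scaled by max(w) into [0, 1]; the mean BDE is scaled by
    2*max(e) into [0, 0.5] and subtracted.  Degenerate maxima (no peak
    explained anywhere, or all-zero BDEs) zero out the respective term.
    """
    if not raw:
        raise ValueError("score_candidates needs at least one candidate")
    max_w = max(w for w, _ in raw)
    max_e = max(e for _, e in raw)
    scores = []
    for w, e in raw:
        s = (w / max_w if max_w > 0 else 0.0) - (e / (2 * max_e) if max_e > 0 else 0.0)
        scores.append(s)
    return scores


def score_spectrum(
    candidates: Sequence[Molecule],
    spectrum: Spectrum,
    fcfg: Optional[FragmenterConfig] = None,
    params: Optional[MatchParams] = None,
    sparams: Optional[ScoreParams] = None,
    rules: Optional[Sequence[NeutralLossRule]] = None,
    bde: Optional[BDETable] = None,
) -> list[CandidateScore]:
    """Fragment, match and score every candidate against one spectrum.

    Output preserves candidate order; candidates explaining no peak keep
    a score contribution of zero for both terms.  Scores are independent
    of the candidate processing order.
    """
    if not candidates:
        raise ValueError("no candidates to score")
    sparams = sparams or ScoreParams()
    results = []
    for mol in candidates:
        outcome = fragment_and_match(mol, spectrum, fcfg, params, rules, bde)
        # e_i: mean enthalpy per bond cleaved across the distinct
        # explaining fragments (intrinsic-charge penalties enter the
        # numerator; explained roots break no bonds and contribute none)
        explained = {
            id(m.fragment): (m.effective_bde, len(m.fragment.broken_bonds))
            for m in outcome.matches
        }
        w = sum(peak_weight(m.peak, sparams) for m in outcome.matches)
        n_bonds = sum(nb for _, nb in explained.values())
        e = sum(bd for bd, _ in explained.values()) / n_bonds if n_bonds else 0.0
        results.append(
            CandidateScore(
                candidate_id=mol.id,
                matches=outcome.matches,
                weight=w,
                mean_bde=e,
                explained_peaks=len(outcome.matches),
                total_fragments=outcome.total_fragments,
            )
        )
    for cs, s in zip(results, score_candidates([(r.weight, r.mean_bde) for r in results])):
        cs.score = s
    return results
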