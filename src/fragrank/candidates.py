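"""Candidate retrieval from a local structure library.

The library plays the role of an upstream compound database queried by
exact neutral mass or elemental composition.  Remote databases can be
wrapped behind the same interface; the bundled implementation reads SDF
or two-column SMILES+id TSV files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .chem_core import Formula, Molecule, formula_of, monoisotopic_mass, parse_structures, parse_structure
from .constants import CHNOPS

logger = logging.getLogger(__name__)

__all__ = ["LibraryRecord", "CandidateLibrary", "load_library", "library_from_molecules",
           "search_by_mass", "search_by_formula", "select_by_ids"]


@dataclass(frozen=True)
class LibraryRecord:
    id: str
    molecule: Molecule
    mass: float  # neutral monoisotopic mass, Da


@dataclass
class CandidateLibrary:
    records: list[LibraryRecord]
    source: str = "local"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def library_from_molecules(molecules: Sequence[Molecule], source: str = "memory") -> CandidateLibrary:
    records = [
        LibraryRecord(m.id, m, monoisotopic_mass(formula_of(m))) for m in molecules
    ]
    return CandidateLibrary(records, source=source)


def load_library(path: Union[str, Path], format: Optional[str] = None) -> CandidateLibrary:
    """Load an SDF or SMILES-TSV library file.

    Unparseable records are skipped with a logged count; a file yielding
    zero parseable records is an error.  The TSV format is one structure
    per line: SMILES, optionally followed by a tab-separated identifier.
    """
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in (".sdf", ".mol") else "smiles-tsv"
    text = path.read_text()
    molecules: list[Molecule] = []
    skipped = 0
    if format == "sdf":
        n_records = max(text.count("$$$$"), 1)
        molecules = parse_structures(text, "sdf")
        skipped = n_records - len(molecules)
    elif format == "smiles-tsv":
        for k, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            rec_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"record-{k}"
            try:
                molecules.append(parse_structure(smiles, "smiles", id=rec_id))
            except ValueError:
                skipped += 1
                logger.warning("%s line %d: unparseable SMILES %r", path.name, k, smiles)
    else:
        raise ValueError(f"unknown library format {format!r}")
    if skipped:
        logger.warning("%s: skipped %d unparseable record(s)", path.name, skipped)
    if not molecules:
        raise ValueError(f"{path}: no parseable records")
    return library_from_molecules(molecules, source=str(path))


def _elements_of(m: Molecule) -> set[str]:
    els = {a.element for a in m.atoms}
    if any(a.n_hydrogens for a in m.atoms):
        els.add("H")
    return els


def search_by_mass(
    lib: CandidateLibrary,
    neutral_mass: float,
    ppm: float = 10.0,
    chnops_only: bool = False,
    exclude_ch_only: bool = False,
) -> list[LibraryRecord]:
    """Records within a ppm window of a neutral monoisotopic mass.

    Optional element filters: restrict to CHNOPS compounds, and/or drop
    plain hydrocarbons.  Results sort by |mass difference|, then id.
    """
    if neutral_mass <= 0:
        raise ValueError("query mass must be > 0")
    window = ppm * 1e-6 * neutral_mass
    hits = []
    for rec in lib.records:
        if abs(rec.mass - neutral_mass) > window:
            continue
        els = _elements_of(rec.molecule)
        if chnops_only and not els <= CHNOPS:
            continue
        if exclude_ch_only and els <= {"C", "H"}:
            continue
        hits.append(rec)
    hits.sort(key=lambda r: (abs(r.mass - neutral_mass), r.id))
    return hits


def search_by_formula(lib: CandidateLibrary, f: Formula) -> list[LibraryRecord]:
    """Records whose elemental composition equals ``f`` exactly."""
    return [rec for rec in lib.records if formula_of(rec.molecule) == f]


def select_by_ids(lib: CandidateLibrary, ids: Sequence[str]) -> list[LibraryRecord]:
    """Order-preserving id lookup; unknown ids are reported, not fatal."""
    by_id = {rec.id: rec for rec in lib.records}
    out = []
    for i in ids:
        rec = by_id.get(i)
        if rec is None:
            logger.warning("id %r not in library %s", i, lib.source)
        else:
            out.append(rec)
    return out
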