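"""Peak-list I/O and composite-spectrum construction.

Compounds are often measured at several collision energies; informative
fragmentation may appear only at some of them.  A *composite* spectrum
merges those measurements: peaks closer than a small m/z window are
collapsed to their mean m/z, keeping the highest intensity seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = ["Peak", "Spectrum", "read_peaklist", "merge_spectra", "MERGE_WINDOW"]

#: m/z window (Th) within which peaks from different energies are merged.
MERGE_WINDOW = 0.01


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """Measured peaks (sorted by m/z) with ion-mode metadata."""

    peaks: list[Peak] = field(default_factory=list)
    ion_mode: str = "positive"
    collision_energy: Optional[float] = None
    precursor_mz: Optional[float] = None

    def __post_init__(self):
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"ion_mode must be 'positive' or 'negative', got {self.ion_mode!r}")
        for p in self.peaks:
            if p.mz <= 0:
                raise ValueError(f"non-positive m/z {p.mz}")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def min_mz(self) -> Optional[float]:
        return self.peaks[0].mz if self.peaks else None


def read_peaklist(
    text: str,
    ion_mode: str = "positive",
    collision_energy: Optional[float] = None,
    precursor_mz: Optional[float] = None,
) -> Spectrum:
    """Parse a whitespace-separated "m/z intensity" peak list.

    '#' starts a comment; a third column (e.g. relative intensity in
    MassBank-style exports) is tolerated and ignored.  An empty list is
    valid but downstream operations will warn.
    """
    peaks = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected 'mz intensity', got {raw!r}")
        try:
            mz, intensity = float(fields[0]), float(fields[1])
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric token in {raw!r}") from None
        peaks.append(Peak(mz, intensity))
    if not peaks:
        logger.warning("peak list is empty")
    return Spectrum(peaks, ion_mode=ion_mode, collision_energy=collision_energy,
                    precursor_mz=precursor_mz)


def write_peaklist(spectrum: Spectrum) -> str:
    """Two-column text form of a spectrum."""
    return "\n".join(f"{p.mz:.4f} {p.intensity:g}" for p in spectrum.peaks) + "\n"


def merge_spectra(spectra: Sequence[Spectrum], window: float = MERGE_WINDOW) -> Spectrum:
    """Composite spectrum across collision energies.

    Peaks are pooled, sorted, and clustered greedily in ascending m/z:
    a peak joins the current cluster while its gap to the previous member
    is at most ``window`` Th (transitive chains merge).  Each cluster is
    replaced by the mean m/z of its members and their maximum intensity.
    """
    if not spectra:
        raise ValueError("merge_spectra needs at least one spectrum")
    modes = {s.ion_mode for s in spectra}
    if len(modes) > 1:
        raise ValueError(f"cannot merge spectra of mixed ion modes: {sorted(modes)}")
    pooled = sorted((p for s in spectra for p in s.peaks), key=lambda p: p.mz)
    merged: list[Peak] = []
    cluster: list[Peak] = []
    for peak in pooled:
        # tiny epsilon so peaks exactly at the window edge still merge
        if cluster and peak.mz - cluster[-1].mz > window + 1e-9:
            merged.append(_collapse(cluster))
            cluster = []
        cluster.append(peak)
    if cluster:
        merged.append(_collapse(cluster))
    precursor = next((s.precursor_mz for s in spectra if s.precursor_mz is not None), None)
    return Spectrum(merged, ion_mode=modes.pop(), precursor_mz=precursor)


def _collapse(cluster: list[Peak]) -> Peak:
    mz = sum(p.mz for p in cluster) / len(cluster)
    return Peak(mz, max(p.intensity for p in cluster))
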