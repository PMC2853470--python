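"""Physical constants: monoisotopic atomic masses and the proton mass.

Masses are CODATA/IUPAC monoisotopic values (most abundant isotope),
bundled so that mass arithmetic never depends on an external service.
"""

from __future__ import annotations

#: Monoisotopic mass of the most abundant isotope, in Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Si": 27.9769265347,
    "P": 30.9737615120,
    "S": 31.9720711744,
    "Cl": 34.9688527100,
    "K": 38.9637064864,
    "Br": 78.9183376,
    "I": 126.9044719,
}

#: Mass of a proton in Da. Full precision is kept internally; user-facing
#: reports display it rounded to 1.007.
PROTON_MASS: float = 1.00728

#: Elements common in natural products, used as an optional candidate filter.
CHNOPS: frozenset[str] = frozenset({"C", "H", "N", "O", "P", "S"})
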