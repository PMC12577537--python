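"""Pinned physical constants for mass arithmetic.

All monoisotopic masses are the exact masses of the most abundant isotope
(IUPAC/CODATA values), pinned here so that every mass computed anywhere in
the package is bit-stable. Tolerance for mass comparisons is 1e-4 Da
throughout.
"""

from __future__ import annotations

#: Exact mass of the most abundant isotope, by element symbol (Da).
ISOTOPE_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: m/z shift of a protonated molecule [M+H]+ (proton mass; electron folded in).
PROTON_SHIFT = 1.007276
#: m/z shift of a sodiated molecule [M+Na]+ (Na+ ion mass).
SODIUM_SHIFT = 22.989218
#: m/z shift of a deprotonated molecule [M-H]- .
DEPROTONATION_SHIFT = -1.007276

#: Monoisotopic masses of the fixed Ugi-4CR components (Da).
MASS_WATER = 2 * ISOTOPE_MASS["H"] + ISOTOPE_MASS["O"]              # 18.0106
MASS_AMMONIA = ISOTOPE_MASS["N"] + 3 * ISOTOPE_MASS["H"]            # 17.0265
MASS_ACRYLIC_ACID = (
    3 * ISOTOPE_MASS["C"] + 4 * ISOTOPE_MASS["H"] + 2 * ISOTOPE_MASS["O"]
)                                                                    # 72.0211

#: Mass tolerance (Da) used by every internal consistency check.
MASS_TOL_DA = 1e-4
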