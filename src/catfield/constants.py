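"""Physical constants and element data shared by every module.

All geometry is carried in Å; multipole moments are carried in atomic
units (e, e·bohr, e·bohr²) and potentials are reported in
kcal mol⁻¹ e⁻¹.  The conversion constants below are pinned here so that
every module agrees bit-for-bit.
"""

from __future__ import annotations

#: bohr per Å
ANGSTROM_TO_BOHR: float = 1.8897259886

#: Å per bohr — the exact reciprocal (≈ 0.52917721), so that unit
#: round-trips are lossless
BOHR_TO_ANGSTROM: float = 1.0 / ANGSTROM_TO_BOHR

#: kcal mol⁻¹ per hartree
HARTREE_TO_KCAL_PER_MOL: float = 627.509474

#: potential of a unit charge at 1 Å, in kcal mol⁻¹ e⁻¹ (Coulomb's law)
COULOMB_KCAL_PER_MOL_E_AT_1A: float = HARTREE_TO_KCAL_PER_MOL / ANGSTROM_TO_BOHR

#: multipole-expansion validity guard: points closer than this to any
#: atom center are rejected (bohr)
PROXIMITY_GUARD_BOHR: float = 0.3

#: van der Waals radii in Å (Bondi 1964, with the common later additions
#: for elements Bondi left out).  Element symbols are capitalized.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "Li": 1.82,
    "Be": 1.53,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27,
    "Mg": 1.73,
    "Al": 1.84,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "K": 2.75,
    "Ca": 2.31,
    "Ni": 1.63,
    "Cu": 1.40,
    "Zn": 1.39,
    "Ga": 1.87,
    "Ge": 2.11,
    "As": 1.85,
    "Se": 1.90,
    "Br": 1.85,
    "Kr": 2.02,
    "Pd": 1.63,
    "Ag": 1.72,
    "Cd": 1.58,
    "In": 1.93,
    "Sn": 2.17,
    "Sb": 2.06,
    "Te": 2.06,
    "I": 1.98,
    "Xe": 2.16,
    "Pt": 1.75,
    "Au": 1.66,
    "Hg": 1.55,
    "Pb": 2.02,
}


def vdw_radius(element: str) -> float:
    """Return the Bondi vdW radius (Å) for *element*.

    Raises
    ------
    KeyError
        If the element has no radius in the bundled table.
    """
    return BONDI_VDW_RADII[element]
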