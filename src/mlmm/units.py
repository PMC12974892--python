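"""Unit conventions and conversions.

Internal computation uses Hartree atomic units (bohr, hartree, elementary
charge); all file and CLI interfaces use Å, kcal/mol and elementary charge,
matching molecular-dynamics conventions.
"""

from __future__ import annotations

BOHR_TO_ANGSTROM = 0.52917721092
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
HARTREE_TO_KCALMOL = 627.509474
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL

#: Boltzmann constant, kcal/mol/K
KB_KCALMOL = 0.0019872041

#: conversion factor: (kcal/mol/Å) / amu -> Å/fs²
FORCE_TO_ACC = 4.184e-4

#: atomic masses, amu (elements supported by the toolkit)
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: element-default valence electron populations used by the core/valence
#: split of the Slater densities
VALENCE_POPULATIONS = {"H": 1.0, "C": 4.0, "N": 5.0, "O": 6.0, "S": 6.0}

# each unit's magnitude expressed in the family's base unit (bohr / Hartree)
_LENGTH = {"bohr": 1.0, "A": ANGSTROM_TO_BOHR, "angstrom": ANGSTROM_TO_BOHR}
_ENERGY = {"Hartree": 1.0, "kcal/mol": KCALMOL_TO_HARTREE}
_CHARGE = {"e": 1.0}


class UnknownUnitError(ValueError):
    """Raised when a unit name is not recognised."""


def _family(unit: str):
    for fam in (_LENGTH, _ENERGY, _CHARGE):
        if unit in fam:
            return fam
    raise UnknownUnitError(f"unknown unit: {unit!r}")


def convert_units(value, from_unit: str, to_unit: str):
    """Convert ``value`` between bohr/Å, Hartree/kcal-per-mol or e.

    Raises
    ------
    UnknownUnitError
        If either unit is unknown or the two units measure different
        dimensions.
    """
    fam_from = _family(from_unit)
    fam_to = _family(to_unit)
    if fam_from is not fam_to:
        raise UnknownUnitError(
            f"incompatible units: {from_unit!r} -> {to_unit!r}"
        )
    return value * (fam_from[from_unit] / fam_from[to_unit])
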