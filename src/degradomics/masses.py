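"""Peptide mass bookkeeping: theoretical masses, delta masses, tryptic status.

Monoisotopic residue masses are the default, as appropriate for matching
ion-trap precursor masses against a sequence database; an average-mass table
is available for callers that need it. The proton mass used for m/z <->
neutral-mass conversion is 1.007276 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from pyteomics import mass as _ptmass

__all__ = [
    "PROTON_MASS",
    "PHOSPHO_MASS",
    "ResidueMassTable",
    "MONOISOTOPIC",
    "TrypticStatus",
    "peptide_mass",
    "delta_mass",
    "mz_from_mass",
    "tryptic_status",
]

PROTON_MASS = 1.007276
PHOSPHO_MASS = 79.96633

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue -> mass map plus the constants needed to assemble a peptide.

    ``water`` is added once per peptide (the termini); ``modifications``
    holds named added masses such as phosphorylation.
    """

    residue_masses: Mapping[str, float]
    water: float
    proton: float = PROTON_MASS
    modifications: Mapping[str, float] = field(
        default_factory=lambda: {"phospho": PHOSPHO_MASS}
    )

    def __post_init__(self) -> None:
        missing = [r for r in _STANDARD_RESIDUES if r not in self.residue_masses]
        if missing:
            raise ValueError(f"mass table missing residues: {missing}")
        if self.water <= 0 or any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("all masses must be positive")

    @classmethod
    def monoisotopic(cls) -> "ResidueMassTable":
        masses = {r: _ptmass.std_aa_mass[r] for r in _STANDARD_RESIDUES}
        return cls(residue_masses=masses, water=_ptmass.calculate_mass(formula="H2O"))

    @classmethod
    def average(cls) -> "ResidueMassTable":
        masses = {
            r: _ptmass.calculate_mass(composition=_ptmass.std_aa_comp[r], average=True)
            for r in _STANDARD_RESIDUES
        }
        water = _ptmass.calculate_mass(formula="H2O", average=True)
        return cls(residue_masses=masses, water=water)


MONOISOTOPIC = ResidueMassTable.monoisotopic()


def peptide_mass(
    peptide: str, mod_mass: float = 0.0, table: ResidueMassTable = MONOISOTOPIC
) -> float:
    """Theoretical neutral mass: sum of residue masses + water + mod_mass (Da)."""
    if not peptide:
        raise ValueError("empty peptide")
    if mod_mass < 0:
        raise ValueError("mod_mass must be >= 0")
    total = table.water + mod_mass
    for i, residue in enumerate(peptide):
        try:
            total += table.residue_masses[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r} at position {i}") from None
    return total


def mz_from_mass(neutral_mass: float, charge: int, proton: float = PROTON_MASS) -> float:
    """Precursor m/z (Th) of a neutral mass at the given positive charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * proton) / charge


def delta_mass(
    precursor_mz: float,
    charge: int,
    theoretical_mass: float,
    proton: float = PROTON_MASS,
) -> float:
    """Observed minus theoretical neutral mass (Da).

    The observed neutral mass is ``precursor_mz * z - z * proton``; on a
    linear ion trap the resulting deltas are approximately Gaussian within
    +/- 2 Da and serve as an identification quality control.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (precursor_mz * charge - charge * proton) - theoretical_mass


@dataclass(frozen=True)
class TrypticStatus:
    """Whether a peptide is fully tryptic and how many internal K/R sites it spans."""

    is_fully_tryptic: bool
    missed_cleavages: int


def _cleaves_after(residue: str, following: str, proline_rule: bool) -> bool:
    if residue not in "KR":
        return False
    if proline_rule and following == "P":
        return False
    return True


def tryptic_status(
    peptide: str, prev_aa: str, next_aa: str, proline_rule: bool = True
) -> TrypticStatus:
    """Classify a peptide given its flanking residues ('-' = protein terminus).

    Fully tryptic means both termini are consistent with trypsin cleavage
    (C-terminal to K/R) or fall on a protein terminus. With the proline rule
    enabled (default) K/R followed by P is not a cleavage site, for both the
    terminus checks and missed-cleavage counting.
    """
    if not peptide:
        raise ValueError("empty peptide")
    nterm_ok = prev_aa == "-" or _cleaves_after(prev_aa, peptide[0], proline_rule)
    cterm_ok = next_aa == "-" or _cleaves_after(peptide[-1], next_aa, proline_rule)
    missed = sum(
        1
        for i in range(len(peptide) - 1)
        if _cleaves_after(peptide[i], peptide[i + 1], proline_rule)
    )
    return TrypticStatus(is_fully_tryptic=nterm_ok and cterm_ok, missed_cleavages=missed)
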