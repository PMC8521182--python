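"""Peptide-level physics: average masses and net charge at a given pH.

Fragment weights in a chop-n-drop measurement are effective weights of a
heterogeneous molecular population, so *average* (not monoisotopic) residue
masses are used throughout. Net charge follows the concentration-ratio
(Henderson-Hasselbalch sum) model over ionizable side chains plus one
N-terminal amine and one C-terminal carboxyl.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "CANONICAL_RESIDUES",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "MassTable",
    "ChargeModel",
    "NonCanonicalResidueError",
    "peptide_mass",
    "peptide_charge",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Mass of one water molecule (Da); added once per peptide for the terminal
#: H and OH gained on hydrolysis.
WATER_MASS = 18.0153

#: Expasy/IUPAC average residue masses (Da): free amino-acid average weight
#: minus one water.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "A": 71.0779,
    "C": 103.1429,
    "D": 115.0874,
    "E": 129.1140,
    "F": 147.1738,
    "G": 57.0513,
    "H": 137.1393,
    "I": 113.1576,
    "K": 128.1723,
    "L": 113.1576,
    "M": 131.1960,
    "N": 114.1026,
    "P": 97.1152,
    "Q": 128.1292,
    "R": 156.1857,
    "S": 87.0773,
    "T": 101.1039,
    "V": 99.1311,
    "W": 186.2099,
    "Y": 163.1732,
}


class NonCanonicalResidueError(ValueError):
    """A sequence contains a character outside the 20-residue alphabet."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"non-canonical residue {residue!r} at position {position}"
        )


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, aa in enumerate(sequence):
        if aa not in CANONICAL_RESIDUES:
            raise NonCanonicalResidueError(aa, i)


@dataclass(frozen=True)
class MassTable:
    """Average residue masses plus the per-peptide water mass."""

    residue_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASS)
    )
    water_mass: float = WATER_MASS

    def __post_init__(self) -> None:
        if set(self.residue_mass) != CANONICAL_RESIDUES:
            raise ValueError("mass table must cover exactly the 20 canonical residues")
        if any(m <= 0 for m in self.residue_mass.values()) or self.water_mass <= 0:
            raise ValueError("masses must be strictly positive")

    def mass(self, sequence: str) -> float:
        _check_sequence(sequence)
        return sum(self.residue_mass[aa] for aa in sequence) + self.water_mass


# Bjellqvist pKa values, as used by biopython's concentration-ratio charge
# computation (Bio.SeqUtils.IsoelectricPoint).
_PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


@dataclass(frozen=True)
class ChargeModel:
    """Henderson-Hasselbalch net-charge model.

    ``pka_positive`` maps ``{"Nterm", "K", "R", "H"}`` to pKa values,
    ``pka_negative`` maps ``{"Cterm", "D", "E", "C", "Y"}``. One N-terminal
    and one C-terminal group are always included. Default pH is 4.0, the
    operating pH of FraC pores.
    """

    pka_positive: Mapping[str, float] = field(default_factory=lambda: dict(_PKA_POSITIVE))
    pka_negative: Mapping[str, float] = field(default_factory=lambda: dict(_PKA_NEGATIVE))
    pH: float = 4.0

    def __post_init__(self) -> None:
        for table in (self.pka_positive, self.pka_negative):
            if any(not 0.0 < pka < 14.0 for pka in table.values()):
                raise ValueError("pKa values must lie in (0, 14)")

    def charge(self, sequence: str, pH: float | None = None) -> float:
        _check_sequence(sequence)
        if pH is None:
            pH = self.pH
        pos = self.pka_positive
        neg = self.pka_negative
        total = 1.0 / (1.0 + 10.0 ** (pH - pos["Nterm"]))
        total -= 1.0 / (1.0 + 10.0 ** (neg["Cterm"] - pH))
        for aa in sequence:
            if aa in pos:
                total += 1.0 / (1.0 + 10.0 ** (pH - pos[aa]))
            elif aa in neg:
                total -= 1.0 / (1.0 + 10.0 ** (neg[aa] - pH))
        return total


_DEFAULT_MASS_TABLE = MassTable()
_DEFAULT_CHARGE_MODEL = ChargeModel()


def peptide_mass(sequence: str, table: MassTable | None = None) -> float:
    """Average molecular mass (Da) of a peptide: residue masses + one water."""
    return (table or _DEFAULT_MASS_TABLE).mass(sequence)


def peptide_charge(
    sequence: str, model: ChargeModel | None = None, pH: float | None = None
) -> float:
    """Net charge (elementary charges, signed and fractional) at ``pH``."""
    return (model or _DEFAULT_CHARGE_MODEL).charge(sequence, pH=pH)
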