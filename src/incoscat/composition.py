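"""Incoherent-cross-section accounting for hydrated protein powders.

In incoherent neutron scattering the hydrogen atom dominates: its bound-atom
incoherent cross section (80.27 barn) is ~40x larger than that of any other
element found in biomacromolecules, and deuterium's is 2.05 barn.  A protein
powder hydrated with D2O therefore scatters almost entirely from the protein
hydrogens.  This module turns an elemental composition and a sample mass into
a total incoherent cross section, budgets protein vs hydration-water
contributions, and converts an immobile-atom fraction into hydrogen-atom and
residue counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from scipy.constants import Avogadro

from .exceptions import ParameterError

__all__ = [
    "INCOHERENT_XS_BARN",
    "BARN_CM2",
    "MaterialComposition",
    "CrossSectionBudget",
    "HEWL",
    "HEAVY_WATER",
    "incoherent_cross_section",
    "hydration_contribution",
    "cross_section_budget",
    "immobile_hydrogen_count",
]

#: bound-atom incoherent scattering cross sections, in barn
INCOHERENT_XS_BARN: dict[str, float] = {
    "H": 80.27,
    "D": 2.05,
    "C": 0.001,
    "N": 0.50,
    "O": 0.0008,
    "S": 0.007,
}

BARN_CM2 = 1.0e-24


@dataclass(frozen=True)
class MaterialComposition:
    """Elemental composition of one formula unit plus its molar mass."""

    atom_counts: Mapping[str, int]
    molar_mass: float
    label: str = ""

    def __post_init__(self):
        if not (self.molar_mass > 0):
            raise ParameterError("molar_mass must be > 0")
        for el, n in self.atom_counts.items():
            if n < 0 or int(n) != n:
                raise ParameterError(f"count of {el} must be a nonnegative integer")
        object.__setattr__(self, "atom_counts", dict(self.atom_counts))


#: hen egg white lysozyme, all hydrogens protiated (129 residues, 14.3 kDa)
HEWL = MaterialComposition(
    atom_counts={"C": 613, "H": 959, "N": 193, "O": 185, "S": 10},
    molar_mass=14300.0, label="HEWL")

HEAVY_WATER = MaterialComposition(
    atom_counts={"D": 2, "O": 1}, molar_mass=20.0276, label="D2O")

#: nonexchangeable hydrogen atoms of HEWL, and the per-residue average
HEWL_NONEXCHANGEABLE_H = 689
H_PER_RESIDUE = 6.0


@dataclass(frozen=True)
class CrossSectionBudget:
    """Protein vs hydration-water incoherent scattering budget (cm^2 per sample)."""

    protein_sigma: float
    water_sigma: float

    @property
    def protein_fraction(self) -> float:
        """Protein share of the total incoherent scattering, in percent."""
        return hydration_contribution(self.protein_sigma, self.water_sigma)

    def summary(self) -> str:
        return (f"incoherent cross sections: protein {self.protein_sigma:.4g} cm^2, "
                f"water {self.water_sigma:.4g} cm^2 -> protein contribution "
                f"{self.protein_fraction:.2f}%")


def incoherent_cross_section(material: MaterialComposition, mass_g: float) -> float:
    """Total incoherent cross section (cm^2) of `mass_g` grams of a material.

    sigma = sum_el count_el * sigma_inc(el) * (mass/molar_mass) * N_A.
    Linear in mass; additive over mixture components.
    """
    if mass_g < 0:
        raise ParameterError("mass must be >= 0")
    per_formula_barn = 0.0
    for el, n in material.atom_counts.items():
        if el not in INCOHERENT_XS_BARN:
            raise ParameterError(
                f"no tabulated incoherent cross section for element {el!r}")
        per_formula_barn += n * INCOHERENT_XS_BARN[el]
    moles = mass_g / material.molar_mass
    return per_formula_barn * BARN_CM2 * moles * Avogadro


def hydration_contribution(protein_sigma: float, water_sigma: float) -> float:
    """Protein percentage of the total incoherent scattering."""
    if protein_sigma < 0 or water_sigma < 0:
        raise ParameterError("cross sections must be >= 0")
    total = protein_sigma + water_sigma
    if total == 0:
        raise ParameterError("at least one cross section must be > 0")
    return 100.0 * protein_sigma / total


def cross_section_budget(protein: MaterialComposition = HEWL,
                         protein_mass_g: float = 1.0,
                         water: MaterialComposition = HEAVY_WATER,
                         water_mass_g: float = 0.4) -> CrossSectionBudget:
    """Budget for a hydrated powder (defaults: 1 g HEWL at 0.4 g D2O/g)."""
    return CrossSectionBudget(
        protein_sigma=incoherent_cross_section(protein, protein_mass_g),
        water_sigma=incoherent_cross_section(water, water_mass_g))


def immobile_hydrogen_count(p0: float,
                            nonexchangeable_h: int = HEWL_NONEXCHANGEABLE_H
                            ) -> tuple[float, float]:
    """Immobile nonexchangeable hydrogens and the equivalent residue count.

    hydrogens = p0 * nonexchangeable_h; residues = hydrogens / 6 (average of
    six nonexchangeable hydrogens per amino acid).  Counts are real-valued;
    round only at presentation.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ParameterError(f"p0 must be in [0, 1], got {p0}")
    hydrogens = p0 * nonexchangeable_h
    return hydrogens, hydrogens / H_PER_RESIDUE
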