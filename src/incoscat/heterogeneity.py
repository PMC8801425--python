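"""Amplitude-state partition and free-energy ladder from heterogeneity fits.

The heterogeneity model describes the squared atomic position fluctuation
r^2 as Gamma-distributed: lambda = r^2/<r2> ~ Gamma(shape=beta, rate=beta)
(unit mean).  Fixed thresholds in r^2-space (defaults 0.25 and 1.0 A^2)
split the distribution into small/medium/large-amplitude states ("S", "M",
"L"); the mass in each bin, scaled by the residue count of the protein
(129 for hen egg white lysozyme), gives the number of residues per state,
and occupancy ratios give free-energy differences via
N2/N1 = exp(-dG / RT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ParameterError
from .models import gamma_fluctuation_cdf

__all__ = [
    "DEFAULT_BOUNDS",
    "HEWL_RESIDUES",
    "GAS_CONSTANT_KJ",
    "AmplitudePartition",
    "FreeEnergyLadder",
    "amplitude_bin_fractions",
    "residue_occupancies",
    "free_energy_difference",
    "partition_series",
    "partition_table",
]

#: default S/M and M/L thresholds on r^2 (A^2)
DEFAULT_BOUNDS = (0.25, 1.0)

#: residues in hen egg white lysozyme
HEWL_RESIDUES = 129

#: gas constant in kJ/(mol K)
GAS_CONSTANT_KJ = 8.314462e-3


@dataclass(frozen=True)
class AmplitudePartition:
    """Small/medium/large amplitude-state fractions and residue counts at one T."""

    temperature: float
    bounds: tuple[float, float]
    fractions: tuple[float, float, float]
    residues: tuple[float, float, float]

    @property
    def n_residues(self) -> float:
        return sum(self.residues)

    def summary(self) -> str:
        f, n = self.fractions, self.residues
        return (f"T = {self.temperature:.1f} K: "
                f"S {f[0]:.3f} ({n[0]:.1f} res), "
                f"M {f[1]:.3f} ({n[1]:.1f} res), "
                f"L {f[2]:.3f} ({n[2]:.1f} res)")


@dataclass(frozen=True)
class FreeEnergyLadder:
    """Free-energy differences between successive amplitude states.

    Sign convention: positive when the second (product) state is less
    populated, dG = -RT ln(N2/N1).
    """

    temperature: float
    dG_SM: float
    dG_ML: float
    reference_state: str = "S"

    @property
    def dG_SL(self) -> float:
        """Chain rule: dG(S->L) = dG_SM + dG_ML."""
        return self.dG_SM + self.dG_ML

    def summary(self) -> str:
        return (f"T = {self.temperature:.1f} K: dG(S->M) = {self.dG_SM:+.3f}, "
                f"dG(M->L) = {self.dG_ML:+.3f} kJ/mol (reference "
                f"{self.reference_state})")


def amplitude_bin_fractions(r2_mean: float, beta: float,
                            bounds: Sequence[float] = DEFAULT_BOUNDS
                            ) -> tuple[float, float, float]:
    """Gamma-distribution mass in the S/M/L amplitude bins.

    The thresholds are fixed in r^2-space and converted to lambda-space by the
    mean fluctuation of that temperature (lambda = r^2 / <r2>); the fractions
    are regularized-incomplete-gamma differences and sum to one.  A zero mean
    fluctuation degenerates to all mass in S.
    """
    b1, b2 = float(bounds[0]), float(bounds[1])
    if not (0 < b1 < b2):
        raise ParameterError(f"bounds must be increasing and positive, got {bounds}")
    if r2_mean < 0:
        raise ParameterError(f"r2_mean must be >= 0, got {r2_mean}")
    if r2_mean == 0.0:
        return (1.0, 0.0, 0.0)
    cs = float(gamma_fluctuation_cdf(b1 / r2_mean, beta))
    cm = float(gamma_fluctuation_cdf(b2 / r2_mean, beta))
    return (cs, cm - cs, 1.0 - cm)


def residue_occupancies(fractions: Sequence[float],
                        n_residues: float = HEWL_RESIDUES
                        ) -> tuple[float, float, float]:
    """Scale state fractions to residue counts (real-valued, not rounded)."""
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ParameterError("fractions must sum to 1")
    return tuple(f * n_residues for f in fractions)  # type: ignore[return-value]


def free_energy_difference(n1: float, n2: float, temperature: float) -> float:
    """dG = -RT ln(N2/N1) in kJ/mol; antisymmetric under swapping N1 and N2."""
    if n1 <= 0 or n2 <= 0:
        raise ParameterError("occupancies must be > 0")
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    return -GAS_CONSTANT_KJ * temperature * math.log(n2 / n1)


def partition_series(mspf_results: Iterable, bounds: Sequence[float] = DEFAULT_BOUNDS,
                     n_residues: float = HEWL_RESIDUES,
                     ladder_temperature: float | None = None
                     ) -> tuple[list[AmplitudePartition], FreeEnergyLadder | None]:
    """Partition every temperature of a heterogeneity-fit series.

    `mspf_results` is any iterable of objects with attributes `temperature`,
    `r2` and `beta` (e.g. :class:`incoscat.eins.MspfResult`).  If
    `ladder_temperature` is given, the free-energy ladder (S->M, M->L) is
    computed from the partition at that temperature.
    """
    results = list(mspf_results)
    if not results:
        raise ParameterError("mspf_results must be nonempty")
    partitions = []
    for r in results:
        frac = amplitude_bin_fractions(r.r2, r.beta, bounds)
        partitions.append(AmplitudePartition(
            temperature=float(r.temperature), bounds=(float(bounds[0]), float(bounds[1])),
            fractions=frac, residues=residue_occupancies(frac, n_residues)))
    ladder = None
    if ladder_temperature is not None:
        match = [p for p in partitions
                 if math.isclose(p.temperature, ladder_temperature,
                                 rel_tol=1e-9, abs_tol=1e-6)]
        if not match:
            raise LookupError(
                f"no partition at T = {ladder_temperature} K "
                f"(available: {[p.temperature for p in partitions]})")
        p = match[0]
        ns, nm, nl = p.residues
        ladder = FreeEnergyLadder(
            temperature=p.temperature,
            dG_SM=free_energy_difference(ns, nm, p.temperature),
            dG_ML=free_energy_difference(nm, nl, p.temperature))
    return partitions, ladder


def partition_table(partitions: Iterable[AmplitudePartition]) -> pd.DataFrame:
    """Tidy export: (temperature, f_S, f_M, f_L, n_S, n_M, n_L)."""
    rows = []
    for p in partitions:
        rows.append({
            "temperature": p.temperature,
            "f_S": p.fractions[0], "f_M": p.fractions[1], "f_L": p.fractions[2],
            "n_S": p.residues[0], "n_M": p.residues[1], "n_L": p.residues[2],
        })
    return pd.DataFrame(rows)
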