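"""Catabolic thermodynamics: reaction free energy, energy flux, biomass yield.

ΔG = ΔG° + RT ln Q with activities approximated by molar concentrations
(activity coefficients 1, water activity 1, H+ from pH). A small table of
standard aqueous free energies of formation at 25 °C ships with the
package and can be overridden per reaction. No van 't Hoff temperature
correction of ΔGf° is applied: in situ temperatures here are within a few
kelvin of the standard state and the effect is far below the tolerances
used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "R_KJ_PER_MOL_K",
    "STANDARD_FORMATION_ENERGIES",
    "Reaction",
    "ThermoConditions",
    "YieldResult",
    "gibbs_free_energy",
    "energy_flux",
    "biomass_yield",
    "nitrite_oxidation",
    "ammonia_oxidation",
]

#: Gas constant in kJ mol-1 K-1.
R_KJ_PER_MOL_K: float = 8.314462618e-3

#: Standard Gibbs free energies of formation, kJ/mol, aqueous species at
#: 25 °C (O2 referenced to the element, H+ zero by convention).
STANDARD_FORMATION_ENERGIES: dict[str, float] = {
    "NO2-": -32.2,
    "NO3-": -111.3,
    "NH4+": -79.31,
    "NH3": -26.5,
    "O2": 0.0,
    "H2O": -237.13,
    "H+": 0.0,
}

#: Charges for the shipped species, used for a charge-balance sanity check.
_SPECIES_CHARGE: dict[str, int] = {
    "NO2-": -1,
    "NO3-": -1,
    "NH4+": 1,
    "NH3": 0,
    "O2": 0,
    "H2O": 0,
    "H+": 1,
}


@dataclass
class Reaction:
    """A catabolic reaction: signed stoichiometry (products +, reactants -).

    ``formation_energies`` overrides or extends the shipped ΔGf° table for
    this reaction's species.
    """

    name: str
    stoichiometry: Mapping[str, float]
    formation_energies: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError("empty stoichiometry")
        # charge balance can only be checked when all charges are known
        charges = [_SPECIES_CHARGE.get(s) for s in self.stoichiometry]
        if all(c is not None for c in charges):
            net = sum(
                nu * _SPECIES_CHARGE[s] for s, nu in self.stoichiometry.items()
            )
            if abs(net) > 1e-9:
                raise ValueError(f"reaction {self.name!r} is not charge balanced (net {net:+g})")

    def dgf(self, species: str) -> float:
        if species in self.formation_energies:
            return self.formation_energies[species]
        if species in STANDARD_FORMATION_ENERGIES:
            return STANDARD_FORMATION_ENERGIES[species]
        raise KeyError(species)

    def standard_delta_g(self) -> float:
        """ΔG° = Σ ν ΔGf°, kJ/mol."""
        missing = [
            s
            for s in self.stoichiometry
            if s not in self.formation_energies and s not in STANDARD_FORMATION_ENERGIES
        ]
        if missing:
            raise ValueError(f"no formation energy for species: {sorted(missing)}")
        return sum(nu * self.dgf(s) for s, nu in self.stoichiometry.items())


@dataclass
class ThermoConditions:
    """In situ conditions: temperature (K), species concentrations (mol/L), pH.

    Concentrations are used directly as activities; water activity is 1
    and H+ activity comes from the pH.
    """

    temperature_k: float
    concentrations: Mapping[str, float]
    ph: float = 8.1

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")
        for s, c in self.concentrations.items():
            if c <= 0:
                raise ValueError(f"concentration of {s} must be positive")

    def activity(self, species: str) -> float:
        if species == "H2O":
            return 1.0
        if species == "H+":
            return 10.0 ** (-self.ph)
        if species not in self.concentrations:
            raise KeyError(species)
        return self.concentrations[species]


@dataclass
class YieldResult:
    """Energy flux and biomass yield for one catabolic population."""

    delta_g_kj_mol: float
    energy_flux_j_l_d: float
    c_assim_nmol_l_d: float
    yield_nmol_c_per_j: float


def gibbs_free_energy(rxn: Reaction, cond: ThermoConditions) -> float:
    """ΔG (kJ/mol) under in situ conditions: ΔG° + RT ln Q.

    Q is the activity quotient with signed stoichiometric exponents.
    Raises ValueError naming any species lacking a formation energy or a
    concentration.
    """
    dg0 = rxn.standard_delta_g()
    missing = []
    ln_q = 0.0
    for species, nu in rxn.stoichiometry.items():
        try:
            a = cond.activity(species)
        except KeyError:
            missing.append(species)
            continue
        ln_q += nu * math.log(a)
    if missing:
        raise ValueError(f"no concentration for species: {sorted(missing)}")
    return dg0 + R_KJ_PER_MOL_K * cond.temperature_k * ln_q


def energy_flux(bulk_rate_nmol_l_d: float, delta_g_kj_mol: float) -> float:
    """Catabolic energy flux (J L-1 d-1) from a bulk rate and ΔG.

    nmol * kJ/mol = µJ, hence the 1e-6 factor; the magnitude of ΔG is
    used so exergonic (negative) values give a positive flux.
    """
    if bulk_rate_nmol_l_d < 0:
        raise ValueError("bulk rate must be non-negative")
    return bulk_rate_nmol_l_d * abs(delta_g_kj_mol) * 1e-6


def biomass_yield(c_assim_nmol_l_d: float, flux_j_l_d: float) -> float:
    """Biomass yield (nmol-C J-1) = C assimilated per Joule dissipated."""
    if flux_j_l_d <= 0:
        raise ValueError("energy flux must be positive")
    if c_assim_nmol_l_d < 0:
        raise ValueError("C assimilation must be non-negative")
    return c_assim_nmol_l_d / flux_j_l_d


def nitrite_oxidation(**formation_energies: float) -> Reaction:
    """NO2- + 1/2 O2 -> NO3-."""
    return Reaction(
        name="nitrite_oxidation",
        stoichiometry={"NO2-": -1.0, "O2": -0.5, "NO3-": 1.0},
        formation_energies=formation_energies,
    )


def ammonia_oxidation(**formation_energies: float) -> Reaction:
    """NH4+ + 3/2 O2 -> NO2- + H2O + 2 H+."""
    return Reaction(
        name="ammonia_oxidation",
        stoichiometry={"NH4+": -1.0, "O2": -1.5, "NO2-": 1.0, "H2O": 1.0, "H+": 2.0},
        formation_energies=formation_energies,
    )
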