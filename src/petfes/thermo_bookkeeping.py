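"""Closed-form thermodynamic arithmetic on simulation free energies.

Connects box-volume binding free energies to standard-state quantities,
population-depletion factors, per-monomer costs, and the fold-surface
conversion used to compare chain-detachment energetics with lamellar
crystal measurements.  Sign conventions: corrections are reported in the
binding direction (negative for boxes larger than the 1 M volume);
unbinding free energies are positive for bound-favoring systems.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import ThermoConstants
from .errors import PetfesError

__all__ = [
    "ThermoConstants",
    "SurfaceEnergetics",
    "standard_state_correction",
    "standard_unbinding",
    "population_depletion_factor",
    "per_monomer",
    "fold_surface_cost",
]

_C = ThermoConstants()


@dataclass(frozen=True)
class SurfaceEnergetics:
    """Fold-surface free energy and chain cross-section of a polymer crystal."""

    sigma_e: float = 0.106      # J/m^2
    A_chain: float = 0.20       # nm^2

    def __post_init__(self) -> None:
        if self.sigma_e < 0 or self.A_chain < 0:
            raise PetfesError("surface energetics must be non-negative")


def standard_state_correction(V_box: float, T: float = _C.T,
                              constants: ThermoConstants = _C) -> float:
    """Standard-state correction -kB T ln(V_box / V_standard), kJ/mol.

    Negative for boxes larger than the 1 M volume per molecule: releasing
    the ligand into a larger box overestimates the unbound entropy, so
    binding at 1 M is more favorable than in the box.
    """
    if V_box <= 0:
        raise PetfesError(f"box volume must be positive, got {V_box}")
    return -constants.kB * T * math.log(V_box / constants.V_standard)


def standard_unbinding(dF_box: float, V_box: float, T: float = _C.T,
                       constants: ThermoConstants = _C) -> float:
    """Standard unbinding free energy dF_unbind = -(dF_box + correction)."""
    if not math.isfinite(dF_box):
        raise PetfesError("dF_box must be finite")
    return -(dF_box + standard_state_correction(V_box, T, constants))


def population_depletion_factor(dF: float, T: float = _C.T,
                                constants: ThermoConstants = _C) -> float:
    """Fold-change exp(dF / kB T) by which a penalty dF depletes a state."""
    if not math.isfinite(dF):
        raise PetfesError("dF must be finite")
    if T <= 0:
        raise PetfesError(f"temperature must be positive, got {T}")
    return math.exp(dF / (constants.kB * T))


def per_monomer(dF: float, n_monomers: int) -> float:
    """Free energy per repeat unit, dF / n."""
    if n_monomers < 1:
        raise PetfesError(f"n_monomers must be >= 1, got {n_monomers}")
    return dF / n_monomers


def fold_surface_cost(surface: SurfaceEnergetics,
                      constants: ThermoConstants = _C) -> float:
    """Detachment cost per repeat unit from fold-surface energetics, kJ/mol.

    dF = 2 sigma_e A_chain N_A: creating two fold surfaces of one chain
    cross-section each.  sigma_e in J/m^2 and A_chain in nm^2 combine as
    1 nm^2 = 1e-18 m^2; the result is converted J -> kJ.
    """
    joules_per_molecule = 2.0 * surface.sigma_e * surface.A_chain * 1e-18
    return joules_per_molecule * constants.N_A / 1000.0
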