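"""Physical constants and default thermodynamic conditions.

Units used throughout the package: kJ/mol for energies, nm for
distances, degrees for angles, Kelvin for temperatures.
"""
from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kJ mol^-1 K^-1 (molar gas constant).
KB = 0.0083144621

#: Avogadro constant, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Volume per molecule at the 1 M standard state, nm^3.
V_STANDARD = 1.66054

#: Default bookkeeping temperature, K (25 C).
T_STANDARD = 298.15

#: Default coarse-grained sampling temperature, K.
T_SAMPLING = 300.0

#: Temperature of the experimental amorphous gauche/trans ratio, K (30 C).
T_CALIBRATION = 303.15


def kbt(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


@dataclass(frozen=True)
class ThermoConstants:
    """Bundle of constants entering the thermodynamic bookkeeping."""

    kB: float = KB
    N_A: float = N_AVOGADRO
    V_standard: float = V_STANDARD
    T: float = T_STANDARD

    def __post_init__(self) -> None:
        for name in ("kB", "N_A", "V_standard", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
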