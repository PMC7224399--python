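"""Reduced Lennard-Jones unit system for the coarse-grained diabody models.

Lengths are measured in sigma = 3.5 angstrom (the linker monomer size) and the
native energy unit of the model is epsilon = 100 K.  Internally every energy in
this package is expressed in units of the thermal energy kT at room temperature
(300 K), so that kT_reduced = 1 and kBT = 3 epsilon.  Times are quoted in the
Brownian time tau_B = gamma sigma^2 / kT of a unit-drag bead.
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.constants as _const

#: length unit in angstrom (one linker monomer diameter)
SIGMA_ANGSTROM = 3.5
#: native energy unit in kelvin
EPSILON_KELVIN = 100.0
#: reference temperature in kelvin
ROOM_TEMPERATURE_K = 300.0
#: thermal energy in native epsilon units: kBT = T/eps_K
KT_IN_EPSILON = ROOM_TEMPERATURE_K / EPSILON_KELVIN


@dataclass(frozen=True)
class UnitSystem:
    """Bookkeeping for the reduced unit system.

    ``kT_reduced`` is the thermal energy in the internal energy unit; the
    package works in kT units so the default is exactly 1.
    """

    sigma_angstrom: float = SIGMA_ANGSTROM
    epsilon_kelvin: float = EPSILON_KELVIN
    kT_reduced: float = 1.0
    time_unit_label: str = "tau_B"

    def __post_init__(self) -> None:
        if self.sigma_angstrom <= 0 or self.epsilon_kelvin <= 0 or self.kT_reduced <= 0:
            raise ValueError("unit system scales must be positive")

    @property
    def kT_in_epsilon(self) -> float:
        """Thermal energy at 300 K expressed in the native epsilon unit."""
        return ROOM_TEMPERATURE_K / self.epsilon_kelvin


def spring_constant_si_to_reduced(
    k_si_newton_per_metre: float,
    temperature_K: float = ROOM_TEMPERATURE_K,
    sigma_angstrom: float = SIGMA_ANGSTROM,
) -> float:
    """Convert a spring constant from N/m to kT/sigma^2.

    Used for the linker bond stiffness, quoted as 54 N/m: at 300 K and
    sigma = 3.5 angstrom this is ~1.6e3 kT/sigma^2, giving relative bond
    fluctuations sqrt(kT/k)/r0 of ~2.5%.
    """
    sigma_m = sigma_angstrom * 1e-10
    kT_joule = _const.k * temperature_K
    return k_si_newton_per_metre * sigma_m**2 / kT_joule


#: linker bond stiffness (54 N/m) in kT/sigma^2, 1/2 k (r-r0)^2 convention
LINKER_BOND_K = spring_constant_si_to_reduced(54.0)
#: linker bending coefficient in kT (Kratky-Porod cosine form by default)
LINKER_BEND_K = 1.8
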