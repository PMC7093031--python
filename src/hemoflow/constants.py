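"""Physical constants shared across the fluid and membrane models."""

from dataclasses import dataclass

#: Boltzmann constant [J/K]
KB = 1.380649e-23
#: Reference temperature [K]; membrane coefficients are quoted in multiples of kBT
T_REF = 300.0
#: Thermal energy scale [J]
KBT = KB * T_REF


@dataclass(frozen=True)
class PhysicalConstants:
    """Plasma fluid constants and the thermal energy unit.

    Attributes
    ----------
    kBT:
        Thermal energy [J]. Membrane stiffness coefficients are expressed
        as multiples of this value.
    plasma_kinematic_viscosity:
        Kinematic viscosity of blood plasma [m^2/s].
    plasma_density:
        Mass density of blood plasma [kg/m^3].
    """

    kBT: float = KBT
    plasma_kinematic_viscosity: float = 1.1e-6
    plasma_density: float = 1025.0

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        if self.plasma_kinematic_viscosity <= 0 or self.plasma_density <= 0:
            raise ValueError("plasma viscosity and density must be positive")

    @property
    def plasma_dynamic_viscosity(self) -> float:
        """Dynamic viscosity mu = eta * rho [Pa s]."""
        return self.plasma_kinematic_viscosity * self.plasma_density


DEFAULT_CONSTANTS = PhysicalConstants()
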