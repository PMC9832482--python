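"""Thermodynamic context shared by all energy computations.

All energies in this package are in kJ·mol⁻¹, temperatures in kelvin,
angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Molar gas constant in kJ·mol⁻¹·K⁻¹ (k_B·N_A).
GAS_CONSTANT = 0.0083145


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and the derived thermal energy RT.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    """

    temperature: float = 300.0
    RT: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        object.__setattr__(self, "RT", GAS_CONSTANT * self.temperature)

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/RT in mol·kJ⁻¹."""
        return 1.0 / self.RT
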