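"""Experimental conditions and physical constants.

Every energy in the package is in kcal·mol⁻¹, every rate in s⁻¹, and every
denaturant concentration in mol·L⁻¹; this module pins the gas constant and
sample temperature used to interconvert them.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant in kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class Conditions:
    """Sample conditions shared by all thermodynamic conversions.

    Parameters
    ----------
    temperature : float
        Sample temperature in kelvin.  Defaults to 298 K, the temperature at
        which the stopped-flow and equilibrium experiments are analysed.
    gas_constant : float
        Gas constant in kcal·mol⁻¹·K⁻¹.  Fixed by convention; exposed so the
        record is self-describing.
    denaturant_name : str
        Label for the chemical denaturant (urea throughout).
    ph_or_pd : float
        Solution pH (or direct-reading pD for exchange experiments).
    """

    temperature: float = 298.0
    gas_constant: float = R_KCAL
    denaturant_name: str = "urea"
    ph_or_pd: float = 7.6

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not self.gas_constant > 0:
            raise ValueError("gas_constant must be positive")

    @property
    def rt(self) -> float:
        """R·T in kcal·mol⁻¹."""
        return self.gas_constant * self.temperature


def rt(conditions: Conditions) -> float:
    """Return R·T for *conditions*, in kcal·mol⁻¹."""
    return conditions.rt
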