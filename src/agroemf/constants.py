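"""Physical constants and soil conversion defaults.

All constants are overridable through :class:`SoilConstants`; the defaults
are the values used throughout the analysis and echoed to run logs for
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._errors import DomainError

#: Standard atomic masses (IUPAC 2021 abridged), g/mol.
ATOMIC_MASS_C = 12.011
ATOMIC_MASS_O = 15.999


def c_to_co2_factor(ndigits: int = 2) -> float:
    """Mass ratio CO2 : C from standard atomic masses, rounded.

    With the default rounding this yields the conventional factor 3.66
    used to convert a soil carbon mass flux into a CO2 mass flux.
    """
    ratio = (ATOMIC_MASS_C + 2.0 * ATOMIC_MASS_O) / ATOMIC_MASS_C
    return round(ratio, ndigits)


@dataclass(frozen=True)
class SoilConstants:
    """Soil-related conversion constants.

    Attributes
    ----------
    bulk_density:
        Dry soil bulk density in kg/m^3.
    n_mixing_depth:
        Depth (m) over which mineral nitrogen is assumed to mix.
    c_accounting_depth:
        Depth (m) over which soil organic carbon is accounted.
    c_to_co2:
        Mass conversion factor from carbon to carbon dioxide.
    mirr_factor:
        Multiplier converting maximum initial respiratory response
        (ul O2 / g dry soil) into microbial biomass (ug C / g dry soil).
    """

    bulk_density: float = 1350.0
    n_mixing_depth: float = 0.20
    c_accounting_depth: float = 0.30
    c_to_co2: float = c_to_co2_factor()
    mirr_factor: float = 38.0

    def __post_init__(self) -> None:
        for name in (
            "bulk_density",
            "n_mixing_depth",
            "c_accounting_depth",
            "c_to_co2",
            "mirr_factor",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"SoilConstants.{name} must be strictly positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "bulk_density": self.bulk_density,
            "n_mixing_depth": self.n_mixing_depth,
            "c_accounting_depth": self.c_accounting_depth,
            "c_to_co2": self.c_to_co2,
            "mirr_factor": self.mirr_factor,
        }


DEFAULT_SOIL = SoilConstants()
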