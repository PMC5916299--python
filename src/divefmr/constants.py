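"""Registry of physical and equation constants used in the doubly-labeled-water
(DLW) calculations.

Every numeric constant that enters a CO2-production or water-flux equation is
kept here with its source, so the transcription from the primary literature is
auditable in one place and nothing is hard-coded inline in the math.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping


@dataclass(frozen=True)
class Constant:
    value: float
    units: str
    source: str


#: Default constants registry. Values may be overridden by passing a mapping of
#: name -> float to the functions in :mod:`divefmr.dlw`.
DEFAULT_CONSTANTS: Mapping[str, Constant] = {
    # Denominator of the CO2-production term shared by the single-pool and
    # two-pool equations (accounts for the stoichiometry of O exchange between
    # body water and CO2 via carbonic anhydrase).
    "co2_denominator": Constant(2.078, "dimensionless", "Nagy (1980); Speakman, Nair & Goran (1993)"),
    # Fractionated-evaporation correction coefficient.
    "fractionation_coeff": Constant(0.0062, "dimensionless", "Nagy (1980); Speakman, Nair & Goran (1993)"),
    # Population-average dilution-space ratio N_d/N_o used when ratio_mode='fixed'.
    "dilution_space_ratio": Constant(1.0427, "dimensionless", "Speakman, Nair & Goran (1993)"),
    # Energy equivalent of respiratory CO2 for a carnivore diet.
    "energy_per_l_co2": Constant(23.6, "kJ/L CO2", "Costa (1987)"),
    # Molar volume of an ideal gas at STP, used to convert mol CO2 to volume.
    "molar_volume_stp": Constant(22.4, "L/mol", "physical constant (STP)"),
    # Molar mass of water.
    "water_molar_mass": Constant(18.02, "g/mol", "physical constant"),
    # ppm excess -> mole-fraction excess.
    "ppm_to_mole_fraction": Constant(1e-6, "dimensionless", "unit definition"),
}


def resolve_constants(overrides: Mapping[str, float] | None = None) -> dict[str, float]:
    """Return a plain name->value mapping, applying any overrides.

    Unknown override keys raise ``KeyError`` so typos cannot silently change
    the physics.
    """
    values = {name: c.value for name, c in DEFAULT_CONSTANTS.items()}
    if overrides:
        for name, val in overrides.items():
            if name not in values:
                raise KeyError(f"unknown constant {name!r}")
            values[name] = float(val)
    return values


def constants_provenance() -> dict[str, dict[str, object]]:
    """Citation record for every registered constant (for provenance sidecars)."""
    return {
        name: {"value": c.value, "units": c.units, "source": c.source}
        for name, c in DEFAULT_CONSTANTS.items()
    }
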