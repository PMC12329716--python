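"""Total CO2 and CH4 production from headspace measurements.

Sealed anaerobic microcosms are sampled by headspace gas chromatography,
but a substantial share of the produced gas stays dissolved in the liquid
phase — especially CO2, whose solubility is boosted at circumneutral pH by
speciation into bicarbonate and carbonate.  Total production per tube is

    n_total = n_headspace + c_dissolved * V_liquid

with headspace moles from the ideal gas law and dissolved concentration
from Henry's law, temperature-adjusted via the van 't Hoff relation and
(for CO2) multiplied by the carbonate speciation factor
``1 + K1/[H+] + K1*K2/[H+]^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

R_L_ATM = 0.082057  # gas constant, L·atm/(mol·K)
T_REF = 298.15  # K

__all__ = [
    "GasSample",
    "HenryConstants",
    "STORDALEN_PRESET",
    "headspace_moles",
    "henry_constant",
    "dissolved_concentration",
    "total_gas",
    "media_molarity",
]


@dataclass(frozen=True)
class GasSample:
    """One headspace measurement of one gas in one sealed tube."""

    sample_id: str
    day: int
    gas: str  # "CO2" or "CH4"
    headspace_ppm: float
    temperature: float  # K
    pH: float
    headspace_volume: float  # L
    liquid_volume: float  # L
    total_pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        if self.gas not in ("CO2", "CH4"):
            raise ValueError(f"unknown gas {self.gas!r}")
        if self.headspace_ppm < 0:
            raise ValueError("ppm must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if not 0 < self.pH < 14:
            raise ValueError("pH out of range")
        if self.headspace_volume <= 0 or self.liquid_volume < 0:
            raise ValueError("volumes must be positive")


@dataclass(frozen=True)
class HenryConstants:
    """Henry solubilities at 298.15 K, van 't Hoff temperature coefficients,
    and carbonic acid dissociation constants (25 °C values)."""

    kh_298_co2: float = 3.4e-2  # mol/(L·atm)
    kh_298_ch4: float = 1.4e-3
    vant_hoff_c_co2: float = 2400.0  # K
    vant_hoff_c_ch4: float = 1700.0
    k1: float = 10 ** -6.35
    k2: float = 10 ** -10.33

    def __post_init__(self) -> None:
        for name in ("kh_298_co2", "kh_298_ch4", "vant_hoff_c_co2",
                     "vant_hoff_c_ch4", "k1", "k2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def kh_298(self, gas: str) -> float:
        return self.kh_298_co2 if gas == "CO2" else self.kh_298_ch4

    def vant_hoff_c(self, gas: str) -> float:
        return self.vant_hoff_c_co2 if gas == "CO2" else self.vant_hoff_c_ch4


# Balch-tube incubation geometry: ~26 mL tube, 11 mL liquid, 19 °C.
STORDALEN_PRESET = {
    "headspace_volume": 0.015,
    "liquid_volume": 0.011,
    "temperature": 292.15,
    "total_pressure": 1.0,
}


def headspace_moles(sample: GasSample) -> float:
    """Moles of the gas in the headspace, ideal-gas behavior assumed."""
    p_partial = sample.headspace_ppm * 1e-6 * sample.total_pressure
    return p_partial * sample.headspace_volume / (R_L_ATM * sample.temperature)


def henry_constant(gas: str, temperature: float,
                   constants: HenryConstants | None = None) -> float:
    """Temperature-adjusted Henry solubility, mol/(L·atm).

    KH(T) = KH(298.15) * exp(C * (1/T - 1/298.15)).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    constants = constants or HenryConstants()
    import math

    return constants.kh_298(gas) * math.exp(
        constants.vant_hoff_c(gas) * (1.0 / temperature - 1.0 / T_REF)
    )


def co2_speciation_factor(pH: float, constants: HenryConstants | None = None) -> float:
    """Ratio of total dissolved inorganic carbon to free aqueous CO2."""
    constants = constants or HenryConstants()
    h = 10.0 ** (-pH)
    return 1.0 + constants.k1 / h + constants.k1 * constants.k2 / h**2


def dissolved_concentration(gas: str, partial_pressure: float, pH: float,
                            temperature: float,
                            constants: HenryConstants | None = None) -> float:
    """Dissolved concentration (mol/L) in equilibrium with the headspace.

    CH4 dissolves as the free gas only; CO2 additionally speciates into
    bicarbonate and carbonate, scaling the dissolved pool by the
    pH-dependent speciation factor.
    """
    if partial_pressure < 0:
        raise ValueError("partial pressure must be nonnegative")
    constants = constants or HenryConstants()
    c_free = henry_constant(gas, temperature, constants) * partial_pressure
    if gas == "CO2":
        return c_free * co2_speciation_factor(pH, constants)
    return c_free


def total_gas(sample: GasSample, constants: HenryConstants | None = None,
              peat_mass_g: float | None = None) -> float:
    """Total moles produced: headspace plus dissolved phase.

    Returns micromoles per gram of peat instead when ``peat_mass_g`` is
    supplied.
    """
    constants = constants or HenryConstants()
    p_partial = sample.headspace_ppm * 1e-6 * sample.total_pressure
    n_head = headspace_moles(sample)
    c_diss = dissolved_concentration(
        sample.gas, p_partial, sample.pH, sample.temperature, constants
    )
    total = n_head + c_diss * sample.liquid_volume
    if peat_mass_g is not None:
        if peat_mass_g <= 0:
            raise ValueError("peat mass must be positive")
        return total * 1e6 / peat_mass_g
    return total


def media_molarity(mass_g_per_l: float, molar_mass_g_per_mol: float) -> float:
    """Micromolar concentration of a media salt, to 3 significant figures.

    >>> media_molarity(0.25, 53.49)  # NH4Cl
    4670.0
    """
    if mass_g_per_l <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("mass and molar mass must be positive")
    um = mass_g_per_l / molar_mass_g_per_mol * 1e6
    # round to 3 significant figures
    from math import floor, log10

    ndigits = 2 - floor(log10(abs(um)))
    return round(um, ndigits)
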