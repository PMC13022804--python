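"""Dissolved-gas chemistry: Henry's-law solubility and percent saturation.

Converts among dissolved concentration (``c_aq``), atmospheric-equilibrium
concentration (``c_sat``) and percent saturation for the four gases tracked
by the pipeline (CO2, CH4, N2O, O2) in fresh water at 1 atm:

.. math:: \\mathrm{saturation\\,\\%} = 100 \\, c_{aq} / c_{sat}

Solubility formulations (all evaluated at zero salinity):

* CO2 — Weiss (1974) K0 polynomial, mol L-1 atm-1.
* CH4 — Wiesenburg & Guinasso (1979) Bunsen coefficient divided by the
  ideal molar volume (22.414 L mol-1), mol L-1 atm-1.
* N2O — Weiss & Price (1980) K0 polynomial, mol L-1 atm-1.
* O2 — Benson & Krause (1984) equation for air-saturated fresh water
  (the USGS standard), mg L-1 at 1 atm moist air.

A packaged table of NOAA annual global-mean mixing ratios (2000-2022)
supplies the atmospheric boundary condition.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GAS_SPECIES",
    "GasSpecies",
    "SaturationRecord",
    "henry_constant",
    "equilibrium_concentration",
    "saturation_percent",
    "concentration_from_saturation",
    "do_solubility",
    "do_saturation",
    "load_atmosphere",
    "period_mean_atmosphere",
]

TEMP_RANGE_C = (0.0, 40.0)

#: Molar volume of an ideal gas at STP, L mol-1 (converts Bunsen coefficients).
_MOLAR_VOLUME_STP = 22.414


@dataclass(frozen=True)
class GasSpecies:
    """A supported gas and its element-basis reporting convention.

    ``element_mass`` is the grams of reporting element per mole of gas:
    carbon for CO2 and CH4 (12.011), nitrogen for N2O (28.014, two N atoms),
    and for O2 the full molecular mass since DO is reported as mass of O2.
    ``molecular_mass`` converts the element basis back to mass of gas for
    CO2-equivalent accounting.
    """

    name: str
    element_mass: float
    molecular_mass: float
    mixing_ratio_unit: str  # "ppm" or "ppb"


GAS_SPECIES: dict[str, GasSpecies] = {
    "CO2": GasSpecies("CO2", 12.011, 44.009, "ppm"),
    "CH4": GasSpecies("CH4", 12.011, 16.043, "ppm"),
    "N2O": GasSpecies("N2O", 28.014, 44.013, "ppb"),
    "O2": GasSpecies("O2", 31.998, 31.998, "ppm"),
}

# Weiss (1974) freshwater K0 for CO2, ln K0 in mol L-1 atm-1 with T in K.
_WEISS_CO2 = (-58.0931, 90.5069, 22.2940)
# Weiss & Price (1980) K0 for N2O, same functional form.
_WEISS_PRICE_N2O = (-62.7062, 97.3066, 24.1406)
# Wiesenburg & Guinasso (1979) Bunsen coefficient for CH4.
_WG_CH4 = (-68.8862, 101.4956, 28.7314)


def _require_gas(gas: str | GasSpecies) -> GasSpecies:
    if isinstance(gas, GasSpecies):
        return gas
    try:
        return GAS_SPECIES[gas]
    except KeyError:
        raise ValueError(
            f"unsupported gas {gas!r}; expected one of {sorted(GAS_SPECIES)}"
        ) from None


def _check_temperature(temperature):
    t = np.asarray(temperature, dtype=float)
    lo, hi = TEMP_RANGE_C
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(f"temperature must lie in [{lo}, {hi}] degC, got {temperature}")
    return t


def _k0_polynomial(coefs, t_kelvin):
    a1, a2, a3 = coefs
    return np.exp(a1 + a2 * (100.0 / t_kelvin) + a3 * np.log(t_kelvin / 100.0))


def henry_constant(gas: str | GasSpecies, temperature: float) -> float:
    """Freshwater Henry solubility, mol L-1 atm-1, at ``temperature`` degC.

    Strictly decreasing in temperature over the supported range
    [0, 40] degC for every gas.
    """
    species = _require_gas(gas)
    t = _check_temperature(temperature)
    t_k = t + 273.15
    if species.name == "CO2":
        out = _k0_polynomial(_WEISS_CO2, t_k)
    elif species.name == "N2O":
        out = _k0_polynomial(_WEISS_PRICE_N2O, t_k)
    elif species.name == "CH4":
        out = _k0_polynomial(_WG_CH4, t_k) / _MOLAR_VOLUME_STP
    else:  # O2: Bunsen-style fit (Weiss 1970), used for mol-basis work.
        out = _k0_polynomial((-58.3877, 85.8079, 23.8439), t_k) / _MOLAR_VOLUME_STP
    return out if out.ndim else float(out)


def equilibrium_concentration(
    gas: str | GasSpecies,
    temperature: float,
    mixing_ratio: float,
    pressure_atm: float = 1.0,
) -> float:
    """Atmospheric-equilibrium concentration c_sat, mol L-1.

    ``mixing_ratio`` is in the unit declared for the gas (ppm for CO2/CH4/O2,
    ppb for N2O). Linear in both mixing ratio and total pressure.
    """
    species = _require_gas(gas)
    x = np.asarray(mixing_ratio, dtype=float)
    if np.any(x < 0):
        raise ValueError("mixing ratio must be non-negative")
    scale = 1e-6 if species.mixing_ratio_unit == "ppm" else 1e-9
    out = henry_constant(species, temperature) * x * scale * pressure_atm
    return out if np.ndim(out) else float(out)


def saturation_percent(c_aq: float, c_sat: float) -> float:
    """Percent saturation, 100 * c_aq / c_sat. Requires c_sat > 0."""
    c_sat_arr = np.asarray(c_sat, dtype=float)
    if np.any(c_sat_arr <= 0):
        raise ValueError("c_sat must be strictly positive")
    out = 100.0 * np.asarray(c_aq, dtype=float) / c_sat_arr
    return out if np.ndim(out) else float(out)


def concentration_from_saturation(saturation: float, c_sat: float) -> float:
    """Invert :func:`saturation_percent`: c_aq = saturation/100 * c_sat."""
    sat = np.asarray(saturation, dtype=float)
    if np.any(sat < 0):
        raise ValueError("saturation must be non-negative")
    out = sat / 100.0 * np.asarray(c_sat, dtype=float)
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class SaturationRecord:
    """A gas's dissolved state at known temperature and atmosphere."""

    gas: GasSpecies
    temperature: float
    c_aq: float
    c_sat: float

    @property
    def saturation(self) -> float:
        return saturation_percent(self.c_aq, self.c_sat)


# Benson & Krause (1984) coefficients for DO in fresh water at 1 atm, mg L-1.
_BENSON_KRAUSE = (-139.34411, 1.575701e5, -6.642308e7, 1.2438e10, -8.621949e11)


def do_solubility(temperature: float, pressure_atm: float = 1.0) -> float:
    """Air-saturation DO concentration in fresh water, mg L-1.

    Benson-Krause equation at 1 atm moist air; scaled linearly for other
    total pressures (adequate for the near-sea-level use here).
    """
    t_k = _check_temperature(temperature) + 273.15
    a0, a1, a2, a3, a4 = _BENSON_KRAUSE
    ln_c = a0 + a1 / t_k + a2 / t_k**2 + a3 / t_k**3 + a4 / t_k**4
    out = np.exp(ln_c) * pressure_atm
    return out if np.ndim(out) else float(out)


def do_saturation(do_conc: float, temperature: float, pressure_atm: float = 1.0) -> float:
    """Percent DO saturation for a concentration in mg L-1."""
    return saturation_percent(do_conc, do_solubility(temperature, pressure_atm))


@functools.lru_cache(maxsize=1)
def load_atmosphere() -> pd.DataFrame:
    """NOAA annual global-mean mixing ratios, indexed by year (2000-2022)."""
    with resources.files("riverghg.data").joinpath("atmosphere.csv").open() as fh:
        table = pd.read_csv(fh).set_index("year")
    return table


def period_mean_atmosphere(year_start: int = 2002, year_end: int = 2022) -> dict[str, float]:
    """Period-mean mixing ratios {gas: value in its declared unit}.

    Defaults to the 2002-2022 reconstruction window; xCH4 is returned in ppm
    and xN2O in ppb, matching :data:`GAS_SPECIES` conventions.
    """
    table = load_atmosphere().loc[year_start:year_end]
    if table.empty:
        raise ValueError(f"atmosphere table has no rows in [{year_start}, {year_end}]")
    return {
        "CO2": float(table["xCO2_ppm"].mean()),
        "CH4": float(table["xCH4_ppm"].mean()),
        "N2O": float(table["xN2O_ppb"].mean()),
    }
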