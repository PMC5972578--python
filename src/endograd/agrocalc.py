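"""Experiment-design arithmetic: thermal time and nutrient nitrogen.

Two small utilities used when planning controlled-environment grain-filling
experiments: aligning sampling days between temperature regimes by
accumulated thermal time (degree-days above a base temperature), and
totalling the nitrogen supplied by a liquid nutrient recipe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: atomic mass of nitrogen, mg per mmol
NITROGEN_MOLAR_MASS = 14.0067

#: base temperature (deg C) below which wheat development is assumed to stop
DEFAULT_BASE_TEMP = 4.1


@dataclass
class ThermalRegime:
    """A day/night square-wave temperature programme.

    Symmetric day-night transition ramps leave the daily mean unchanged, so
    ramp shape is ignored and only the plateau temperatures and photoperiod
    matter.
    """

    day_temp: float
    night_temp: float
    day_hours: float = 16.0
    base_temp: float = DEFAULT_BASE_TEMP

    def __post_init__(self) -> None:
        if not 0 < self.day_hours < 24:
            raise ValueError("day_hours must be in (0, 24)")
        if self.day_temp < self.night_temp:
            raise ValueError("day_temp must be >= night_temp")


def daily_thermal_time(regime: ThermalRegime) -> float:
    """Degree-days accumulated per calendar day under the regime.

    Photoperiod-weighted daily mean temperature minus the base temperature:
    ((day*h_day + night*(24-h_day)) / 24) - base.
    """
    mean = (regime.day_temp * regime.day_hours
            + regime.night_temp * (24.0 - regime.day_hours)) / 24.0
    tt = mean - regime.base_temp
    if tt <= 0:
        raise ValueError(
            f"daily mean {mean:.2f} degC is not above base {regime.base_temp} degC")
    return tt


def equivalent_day(reference: ThermalRegime, reference_days: float,
                   target: ThermalRegime) -> int:
    """Sampling day under `target` matching the thermal time of `reference`.

    reference_days * daily(reference) / daily(target), rounded to the nearest
    whole day (halves away from zero).
    """
    ratio = daily_thermal_time(reference) / daily_thermal_time(target)
    exact = reference_days * ratio
    return int(math.floor(exact + 0.5)) if exact >= 0 else int(math.ceil(exact - 0.5))


@dataclass
class NutrientComponent:
    compound: str
    molarity_mm: float
    n_atoms: int
    chelator: bool = False  # organically bound N (e.g. EDTA), excluded by default

    def __post_init__(self) -> None:
        if self.molarity_mm < 0:
            raise ValueError("molarity must be >= 0")
        if self.n_atoms < 0 or int(self.n_atoms) != self.n_atoms:
            raise ValueError("n_atoms must be a non-negative integer")


@dataclass
class NutrientRecipe:
    components: list[NutrientComponent] = field(default_factory=list)
    volume_per_application_l: float = 0.5
    n_applications: int = 9

    def __post_init__(self) -> None:
        if self.volume_per_application_l < 0 or self.n_applications < 0:
            raise ValueError("volume and application count must be >= 0")


def nitrogen_mass(recipe: NutrientRecipe, include_chelators: bool = False) -> float:
    """Total nitrogen supplied by the recipe, in mg.

    Sum over components of molarity (mmol/l) x N atoms x 14.0067 mg/mmol x
    volume per application x number of applications.  Chelator-bound
    nitrogen (FeNaEDTA) is excluded unless ``include_chelators`` is set,
    since only mineral nitrate/ammonium nitrogen is plant-available on the
    relevant timescale.
    """
    total = 0.0
    for comp in recipe.components:
        if comp.chelator and not include_chelators:
            continue
        total += (comp.molarity_mm * comp.n_atoms * NITROGEN_MOLAR_MASS
                  * recipe.volume_per_application_l * recipe.n_applications)
    return total


def high_nitrogen_recipe() -> NutrientRecipe:
    """The high-nitrogen liquid feed: 4 mM calcium nitrate, 9 x 0.5 l."""
    return NutrientRecipe(components=_base_components(canitrate_mm=4.0))


def low_nitrogen_recipe() -> NutrientRecipe:
    """The low-nitrogen feed: 0.4 mM calcium nitrate (CaCl2 balancing Ca)."""
    comps = _base_components(canitrate_mm=0.4)
    comps.append(NutrientComponent("CaCl2 (balance)", 3.6, 0))
    return NutrientRecipe(components=comps)


def _base_components(canitrate_mm: float) -> list[NutrientComponent]:
    return [
        NutrientComponent("Ca(NO3)2.4H2O", canitrate_mm, 2),
        NutrientComponent("KH2PO4", 0.25, 0),
        NutrientComponent("KOH", 0.5, 0),
        NutrientComponent("MgSO4.7H2O", 0.75, 0),
        NutrientComponent("CaCl2", 0.03, 0),
        NutrientComponent("FeNaEDTA", 0.1, 2, chelator=True),
        NutrientComponent("H3BO3", 0.03, 0),
        NutrientComponent("MnSO4.4H2O", 0.01, 0),
        NutrientComponent("ZnCl2.7H2O", 0.001, 0),
        NutrientComponent("CuSO4.5H2O", 0.003, 0),
        NutrientComponent("Na2MoO2.2H2O", 0.0005, 0),
    ]
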