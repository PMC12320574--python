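"""Physical constants and unit conversions used throughout the package.

All geometry is in micrometers, activities in Bq (or kBq/mL for
concentrations), doses in Gy, and molar activities in GBq/mol unless a
function says otherwise.  Cells and medium are unit-density water.
"""

from __future__ import annotations

import numpy as np

#: Physical half-life of Ac-225 in days.
AC225_HALF_LIFE_DAYS: float = 9.92

#: Joules per MeV.
MEV_TO_J: float = 1.602176634e-13

#: Density of water in kg per um^3 (1 g/cm^3).
WATER_DENSITY_KG_PER_UM3: float = 1.0e-15

SECONDS_PER_HOUR: float = 3600.0
SECONDS_PER_DAY: float = 86400.0


def decay_constant_per_s(half_life_days: float) -> float:
    """Radioactive decay constant lambda = ln2 / T_half in 1/s."""
    if half_life_days <= 0:
        raise ValueError("half-life must be positive")
    return np.log(2.0) / (half_life_days * SECONDS_PER_DAY)


def sphere_mass_kg(radius_um: float) -> float:
    """Mass of a unit-density water sphere of the given radius."""
    return WATER_DENSITY_KG_PER_UM3 * (4.0 / 3.0) * np.pi * radius_um**3


def molar_activity_from_specific(specific_activity_mbq_per_mg: float,
                                 molar_mass_kda: float) -> float:
    """Convert specific activity (MBq/mg) to molar activity (GBq/mol).

    For example a 150-kDa IgG labeled at 3.4 MBq/mg carries
    3.4e9 Bq/g * 1.5e5 g/mol = 5.1e14 Bq/mol = 5.1e5 GBq/mol.
    """
    if specific_activity_mbq_per_mg < 0 or molar_mass_kda <= 0:
        raise ValueError("specific activity must be >= 0 and molar mass > 0")
    bq_per_g = specific_activity_mbq_per_mg * 1e6 / 1e-3
    bq_per_mol = bq_per_g * molar_mass_kda * 1e3
    return bq_per_mol / 1e9


def activity_concentration_kbq_per_ml(molar_activity_gbq_per_mol: float,
                                      carrier_mol_per_ml: float) -> float:
    """Activity concentration produced by a carrier at a given molar activity."""
    return molar_activity_gbq_per_mol * carrier_mol_per_ml * 1e6


def percent_excess(larger: float, smaller: float) -> float:
    """Percent by which `larger` exceeds `smaller`: 100 * (larger/smaller - 1)."""
    if smaller == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (larger / smaller - 1.0)
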