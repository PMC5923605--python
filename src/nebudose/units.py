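"""Central unit conversions.

The package mixes the units its inputs naturally come in: particle diameters
in nm, image areas in nm²/µm², insert areas in cm², suspension concentrations
in µg/mL, applied volumes in µL, and doses in µg/cm².  Every conversion lives
here so the rest of the code can stay in its natural unit and no factor of
10^x is ever typed twice.

Internal canon: lengths nm, pixel/field areas nm² (µm² at reporting level),
masses µg, doses µg/cm².
"""

import math

NM_PER_UM = 1.0e3
NM_PER_CM = 1.0e7
NM2_PER_UM2 = 1.0e6
UM2_PER_CM2 = 1.0e8
NM2_PER_CM2 = 1.0e14
NM3_PER_CM3 = 1.0e21
UG_PER_G = 1.0e6
ML_PER_UL = 1.0e-3


def nm2_to_um2(area_nm2: float) -> float:
    return area_nm2 / NM2_PER_UM2


def um2_to_cm2(area_um2: float) -> float:
    return area_um2 / UM2_PER_CM2


def nm_to_cm(length_nm: float) -> float:
    return length_nm / NM_PER_CM


def density_to_ug_nm3(density_g_cm3: float) -> float:
    """g/cm³ → µg/nm³."""
    return density_g_cm3 * UG_PER_G / NM3_PER_CM3


def sphere_volume_nm3(diameter_nm: float) -> float:
    """Volume of a sphere of the given diameter, nm³."""
    return math.pi * diameter_nm**3 / 6.0


def disk_area_nm2(diameter_nm: float) -> float:
    """Projected (equatorial-disk) area of a sphere, π d²/4, nm²."""
    return math.pi * diameter_nm**2 / 4.0


def particle_mass_ug(diameter_nm: float, density_g_cm3: float) -> float:
    """Mass of one spherical particle, µg = ρ π d³ / 6."""
    return density_to_ug_nm3(density_g_cm3) * sphere_volume_nm3(diameter_nm)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures (display only; never used internally).

    round_sig(0.02727, 2) == 0.027; round_sig(0.6818, 2) == 0.68.
    """
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
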