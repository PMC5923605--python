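"""Closed-form dose arithmetic for nebulized nanoparticle exposure.

Three quantities tie an air–liquid-interface exposure together:

* the **nominal areal dose** — the µg/cm² the insert would receive if the
  entire applied suspension volume deposited uniformly on its growth area,
* the **delivered (measured) areal dose** — the µg/cm² inferred from the
  particle-occupied area of a micrograph under a sphere/monolayer model,
* the **deposition efficiency** — delivered dose as a percent of nominal.

The sphere/monolayer model assumes every segmented pixel belongs to a single
layer of primary particles of known diameter d and bulk density ρ: the
particle count is the occupied area divided by the projected equatorial-disk
area π d²/4, and the mass is that count times the sphere mass ρ π d³/6.
Equivalently, dose = coverage_fraction × (2/3) ρ d.  Vertically stacked
aggregates add mass without adding projected area, so the model undercounts
them by construction; the simulator's stacking mode quantifies that bias.

All computations run at full precision; printed-style rounding (2 s.f. for
doses, integer percent for efficiencies) lives in :mod:`nebudose.report`.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import units

__all__ = [
    "ParticleSpec",
    "ExposureSpec",
    "DoseEstimate",
    "nominal_dose",
    "area_to_dose",
    "deposition_efficiency",
]


def _require_positive(value: float, field: str) -> None:
    if not value > 0:
        raise ValueError(f"{field} must be > 0, got {value!r}")


@dataclass(frozen=True)
class ParticleSpec:
    """A primary-particle description: name, diameter (nm), bulk density (g/cm³).

    Particles are modelled as solid spheres; the projected area of one
    particle is the equatorial disk π d²/4 and its mass is ρ π d³/6.
    """

    name: str
    primary_diameter_nm: float
    density_g_cm3: float

    def __post_init__(self) -> None:
        _require_positive(self.primary_diameter_nm, "primary_diameter_nm")
        _require_positive(self.density_g_cm3, "density_g_cm3")

    @property
    def projected_area_nm2(self) -> float:
        return units.disk_area_nm2(self.primary_diameter_nm)

    @property
    def mass_ug(self) -> float:
        return units.particle_mass_ug(self.primary_diameter_nm, self.density_g_cm3)


@dataclass(frozen=True)
class ExposureSpec:
    """One nebulization/inoculation condition.

    Defaults mirror the standard hanging-insert setup: 30 µL applied to a
    1.1 cm² growth area; concentration is the suspension concentration in
    µg/mL.
    """

    concentration_ug_ml: float
    volume_ul: float = 30.0
    insert_area_cm2: float = 1.1

    def __post_init__(self) -> None:
        _require_positive(self.concentration_ug_ml, "concentration_ug_ml")
        _require_positive(self.volume_ul, "volume_ul")
        _require_positive(self.insert_area_cm2, "insert_area_cm2")


@dataclass(frozen=True)
class DoseEstimate:
    """Measured vs nominal areal dose for one condition (both µg/cm²)."""

    measured_dose_ug_cm2: float
    nominal_dose_ug_cm2: float

    def __post_init__(self) -> None:
        if self.measured_dose_ug_cm2 < 0:
            raise ValueError(
                f"measured_dose_ug_cm2 must be >= 0, got {self.measured_dose_ug_cm2!r}"
            )
        _require_positive(self.nominal_dose_ug_cm2, "nominal_dose_ug_cm2")

    @property
    def efficiency_percent(self) -> float:
        """Deposition efficiency: 100 × measured / nominal."""
        return deposition_efficiency(self.measured_dose_ug_cm2, self.nominal_dose_ug_cm2)


def nominal_dose(exposure: ExposureSpec) -> float:
    """Nominal areal dose, µg/cm² = concentration × volume / insert area.

    The µL→mL factor is applied internally; the result is full precision
    (e.g. 1 µg/mL × 30 µL / 1.1 cm² = 0.02727… µg/cm², printed as 0.027).
    """
    return (
        exposure.concentration_ug_ml
        * exposure.volume_ul
        * units.ML_PER_UL
        / exposure.insert_area_cm2
    )


def area_to_dose(
    total_np_area_um2: float,
    particle: ParticleSpec,
    field_area_um2: float,
) -> float:
    """Convert particle-occupied image area to areal dose, µg/cm².

    Two-step sphere/monolayer computation: particle count
    N = occupied area / (π d²/4), mass = N × ρ π d³/6, dose = mass / field
    area.  Algebraically this is coverage_fraction × (2/3) ρ d.
    """
    _require_positive(field_area_um2, "field_area_um2")
    if total_np_area_um2 < 0:
        raise ValueError(f"total_np_area_um2 must be >= 0, got {total_np_area_um2!r}")
    if total_np_area_um2 > field_area_um2:
        raise ValueError(
            f"total_np_area_um2 ({total_np_area_um2!r}) exceeds "
            f"field_area_um2 ({field_area_um2!r})"
        )
    total_np_area_nm2 = total_np_area_um2 * units.NM2_PER_UM2
    n_particles = total_np_area_nm2 / particle.projected_area_nm2
    mass_ug = n_particles * particle.mass_ug
    return mass_ug / units.um2_to_cm2(field_area_um2)


def deposition_efficiency(measured_ug_cm2: float, nominal_ug_cm2: float) -> float:
    """Deposition efficiency in percent: 100 × measured / nominal dose."""
    _require_positive(nominal_ug_cm2, "nominal_ug_cm2")
    if measured_ug_cm2 < 0:
        raise ValueError(f"measured_ug_cm2 must be >= 0, got {measured_ug_cm2!r}")
    return 100.0 * measured_ug_cm2 / nominal_ug_cm2
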