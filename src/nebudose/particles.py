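"""Reference particle table.

Ships the two JRC benchmark anatase TiO₂ materials used throughout the
examples: NM-100 (primary diameter 100 nm) and NM-101 (6.5 nm), both with
bulk density 3.84 g/cm³.  The table is a plain CSV so users can extend it
with their own materials.
"""

from __future__ import annotations

import csv
from importlib import resources

from .dosimetry import ParticleSpec

__all__ = ["load_particle_table", "get_particle"]


def load_particle_table() -> dict[str, ParticleSpec]:
    """Load the bundled particle table as {name: ParticleSpec}."""
    table: dict[str, ParticleSpec] = {}
    path = resources.files("nebudose.data").joinpath("particles.csv")
    with path.open(newline="") as handle:
        for row in csv.DictReader(handle):
            spec = ParticleSpec(
                name=row["name"],
                primary_diameter_nm=float(row["primary_diameter_nm"]),
                density_g_cm3=float(row["density_g_cm3"]),
            )
            table[spec.name] = spec
    return table


def get_particle(name: str) -> ParticleSpec:
    """Look up a bundled particle by name (e.g. ``"NM-100"``)."""
    table = load_particle_table()
    try:
        return table[name]
    except KeyError:
        known = ", ".join(sorted(table))
        raise KeyError(f"unknown particle {name!r}; bundled particles: {known}") from None
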