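"""Report-layer formatting: printed-style rounding and dose tables.

All computation upstream runs at full precision; this module owns the
display conventions — doses to 2 significant figures, efficiencies to
integer percent — and renders the sample × concentration × nominal ×
measured × efficiency text table.

Note that integer-rounded efficiencies are generally *not* recoverable from
the 2 s.f. dose columns of the same table (e.g. 0.02/0.027 rounds to 74%,
while the full-precision pair behind it may round to 92%); efficiency is
always computed from full-precision doses before rounding.
"""

from __future__ import annotations

import pandas as pd

from .units import round_sig

__all__ = ["format_dose", "format_efficiency", "render_dose_table"]


def format_dose(dose_ug_cm2: float) -> float:
    """Dose for display: 2 significant figures."""
    return round_sig(dose_ug_cm2, 2)


def format_efficiency(efficiency_percent: float) -> int:
    """Efficiency for display: integer percent."""
    return int(round(efficiency_percent))


def render_dose_table(rows: pd.DataFrame) -> str:
    """Render a deposition report table from per-condition rows.

    Expects columns: sample, concentration_ug_ml, nominal_dose_ug_cm2,
    measured_dose_ug_cm2, efficiency_pct (full precision); applies display
    rounding here only.
    """
    display = pd.DataFrame(
        {
            "Sample": rows["sample"],
            "Concentration (µg/mL)": rows["concentration_ug_ml"],
            "Nominal Dose (µg/cm²)": rows["nominal_dose_ug_cm2"].map(
                lambda x: f"{format_dose(x):g}"
            ),
            "Measured Dose (µg/cm²)": rows["measured_dose_ug_cm2"].map(
                lambda x: f"{format_dose(x):g}"
            ),
            "Efficiency (%)": rows["efficiency_pct"].map(format_efficiency),
        }
    )
    return display.to_string(index=False)
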