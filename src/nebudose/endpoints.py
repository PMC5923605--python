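"""Bioassay endpoint formulas: tracer passage and viability normalization.

Two scalar endpoints accompany the dosimetry:

* **Paracellular tracer passage** across an epithelial monolayer on a
  permeable insert (e.g. Lucifer Yellow), expressed as the percent of
  apical tracer mass recovered basolaterally:

      passage % = 100 × (C_Bl × V_Bl) / (C0 × V_Ap)

  with C_Bl the basolateral concentration after incubation, C0 the initial
  apical (donor) concentration, and V_Bl/V_Ap the chamber volumes.  The
  ratio is dimensionless as long as the two concentrations and the two
  volumes each share a unit.  Values above 100% violate mass balance and
  are returned as computed but flagged with a warning.

* **Viability percent of untreated control** from plate-reader signals
  (e.g. resazurin fluorescence), with explicit blank subtraction:

      viability % = 100 × (sample − blank) / (control − blank)

  The blank defaults to 0, so the bare sample/control ratio is the special
  case blank = 0.  Negative results (sample below blank) clamp to 0 with a
  warning.

CSV batch helpers append endpoint columns to a table of per-insert rows and
summarize group means ± sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PermeabilityMeasurement",
    "ViabilityMeasurement",
    "ly_passage_percent",
    "viability_percent",
    "append_endpoint_columns",
    "group_summary",
]


@dataclass(frozen=True)
class PermeabilityMeasurement:
    """One insert's tracer-passage measurement.

    Concentrations in any shared unit; volumes in mL (any shared unit works
    since only the ratio enters).
    """

    c_basolateral: float
    c0: float
    basolateral_volume_ml: float = 1.5
    apical_volume_ml: float = 0.5

    def __post_init__(self) -> None:
        if self.c_basolateral < 0:
            raise ValueError(f"c_basolateral must be >= 0, got {self.c_basolateral!r}")
        if not self.c0 > 0:
            raise ValueError(f"c0 must be > 0, got {self.c0!r}")
        if not self.basolateral_volume_ml > 0:
            raise ValueError("basolateral_volume_ml must be > 0")
        if not self.apical_volume_ml > 0:
            raise ValueError("apical_volume_ml must be > 0")


@dataclass(frozen=True)
class ViabilityMeasurement:
    """One insert's viability signals (sample, untreated control, blank)."""

    sample_signal: float
    control_signal: float
    blank_signal: float = 0.0

    def __post_init__(self) -> None:
        if not self.control_signal > self.blank_signal:
            raise ValueError(
                f"control_signal ({self.control_signal!r}) must exceed "
                f"blank_signal ({self.blank_signal!r})"
            )


def ly_passage_percent(m: PermeabilityMeasurement) -> float:
    """Percent of apical tracer mass recovered basolaterally.

    100 × (C_Bl × V_Bl) / (C0 × V_Ap); > 100% is flagged as a mass-balance
    violation but returned as computed.
    """
    passage = (
        100.0
        * (m.c_basolateral * m.basolateral_volume_ml)
        / (m.c0 * m.apical_volume_ml)
    )
    if passage > 100.0:
        warnings.warn(
            f"passage {passage:.3g}% exceeds 100%: basolateral tracer mass exceeds "
            "the apical donor mass (mass-balance violation; check inputs)",
            stacklevel=2,
        )
    return passage


def viability_percent(m: ViabilityMeasurement) -> float:
    """Viability as percent of untreated control, blank-subtracted.

    100 × (sample − blank) / (control − blank); negative values clamp to 0
    with a warning.
    """
    value = 100.0 * (m.sample_signal - m.blank_signal) / (m.control_signal - m.blank_signal)
    if value < 0:
        warnings.warn(
            f"viability {value:.3g}% < 0 (sample below blank); clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return value


def append_endpoint_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append computed endpoint columns to a per-insert table.

    Recognized inputs (any subset): viability needs ``sample_signal``,
    ``control_signal`` and optionally ``blank_signal``; passage needs
    ``c_basolateral``, ``c0``, ``basolateral_volume_ml``,
    ``apical_volume_ml``.  Returns a copy with ``viability_pct`` and/or
    ``ly_passage_pct`` columns.
    """
    out = table.copy()
    if {"sample_signal", "control_signal"}.issubset(out.columns):
        blanks = out["blank_signal"] if "blank_signal" in out.columns else 0.0
        out["viability_pct"] = [
            viability_percent(
                ViabilityMeasurement(
                    sample_signal=row.sample_signal,
                    control_signal=row.control_signal,
                    blank_signal=blank,
                )
            )
            for row, blank in zip(
                out.itertuples(), blanks if hasattr(blanks, "__iter__") else [blanks] * len(out)
            )
        ]
    if {"c_basolateral", "c0"}.issubset(out.columns):
        out["ly_passage_pct"] = [
            ly_passage_percent(
                PermeabilityMeasurement(
                    c_basolateral=row["c_basolateral"],
                    c0=row["c0"],
                    basolateral_volume_ml=row.get("basolateral_volume_ml", 1.5),
                    apical_volume_ml=row.get("apical_volume_ml", 0.5),
                )
            )
            for _, row in out.iterrows()
        ]
    return out


def group_summary(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Mean ± sd of endpoint columns per group."""
    endpoint_cols = [c for c in ("viability_pct", "ly_passage_pct") if c in table.columns]
    if not endpoint_cols:
        raise ValueError("no endpoint columns found; run append_endpoint_columns first")
    return table.groupby(group_col)[endpoint_cols].agg(["mean", "std"])
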