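"""Acetylene-reduction (nitrogenase) rates and elemental C:N ratios.

The acetylene reduction assay proxies nitrogenase activity: ethylene
produced over an incubation is divided by dry mass and by the *active*
hours.  Unicellular diazotrophic cyanobacteria separate oxygen-sensitive
nitrogen fixation from daytime photosynthesis, so activity is conventionally
attributed to the dark hours of the photoperiod only; the counting
convention is explicit here via ``active_phase``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .units import MOLAR_MASS_C, MOLAR_MASS_N

__all__ = [
    "ActivePhase",
    "IncubationRecord",
    "ElementalComposition",
    "acetylene_reduction_rate",
    "cn_molar_ratio",
    "acetylene_rates_from_csv",
    "cn_ratios_from_csv",
]


class ActivePhase(str, Enum):
    DARK_ONLY = "dark_only"
    LIGHT_ONLY = "light_only"
    CONTINUOUS = "continuous"


@dataclass(frozen=True)
class IncubationRecord:
    """One assay bottle: total ethylene produced over an incubation span on
    a fixed light:dark photoperiod.

    The span is assumed to start at light onset; dark hours in a partial
    final cycle accrue only after the light phase of that cycle has elapsed.
    """

    ethylene_nmol: float
    span_h: float
    light_h: float
    dark_h: float
    dry_mass_mg: float
    active_phase: ActivePhase = ActivePhase.DARK_ONLY

    def __post_init__(self) -> None:
        if self.ethylene_nmol < 0:
            raise ValueError("ethylene_nmol must be >= 0")
        if self.span_h <= 0:
            raise ValueError("span_h must be positive")
        if self.dry_mass_mg <= 0:
            raise ValueError("dry_mass_mg must be positive")
        if self.light_h < 0 or self.dark_h < 0 or abs(self.light_h + self.dark_h - 24.0) > 1e-9:
            raise ValueError("light_h + dark_h must equal 24")

    def active_hours(self) -> float:
        """Hours of the span during which fixation is assumed active."""
        phase = ActivePhase(self.active_phase)
        if phase is ActivePhase.CONTINUOUS:
            return self.span_h
        full_cycles, remainder = divmod(self.span_h, 24.0)
        if phase is ActivePhase.DARK_ONLY:
            return full_cycles * self.dark_h + max(0.0, remainder - self.light_h)
        return full_cycles * self.light_h + min(remainder, self.light_h)


def acetylene_reduction_rate(record: IncubationRecord) -> float:
    """Mass-specific acetylene reduction rate, nmol C2H4 mg^-1 h^-1."""
    active = record.active_hours()
    if active <= 0:
        raise ValueError(
            f"no active hours in a {record.span_h} h span for phase "
            f"{ActivePhase(record.active_phase).value}"
        )
    return record.ethylene_nmol / (record.dry_mass_mg * active)


@dataclass(frozen=True)
class ElementalComposition:
    """Carbon and nitrogen masses of a sample (any common mass unit)."""

    carbon_ug: float
    nitrogen_ug: float

    def __post_init__(self) -> None:
        if self.carbon_ug < 0 or self.nitrogen_ug < 0:
            raise ValueError("elemental masses must be >= 0")


def cn_molar_ratio(comp: ElementalComposition) -> float:
    """Molar C:N ratio: (C/12.011) / (N/14.007)."""
    if comp.nitrogen_ug == 0:
        raise ValueError("nitrogen mass must be positive")
    return (comp.carbon_ug / MOLAR_MASS_C) / (comp.nitrogen_ug / MOLAR_MASS_N)


def acetylene_rates_from_csv(path, active_phase: ActivePhase = ActivePhase.DARK_ONLY) -> pd.DataFrame:
    """Per-bottle rates from a CSV with columns bottle_id, ethylene_nmol,
    span_h, dark_h_per_day, dry_mass_mg."""
    df = pd.read_csv(path)
    required = {"bottle_id", "ethylene_nmol", "span_h", "dark_h_per_day", "dry_mass_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"acetylene CSV missing columns: {sorted(missing)}")
    rates = []
    for _, row in df.iterrows():
        rec = IncubationRecord(
            ethylene_nmol=row["ethylene_nmol"],
            span_h=row["span_h"],
            light_h=24.0 - row["dark_h_per_day"],
            dark_h=row["dark_h_per_day"],
            dry_mass_mg=row["dry_mass_mg"],
            active_phase=active_phase,
        )
        rates.append(acetylene_reduction_rate(rec))
    out = df.copy()
    out["rate_nmol_mg_h"] = rates
    return out


def cn_ratios_from_csv(path) -> pd.DataFrame:
    """Per-sample molar C:N from a CSV with columns sample_id, carbon_ug,
    nitrogen_ug."""
    df = pd.read_csv(path)
    required = {"sample_id", "carbon_ug", "nitrogen_ug"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"C:N CSV missing columns: {sorted(missing)}")
    out = df.copy()
    out["cn_molar"] = [
        cn_molar_ratio(ElementalComposition(c, n))
        for c, n in zip(df["carbon_ug"], df["nitrogen_ug"])
    ]
    return out
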