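"""Aggregate size metrics from measured dimensions.

Field aggregates are irregular ellipsoids; their size is summarized by the
equivalent spherical diameter (ESD), the diameter of the sphere with the same
volume.  Volume and surface area are derived from the ESD, but the working
volume may be set independently because measured budgets sometimes refer to a
directly determined volume rather than the ESD-implied one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "AggregateGeometry",
    "esd_from_axes",
    "sphere_volume",
    "sphere_surface_area",
    "esd_for_volume",
    "read_axes_csv",
]


def esd_from_axes(a_mm: float, b_mm: float, c_mm: float) -> float:
    """ESD of an ellipsoid from its three principal diameters (mm).

    The diameter of the sphere with the ellipsoid's volume: the geometric
    mean (a*b*c)**(1/3).
    """
    for name, v in (("a_mm", a_mm), ("b_mm", b_mm), ("c_mm", c_mm)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    return (a_mm * b_mm * c_mm) ** (1.0 / 3.0)


def sphere_volume(esd_mm: float) -> float:
    """Volume (mm^3) of a sphere of diameter esd_mm."""
    if esd_mm <= 0:
        raise ValueError(f"esd_mm must be positive, got {esd_mm!r}")
    return math.pi / 6.0 * esd_mm**3


def sphere_surface_area(esd_mm: float) -> float:
    """Surface area (mm^2) of a sphere of diameter esd_mm."""
    if esd_mm <= 0:
        raise ValueError(f"esd_mm must be positive, got {esd_mm!r}")
    return math.pi * esd_mm**2


def esd_for_volume(volume_mm3: float) -> float:
    """Inverse of :func:`sphere_volume`: the ESD (mm) of a given volume."""
    if volume_mm3 <= 0:
        raise ValueError(f"volume_mm3 must be positive, got {volume_mm3!r}")
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class AggregateGeometry:
    """Size metrics of a single aggregate.

    ``volume_mm3`` defaults to the sphere volume implied by the ESD but can
    be overridden with an independently measured volume; surface area and
    radius always follow the ESD.
    """

    esd_mm: float
    volume_mm3: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.esd_mm <= 0:
            raise ValueError(f"esd_mm must be positive, got {self.esd_mm!r}")
        if self.volume_mm3 is None:
            object.__setattr__(self, "volume_mm3", sphere_volume(self.esd_mm))
        elif self.volume_mm3 <= 0:
            raise ValueError(f"volume_mm3 must be positive, got {self.volume_mm3!r}")

    @classmethod
    def from_axes(cls, a_mm: float, b_mm: float, c_mm: float) -> "AggregateGeometry":
        return cls(esd_mm=esd_from_axes(a_mm, b_mm, c_mm))

    @property
    def radius_cm(self) -> float:
        return self.esd_mm / 2.0 * 0.1

    @property
    def surface_area_mm2(self) -> float:
        return sphere_surface_area(self.esd_mm)

    @property
    def sphere_volume_mm3(self) -> float:
        """Volume implied by the ESD (ignores any override)."""
        return sphere_volume(self.esd_mm)

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 * 1e-3


def read_axes_csv(path) -> pd.DataFrame:
    """Read measured aggregate axes (columns aggregate_id, a_mm, b_mm, c_mm)
    and append esd_mm and volume_mm3 columns."""
    df = pd.read_csv(path)
    required = {"aggregate_id", "a_mm", "b_mm", "c_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"axes CSV missing columns: {sorted(missing)}")
    df = df.copy()
    df["esd_mm"] = [
        esd_from_axes(a, b, c) for a, b, c in zip(df["a_mm"], df["b_mm"], df["c_mm"])
    ]
    df["volume_mm3"] = [sphere_volume(e) for e in df["esd_mm"]]
    return df
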