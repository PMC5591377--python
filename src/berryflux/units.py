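"""Physical constants, unit conversions and environment-dependent coefficients.

All public functions take and return values in the field's customary units:
temperature in degrees Celsius, salinity on the practical salinity scale,
diffusion coefficients in cm^2 s^-1, dissolved O2 in umol L^-1, per-aggregate
rates in nmol h^-1 and volumetric rates in umol cm^-3 h^-1 (numerically equal
to nmol mm^-3 h^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MOLAR_MASS_C",
    "MOLAR_MASS_N",
    "MediumProperties",
    "ModelParams",
    "diffusion_coefficient",
    "air_saturation",
    "per_aggregate_to_volumetric",
    "volumetric_to_per_aggregate",
]

MOLAR_MASS_C = 12.011  # g mol^-1
MOLAR_MASS_N = 14.007  # g mol^-1

#: molar volume of O2 at STP, L mol^-1 (used to convert mL/L solubility to umol/L)
_O2_MOLAR_VOLUME_L = 22.3916

# O2 diffusion coefficient anchors for ~3.5% saline water (cm^2 s^-1)
_D_T1, _D_V1 = 24.0, 2.175e-5
_D_T2, _D_V2 = 27.0, 2.3535e-5

_TEMP_RANGE = (0.0, 40.0)
_SAL_RANGE = (0.0, 40.0)


def _check_range(value: float, lo: float, hi: float, name: str) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name} must be within [{lo}, {hi}], got {value!r}")


def diffusion_coefficient(temperature_c: float) -> float:
    """O2 diffusion coefficient in saline water, cm^2 s^-1.

    Linear in temperature through the two calibration anchors
    (2.175e-5 at 24 C, 2.3535e-5 at 27 C); extrapolated linearly
    elsewhere within [0, 40] C.
    """
    _check_range(temperature_c, *_TEMP_RANGE, name="temperature_c")
    slope = (_D_V2 - _D_V1) / (_D_T2 - _D_T1)
    return _D_V1 + slope * (temperature_c - _D_T1)


def air_saturation(temperature_c: float, salinity: float) -> float:
    """Air-saturation O2 concentration of seawater, umol L^-1.

    Garcia & Gordon (1992) solubility fit to the Benson & Krause data,
    volumetric (mL L^-1) coefficient set, converted to umol L^-1 with the
    O2 molar volume at STP.  Valid for T in [0, 40] C, S in [0, 40].
    """
    _check_range(temperature_c, *_TEMP_RANGE, name="temperature_c")
    _check_range(salinity, *_SAL_RANGE, name="salinity")
    a = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
    b = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
    c0 = -4.88682e-7
    ts = math.log((298.15 - temperature_c) / (273.15 + temperature_c))
    ln_c = sum(ai * ts**i for i, ai in enumerate(a))
    ln_c += salinity * sum(bi * ts**i for i, bi in enumerate(b))
    ln_c += c0 * salinity**2
    ml_per_l = math.exp(ln_c)
    return ml_per_l * 1000.0 / _O2_MOLAR_VOLUME_L


def per_aggregate_to_volumetric(rate_nmol_h: float, volume_mm3: float) -> float:
    """Convert a per-aggregate rate (nmol h^-1) to volumetric (umol cm^-3 h^-1).

    1 nmol mm^-3 h^-1 equals 1 umol cm^-3 h^-1, so this is a plain division.
    """
    if volume_mm3 <= 0:
        raise ValueError(f"volume_mm3 must be positive, got {volume_mm3!r}")
    return rate_nmol_h / volume_mm3


def volumetric_to_per_aggregate(rate_umol_cm3_h: float, volume_mm3: float) -> float:
    """Inverse of :func:`per_aggregate_to_volumetric`."""
    if volume_mm3 <= 0:
        raise ValueError(f"volume_mm3 must be positive, got {volume_mm3!r}")
    return rate_umol_cm3_h * volume_mm3


@dataclass(frozen=True)
class MediumProperties:
    """Bathing-water properties relevant to O2 transport.

    Attributes
    ----------
    temperature_c : water temperature, C
    salinity : practical salinity
    d_w : O2 diffusion coefficient in the water, cm^2 s^-1
    c_sat : air-saturation (ambient/bulk) O2 concentration, umol L^-1
    """

    temperature_c: float
    salinity: float
    d_w: float
    c_sat: float

    def __post_init__(self) -> None:
        _check_range(self.temperature_c, *_TEMP_RANGE, name="temperature_c")
        _check_range(self.salinity, *_SAL_RANGE, name="salinity")
        if self.d_w <= 0:
            raise ValueError(f"d_w must be positive, got {self.d_w!r}")
        if self.c_sat <= 0:
            raise ValueError(f"c_sat must be positive, got {self.c_sat!r}")

    @classmethod
    def for_conditions(
        cls,
        temperature_c: float,
        salinity: float,
        d_w: float | None = None,
        c_sat: float | None = None,
    ) -> "MediumProperties":
        """Build properties for given conditions, deriving D_w and C_sat
        from the built-in parameterizations unless overridden."""
        if d_w is None:
            d_w = diffusion_coefficient(temperature_c)
        if c_sat is None:
            c_sat = air_saturation(temperature_c, salinity)
        return cls(temperature_c=temperature_c, salinity=salinity, d_w=d_w, c_sat=c_sat)

    @property
    def d_w_cm2_h(self) -> float:
        """D_w converted to cm^2 h^-1 (used with hourly rates)."""
        return self.d_w * 3600.0

    @property
    def c_sat_umol_cm3(self) -> float:
        """C_sat converted to umol cm^-3."""
        return self.c_sat * 1e-3


@dataclass(frozen=True)
class ModelParams:
    """Tunable parameters of the aggregate O2 model.

    theta
        Ratio of apparent O2 diffusivity inside the aggregate to that in
        free water (gel-like matrix; default 0.95).
    pq
        Photosynthetic quotient, mol O2 released per mol C fixed
        (default 1.2).
    dbl_um
        Diffusive boundary-layer thickness in um; ``math.inf`` selects the
        stagnant infinite-medium external solution (the default).
    anoxia_umol_l
        O2 concentration below which the core is called anoxic
        (default 1 umol L^-1).
    """

    theta: float = 0.95
    pq: float = 1.2
    dbl_um: float = math.inf
    anoxia_umol_l: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.theta <= 1):
            raise ValueError(f"theta must be in (0, 1], got {self.theta!r}")
        if self.pq <= 0:
            raise ValueError(f"pq must be positive, got {self.pq!r}")
        if self.dbl_um <= 0:
            raise ValueError(f"dbl_um must be positive (may be inf), got {self.dbl_um!r}")
        if self.anoxia_umol_l < 0:
            raise ValueError(f"anoxia_umol_l must be >= 0, got {self.anoxia_umol_l!r}")
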