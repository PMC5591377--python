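"""Estimators turning microsensor recordings into whole-aggregate rates.

Depth microprofiles through an aggregate give the O2 field along the
vertical through its center; the external part of the profile carries the
diffusive flux between aggregate and water.  Two flux estimators are
provided:

``radial`` (default)
    The external steady field around a sphere is C(r) = C_inf + k/r.  Depths
    above the aggregate surface are mapped to radial distance
    r = R + (surface_depth - depth) and (C_inf, k) are fit by least squares;
    the total exchange is 4 pi D_w k.  Positive k means efflux (net
    production), negative means uptake (respiration).

``planar``
    Fick's first law across the diffusive boundary layer: a straight-line
    fit of C against height above the surface over a configurable window
    gives the areal flux J = -D_w dC/dz, scaled by the sphere surface
    pi ESD^2.

Gross photosynthesis comes either from profiles (net + dark respiration) or
from the light-dark shift technique: at steady state in the light, local
gross production is balanced by respiration plus diffusion; in the first
seconds after darkening both are unchanged, so the initial rate of O2
decline at the sensor equals the local gross photosynthesis.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import AggregateGeometry
from .transient import TransientTrace
from .units import (
    MOLAR_MASS_C,
    MediumProperties,
    ModelParams,
    per_aggregate_to_volumetric,
)

__all__ = [
    "RadialProfile",
    "RateTable",
    "ProfileFormatError",
    "read_profile",
    "write_profile",
    "read_trace",
    "write_trace",
    "whole_aggregate_flux",
    "gross_photosynthesis",
    "light_dark_shift_rate",
    "carbon_fixation",
    "resp_to_gross_ratio",
    "build_rate_table",
]


class ProfileFormatError(ValueError):
    """Malformed profile/trace file."""


@dataclass(frozen=True)
class RadialProfile:
    """A depth microprofile: O2 (umol L^-1) vs depth (um, positive downward
    from the water surface), with acquisition metadata."""

    depth_um: np.ndarray
    o2_umol_l: np.ndarray
    surface_depth_um: float
    light_ue: float | None = None
    temperature_c: float | None = None
    salinity: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_um, dtype=float)
        c = np.asarray(self.o2_umol_l, dtype=float)
        if d.shape != c.shape or d.ndim != 1:
            raise ValueError("depth_um and o2_umol_l must be 1-D arrays of equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depth_um must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("o2_umol_l must be non-negative")
        if not (d[0] <= self.surface_depth_um <= d[-1]):
            raise ValueError("surface_depth_um must lie within the depth range")
        object.__setattr__(self, "depth_um", d)
        object.__setattr__(self, "o2_umol_l", c)


_HEADER_KEYS = {
    "surface_depth_um": "surface_depth_um",
    "light_uE": "light_ue",
    "temperature_c": "temperature_c",
    "salinity": "salinity",
}


def _parse_headers(lines: list[str]) -> tuple[dict, int]:
    meta: dict = {}
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if not s.startswith("#"):
            break
        body = s.lstrip("#").strip()
        if "=" not in body:
            raise ProfileFormatError(f"line {i + 1}: malformed header {s!r}")
        key, _, val = body.partition("=")
        key = key.strip()
        if key in _HEADER_KEYS:
            try:
                meta[_HEADER_KEYS[key]] = float(val)
            except ValueError as exc:
                raise ProfileFormatError(f"line {i + 1}: non-numeric header value {val!r}") from exc
        else:
            meta.setdefault("_extra", {})[key] = val.strip()
    return meta, i


def _parse_numeric_rows(lines: list[str], start: int, n_cols: int, colnames: list[str]) -> np.ndarray:
    header = [c.strip() for c in lines[start].strip().split(",")]
    if header != colnames:
        raise ProfileFormatError(
            f"line {start + 1}: expected columns {colnames}, got {header}"
        )
    rows = []
    for j, line in enumerate(lines[start + 1 :], start=start + 2):
        s = line.strip()
        if not s:
            continue
        cells = s.split(",")
        if len(cells) != n_cols:
            raise ProfileFormatError(f"line {j}: expected {n_cols} cells, got {len(cells)}")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ProfileFormatError(f"line {j}: non-numeric cell in {s!r}") from exc
    if not rows:
        raise ProfileFormatError("no data rows")
    return np.asarray(rows)


def read_profile(path) -> RadialProfile:
    """Read a depth-profile CSV.

    Format: comment headers ``# surface_depth_um=``, ``# light_uE=``,
    ``# temperature_c=``, ``# salinity=`` followed by a
    ``depth_um,o2_umol_l`` table.  Malformed rows are rejected with their
    line number.
    """
    lines = Path(path).read_text().splitlines()
    meta, start = _parse_headers(lines)
    meta.pop("_extra", None)
    if "surface_depth_um" not in meta:
        raise ProfileFormatError("missing required header '# surface_depth_um='")
    data = _parse_numeric_rows(lines, start, 2, ["depth_um", "o2_umol_l"])
    try:
        return RadialProfile(depth_um=data[:, 0], o2_umol_l=data[:, 1], **meta)
    except ValueError as exc:
        raise ProfileFormatError(str(exc)) from exc


def write_profile(profile: RadialProfile, path) -> None:
    """Write a profile in the CSV format accepted by :func:`read_profile`."""
    buf = io.StringIO()
    buf.write(f"# surface_depth_um={profile.surface_depth_um:g}\n")
    if profile.light_ue is not None:
        buf.write(f"# light_uE={profile.light_ue:g}\n")
    if profile.temperature_c is not None:
        buf.write(f"# temperature_c={profile.temperature_c:g}\n")
    if profile.salinity is not None:
        buf.write(f"# salinity={profile.salinity:g}\n")
    buf.write("depth_um,o2_umol_l\n")
    for d, c in zip(profile.depth_um, profile.o2_umol_l):
        buf.write(f"{d:.6g},{c:.10g}\n")
    Path(path).write_text(buf.getvalue())


def read_trace(path) -> TransientTrace:
    """Read a point time-series CSV (``# dark_onset_s=`` header,
    ``time_s,o2_umol_l`` columns)."""
    lines = Path(path).read_text().splitlines()
    meta: dict = {}
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if not s.startswith("#"):
            break
        body = s.lstrip("#").strip()
        key, _, val = body.partition("=")
        if key.strip() == "dark_onset_s":
            try:
                meta["dark_onset_s"] = float(val)
            except ValueError as exc:
                raise ProfileFormatError(f"line {i + 1}: non-numeric dark_onset_s") from exc
    data = _parse_numeric_rows(lines, i, 2, ["time_s", "o2_umol_l"])
    return TransientTrace(time_s=data[:, 0], o2_umol_l=data[:, 1], **meta)


def write_trace(trace: TransientTrace, path) -> None:
    buf = io.StringIO()
    if trace.dark_onset_s is not None:
        buf.write(f"# dark_onset_s={trace.dark_onset_s:g}\n")
    buf.write("time_s,o2_umol_l\n")
    for t, c in zip(trace.time_s, trace.o2_umol_l):
        buf.write(f"{t:.6g},{c:.10g}\n")
    Path(path).write_text(buf.getvalue())


def whole_aggregate_flux(
    profile: RadialProfile,
    geometry: AggregateGeometry,
    medium: MediumProperties,
    method: str = "radial",
    min_clearance_um: float = 50.0,
    max_distance_um: float | None = None,
    planar_window_um: tuple[float, float] = (50.0, 250.0),
) -> float:
    """Whole-aggregate O2 exchange from the external part of a depth profile,
    nmol h^-1, signed (efflux/net production positive, uptake negative).

    External points are those at least ``min_clearance_um`` above the
    aggregate surface (excludes sensor-contact artifacts) and at most
    ``max_distance_um`` away (default one ESD).  See the module docstring
    for the two estimators.
    """
    height_um = profile.surface_depth_um - profile.depth_um  # >0 above surface
    if max_distance_um is None:
        max_distance_um = geometry.esd_mm * 1000.0
    sel = (height_um >= min_clearance_um) & (height_um <= max_distance_um)
    if sel.sum() < 4:
        raise ValueError(
            f"need >= 4 external points between {min_clearance_um} and "
            f"{max_distance_um} um above the surface, found {int(sel.sum())}"
        )
    c = profile.o2_umol_l[sel]
    d_h = medium.d_w_cm2_h

    if method == "radial":
        r_cm = geometry.radius_cm + height_um[sel] * 1e-4
        design = np.column_stack([np.ones_like(r_cm), 1.0 / r_cm])
        coef, _, rank, _ = np.linalg.lstsq(design, c, rcond=None)
        if rank < 2:
            raise ValueError("degenerate external points: cannot fit C_inf + k/r")
        k = coef[1]  # umol L^-1 cm
        # 4 pi D k : cm^2/h * umol/L/cm^-1 -> 1e-3 umol/h -> nmol/h (x1)
        return float(4.0 * math.pi * d_h * k)
    elif method == "planar":
        lo, hi = planar_window_um
        selp = (height_um >= lo) & (height_um <= hi)
        if selp.sum() < 2:
            raise ValueError(f"need >= 2 points in the planar window [{lo}, {hi}] um")
        x_cm = height_um[selp] * 1e-4
        slope = np.polyfit(x_cm, profile.o2_umol_l[selp], 1)[0]  # umol L^-1 cm^-1
        area_cm2 = geometry.surface_area_mm2 * 1e-2
        # J = -D dC/dz, umol cm^-2 h^-1 after the L->cm^3 conversion
        return float(-d_h * slope * 1e-3 * area_cm2 * 1e3)
    raise ValueError(f"unknown method {method!r}")


def gross_photosynthesis(net: float, dark_respiration: float) -> float:
    """Gross = net photosynthesis + dark respiration magnitude.

    Works identically for per-aggregate (nmol h^-1) and volumetric
    (umol cm^-3 h^-1) inputs.
    """
    if dark_respiration < 0:
        raise ValueError("dark_respiration is a magnitude and must be >= 0")
    return net + dark_respiration


def light_dark_shift_rate(
    trace: TransientTrace,
    dark_onset_s: float | None = None,
    window_s: tuple[float, float] = (2.0, 12.0),
) -> float:
    """Volumetric gross photosynthesis at the sensor point from a light-dark
    shift, umol cm^-3 h^-1.

    The initial O2 decline after darkening is fit by least squares over
    ``window_s`` (seconds after the dark onset; the default skips the first
    2 s of sensor response) and negated.  Longer windows are biased low by
    diffusive relaxation.
    """
    if dark_onset_s is None:
        dark_onset_s = trace.dark_onset_s
    if dark_onset_s is None:
        raise ValueError("dark_onset_s not given and not recorded on the trace")
    t0, t1 = (dark_onset_s + w for w in window_s)
    sel = (trace.time_s >= t0) & (trace.time_s <= t1)
    if sel.sum() < 2:
        raise ValueError(f"fit window [{t0}, {t1}] s contains {int(sel.sum())} samples")
    slope = np.polyfit(trace.time_s[sel], trace.o2_umol_l[sel], 1)[0]  # umol L^-1 s^-1
    return float(-slope * 3.6)  # x3600 s/h, x1e-3 L/cm^3


def carbon_fixation(gross_o2_nmol_h: float, pq: float) -> float:
    """Carbon fixation (ng C h^-1) from gross O2 production via the
    photosynthetic quotient: gross / PQ * 12.011."""
    if gross_o2_nmol_h < 0:
        raise ValueError("gross_o2_nmol_h must be >= 0")
    if pq <= 0:
        raise ValueError("pq must be positive")
    return gross_o2_nmol_h / pq * MOLAR_MASS_C


def resp_to_gross_ratio(dark_respiration: float, gross: float) -> float:
    """Ratio of dark respiration to gross photosynthesis."""
    if gross <= 0:
        raise ValueError("gross must be positive")
    return dark_respiration / gross


@dataclass(frozen=True)
class RateTable:
    """Per-aggregate and volumetric rates at each light level (the machine
    form of a published-style rate table)."""

    rows: tuple[dict, ...]
    volume_mm3: float
    pq: float
    complete: bool = True
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))

    def presentation(self) -> pd.DataFrame:
        """Rounded the way such tables are printed: integers for
        per-aggregate nmol h^-1 and ng h^-1, one decimal for volumetric."""
        df = self.to_dataframe()
        out = df.copy()
        for col in df.columns:
            if col.endswith("_nmol_h") or col == "carbon_fixation_ng_h":
                out[col] = df[col].round(0)
            elif col.endswith("_umol_cm3_h"):
                out[col] = df[col].round(1)
        return out


def build_rate_table(
    dark_profile: RadialProfile | None,
    light_profiles: dict[float, RadialProfile],
    geometry: AggregateGeometry,
    medium: MediumProperties,
    model: ModelParams | None = None,
    shift_traces: dict[float, TransientTrace] | None = None,
    flux_method: str = "radial",
) -> RateTable:
    """Assemble the full rate table from one dark and >= 1 lighted profiles.

    Gross photosynthesis and carbon fixation require the dark profile; if it
    is missing the table is returned partial and flagged.
    """
    if model is None:
        model = ModelParams()
    if not light_profiles and dark_profile is None:
        raise ValueError("need at least one profile")
    shift_traces = shift_traces or {}
    vol = geometry.volume_mm3
    notes: list[str] = []

    dark_resp = None
    rows: list[dict] = []
    if dark_profile is not None:
        flux = whole_aggregate_flux(dark_profile, geometry, medium, method=flux_method)
        dark_resp = abs(min(flux, 0.0))
        if flux > 0:
            notes.append("dark profile gave positive flux; respiration set to 0")
        rows.append(
            {
                "light_ue": 0.0,
                "dark_respiration_nmol_h": dark_resp,
                "vol_dark_respiration_umol_cm3_h": per_aggregate_to_volumetric(dark_resp, vol),
            }
        )
    else:
        notes.append("no dark profile: gross and carbon-fixation columns unavailable")

    for light in sorted(light_profiles):
        net = whole_aggregate_flux(light_profiles[light], geometry, medium, method=flux_method)
        row: dict = {
            "light_ue": float(light),
            "net_photosynthesis_nmol_h": net,
            "vol_net_photosynthesis_umol_cm3_h": per_aggregate_to_volumetric(net, vol),
        }
        if dark_resp is not None:
            gross = gross_photosynthesis(net, dark_resp)
            row["gross_photosynthesis_nmol_h"] = gross
            row["vol_gross_photosynthesis_umol_cm3_h"] = per_aggregate_to_volumetric(gross, vol)
            row["carbon_fixation_ng_h"] = carbon_fixation(max(gross, 0.0), model.pq)
        if light in shift_traces:
            row["ld_shift_vol_gross_umol_cm3_h"] = light_dark_shift_rate(shift_traces[light])
        rows.append(row)

    return RateTable(
        rows=tuple(rows),
        volume_mm3=vol,
        pq=model.pq,
        complete=dark_resp is not None,
        notes=tuple(notes),
    )
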