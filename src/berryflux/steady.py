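"""Closed-form steady-state O2 field around a uniformly reacting sphere.

A spherical aggregate of radius R reacts at a uniform volumetric rate Q
(production positive, respiration negative) in a diffusive medium.  Inside,
O2 moves with apparent diffusivity theta*D_w; outside, with D_w.  At steady
state the field is

    inside  (r <= R):          C(r) = C_R + q_in/(6 theta D) (R^2 - r^2)
    outside (R <= r <= R+dbl): C(r) = C_inf + Q_tot/(4 pi D) (1/r - 1/(R+dbl))
    beyond the boundary layer: C(r) = C_inf

with Q_tot the total reaction rate and continuity of concentration and flux
at r = R.  With an infinite stagnant medium (dbl -> inf) the external term is
the familiar Q_tot/(4 pi D r) tail.

The total reaction is Q times the aggregate's working volume; when that
volume is overridden (see :class:`~berryflux.geometry.AggregateGeometry`) the
internal uniform source is rescaled to q_in = Q * V_aggregate / V_sphere(R)
so the surface flux stays consistent with the stated total.  With the default
volume the two coincide.

Setting Q to minus the critical respiration drives the core concentration
exactly to zero: that rate is the diffusion-limitation (anoxia) threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import AggregateGeometry
from .units import MediumProperties, ModelParams

__all__ = ["RadialSolution", "solve_steady", "critical_respiration", "core_concentration"]


@dataclass(frozen=True)
class RadialSolution:
    """Steady radial O2 field.

    ``concentration_umol_cm3`` is the non-negative-truncated profile on
    ``radius_cm``; ``core_anoxic`` flags that the untruncated solution went
    negative somewhere (respiration stronger than diffusion can supply).
    """

    radius_cm: np.ndarray
    concentration_umol_cm3: np.ndarray
    geometry: AggregateGeometry
    q_umol_cm3_h: float
    medium: MediumProperties
    model: ModelParams
    core_anoxic: bool

    @property
    def o2_umol_l(self) -> np.ndarray:
        return self.concentration_umol_cm3 * 1e3

    def at(self, r_cm):
        """Evaluate the closed form (clipped at zero) at radius or radii r_cm,
        in umol cm^-3."""
        r_arr = np.atleast_1d(np.asarray(r_cm, dtype=float))
        c = np.clip(
            _evaluate(r_arr, self.geometry, self.q_umol_cm3_h, self.medium, self.model),
            0.0,
            None,
        )
        return c if np.ndim(r_cm) else float(c[0])


def _resistances(
    geometry: AggregateGeometry, medium: MediumProperties, model: ModelParams
) -> tuple[float, float]:
    """Internal and external transport resistances (h cm^3 umol^-1 scale).

    Returned as the two bracketed terms of
    C(0) - C_inf = Q R^2 [ext + int]:  ext = (1/(3D))(1 - R/(R+dbl)),
    int = 1/(6 theta D), with D in cm^2 h^-1.
    """
    d_h = medium.d_w_cm2_h
    r = geometry.radius_cm
    if math.isinf(model.dbl_um):
        shield = 1.0
    else:
        dbl_cm = model.dbl_um * 1e-4
        shield = 1.0 - r / (r + dbl_cm)
    ext = shield / (3.0 * d_h)
    internal = 1.0 / (6.0 * model.theta * d_h)
    return ext, internal


def _evaluate(
    r_cm: np.ndarray,
    geometry: AggregateGeometry,
    q_umol_cm3_h: float,
    medium: MediumProperties,
    model: ModelParams,
) -> np.ndarray:
    d_h = medium.d_w_cm2_h
    rr = geometry.radius_cm
    c_inf = medium.c_sat_umol_cm3
    v_sphere_cm3 = 4.0 / 3.0 * math.pi * rr**3
    q_total = q_umol_cm3_h * geometry.volume_cm3  # umol h^-1
    q_in = q_total / v_sphere_cm3  # effective internal volumetric rate

    if math.isinf(model.dbl_um):
        inv_outer = 0.0
        r_edge = math.inf
    else:
        r_edge = rr + model.dbl_um * 1e-4
        inv_outer = 1.0 / r_edge

    c_surface = c_inf + q_total / (4.0 * math.pi * d_h) * (1.0 / rr - inv_outer)
    c = np.empty_like(r_cm)
    inside = r_cm <= rr
    c[inside] = c_surface + q_in / (6.0 * model.theta * d_h) * (rr**2 - r_cm[inside] ** 2)
    outside = ~inside
    with np.errstate(divide="ignore"):
        ext = c_inf + q_total / (4.0 * math.pi * d_h) * (1.0 / r_cm[outside] - inv_outer)
    c[outside] = np.where(r_cm[outside] <= r_edge, ext, c_inf)
    return c


def solve_steady(
    geometry: AggregateGeometry,
    q_umol_cm3_h: float,
    medium: MediumProperties,
    model: ModelParams | None = None,
    n_points: int = 500,
    r_max_cm: float | None = None,
) -> RadialSolution:
    """Steady-state radial O2 profile for uniform reaction rate Q.

    Parameters
    ----------
    q_umol_cm3_h
        Net volumetric reaction rate, production positive and respiration
        negative, referred to the aggregate's working volume.
    n_points, r_max_cm
        Output grid: ``n_points`` radii from 0 to ``r_max_cm``
        (default 4 aggregate radii).

    Concentrations are clipped at zero; if the untruncated solution goes
    negative the returned solution is flagged ``core_anoxic`` (the stated Q
    cannot be sustained everywhere).
    """
    if model is None:
        model = ModelParams()
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if r_max_cm is None:
        r_max_cm = 4.0 * geometry.radius_cm
    r = np.linspace(0.0, r_max_cm, n_points)
    c = _evaluate(r, geometry, q_umol_cm3_h, medium, model)
    anoxic = bool(np.any(c < 0.0))
    return RadialSolution(
        radius_cm=r,
        concentration_umol_cm3=np.clip(c, 0.0, None),
        geometry=geometry,
        q_umol_cm3_h=q_umol_cm3_h,
        medium=medium,
        model=model,
        core_anoxic=anoxic,
    )


def critical_respiration(
    geometry: AggregateGeometry,
    medium: MediumProperties,
    model: ModelParams | None = None,
) -> float:
    """Diffusion-limitation threshold, umol cm^-3 h^-1 (positive magnitude).

    The uniform volumetric respiration at which the core concentration just
    reaches zero:

        Q_crit = C_inf / ( R^2 [ (1/(3D))(1 - R/(R+dbl)) + 1/(6 theta D) ] )

    which for an infinite stagnant medium reduces to
    C_inf / ( R^2 (1/(3D) + 1/(6 theta D)) ).  Respiration above this value
    makes the aggregate core anoxic no matter how oxygenated the bulk water.
    """
    if model is None:
        model = ModelParams()
    ext, internal = _resistances(geometry, medium, model)
    r = geometry.radius_cm
    q_crit_sphere = medium.c_sat_umol_cm3 / (r**2 * (ext + internal))
    # With an overridden working volume Q is referred to that volume; rescale
    # so that solve_steady(-Q_crit) still zeroes the core exactly.
    return q_crit_sphere * geometry.sphere_volume_mm3 / geometry.volume_mm3


def core_concentration(solution: RadialSolution) -> float:
    """O2 concentration at the aggregate center, umol L^-1."""
    return float(solution.at(0.0) * 1e3)
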