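"""Time-dependent radial diffusion-reaction solver for light-dark experiments.

Solves, in spherical symmetry,

    dC/dt = (1/r^2) d/dr ( r^2 D(r) dC/dr ) + q(r, t)

with D = theta*D_w inside the aggregate and D_w outside, a symmetry condition
at r = 0, and a far-field Dirichlet condition C = C_inf at the outer edge of
the domain (10 aggregate radii by default, or the configured boundary-layer
thickness).  The source q is piecewise constant in time (a light schedule)
and uniform inside the aggregate.  Consumption is smoothly switched off as
the local concentration approaches zero, so no O2 is consumed where none is
left and the state stays non-negative up to solver tolerance.

Discretization is a conservative finite-volume scheme on uniform spherical
shells (the r = 0 singularity is handled naturally by the zero-area inner
face), integrated in time by method of lines with LSODA and a tridiagonal
Jacobian bandwidth, one light segment at a time so source switches land
exactly on segment boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import AggregateGeometry
from .steady import RadialSolution, solve_steady
from .units import MediumProperties, ModelParams

__all__ = [
    "SourceSegment",
    "SourceSchedule",
    "TransientTrace",
    "TransientSolution",
    "simulate",
    "time_to_anoxia",
]

#: concentration scale (umol/L) over which consumption ramps off near anoxia
_O2_LIMIT_SCALE = 1.0


@dataclass(frozen=True)
class SourceSegment:
    """One interval of the light schedule: uniform volumetric source
    q (umol cm^-3 h^-1, production positive) on [t_start_s, t_end_s)."""

    t_start_s: float
    t_end_s: float
    q_umol_cm3_h: float

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise ValueError("segment must have t_end_s > t_start_s")


@dataclass(frozen=True)
class SourceSchedule:
    """Contiguous piecewise-constant source protocol."""

    segments: tuple[SourceSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        for prev, nxt in zip(segs, segs[1:]):
            if not math.isclose(prev.t_end_s, nxt.t_start_s):
                raise ValueError("schedule segments must be contiguous")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, q_umol_cm3_h: float, t_end_s: float) -> "SourceSchedule":
        return cls((SourceSegment(0.0, t_end_s, q_umol_cm3_h),))

    @classmethod
    def from_steps(cls, steps: list[tuple[float, float, float]]) -> "SourceSchedule":
        """Build from (t_start_s, t_end_s, q) triples."""
        return cls(tuple(SourceSegment(*s) for s in steps))

    @property
    def t_end_s(self) -> float:
        return self.segments[-1].t_end_s

    def rate_at(self, t_s: float) -> float:
        for seg in self.segments:
            if seg.t_start_s <= t_s < seg.t_end_s:
                return seg.q_umol_cm3_h
        return self.segments[-1].q_umol_cm3_h


@dataclass(frozen=True)
class TransientTrace:
    """O2 time series at a single tracked radius (umol L^-1 vs seconds)."""

    time_s: np.ndarray
    o2_umol_l: np.ndarray
    radius_cm: float = 0.0
    dark_onset_s: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        c = np.asarray(self.o2_umol_l, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("time_s and o2_umol_l must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "o2_umol_l", c)


@dataclass(frozen=True)
class TransientSolution:
    """Full space-time solution C(r, t) in umol L^-1."""

    time_s: np.ndarray
    radius_cm: np.ndarray  # cell centers
    o2_umol_l: np.ndarray  # shape (n_times, n_cells)
    geometry: AggregateGeometry
    medium: MediumProperties
    model: ModelParams
    schedule: SourceSchedule
    cell_volumes_cm3: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def center_trace(self, dark_onset_s: float | None = None) -> TransientTrace:
        return TransientTrace(
            time_s=self.time_s,
            o2_umol_l=self.o2_umol_l[:, 0],
            radius_cm=float(self.radius_cm[0]),
            dark_onset_s=dark_onset_s,
        )

    def trace_at(self, r_cm: float, dark_onset_s: float | None = None) -> TransientTrace:
        i = int(np.argmin(np.abs(self.radius_cm - r_cm)))
        return TransientTrace(
            time_s=self.time_s,
            o2_umol_l=self.o2_umol_l[:, i],
            radius_cm=float(self.radius_cm[i]),
            dark_onset_s=dark_onset_s,
        )

    def final_profile(self) -> tuple[np.ndarray, np.ndarray]:
        return self.radius_cm, self.o2_umol_l[-1]

    def total_o2_umol(self) -> np.ndarray:
        """Domain O2 inventory per stored time (umol)."""
        return (self.o2_umol_l * 1e-3 * self.cell_volumes_cm3[None, :]).sum(axis=1)


class _Grid:
    """Uniform spherical finite-volume grid."""

    def __init__(
        self,
        geometry: AggregateGeometry,
        medium: MediumProperties,
        model: ModelParams,
        n_inside: int,
        far_factor: float,
    ) -> None:
        r_agg = geometry.radius_cm
        if math.isinf(model.dbl_um):
            r_outer = r_agg * (1.0 + far_factor)
        else:
            r_outer = r_agg + model.dbl_um * 1e-4
        dr = r_agg / n_inside
        n = max(int(round(r_outer / dr)), n_inside + 2)
        faces = np.arange(n + 1) * dr
        self.dr = dr
        self.centers = 0.5 * (faces[:-1] + faces[1:])
        self.face_area = 4.0 * math.pi * faces**2
        self.volumes = 4.0 / 3.0 * math.pi * (faces[1:] ** 3 - faces[:-1] ** 3)
        d_cell = np.where(self.centers < r_agg, model.theta * medium.d_w, medium.d_w)
        # harmonic mean at interior faces
        d_face = np.zeros(n + 1)
        d_face[1:-1] = 2.0 * d_cell[:-1] * d_cell[1:] / (d_cell[:-1] + d_cell[1:])
        d_face[-1] = d_cell[-1]
        self.d_face = d_face
        self.inside = self.centers < r_agg
        self.n = n


def _rhs_factory(grid: _Grid, c_inf: float, q_umol_l_s: float, dirichlet: bool):
    a = grid.face_area
    d = grid.d_face
    dr = grid.dr
    v = grid.volumes
    inside = grid.inside
    # transmissivities (cm^3/s) at interior faces and the outer face
    trans = a[1:-1] * d[1:-1] / dr
    trans_out = a[-1] * d[-1] / (0.5 * dr)

    def rhs(t: float, c: np.ndarray) -> np.ndarray:
        flux = trans * (c[1:] - c[:-1])  # face flux * dr, umol/L cm^3/s
        dc = np.zeros_like(c)
        dc[:-1] += flux
        dc[1:] -= flux
        if dirichlet:
            dc[-1] += trans_out * (c_inf - c[-1])
        dc /= v
        if q_umol_l_s != 0.0:
            src = np.where(inside, q_umol_l_s, 0.0)
            if q_umol_l_s < 0.0:
                src = src * np.clip(c / _O2_LIMIT_SCALE, 0.0, 1.0)
            dc += src
        return dc

    return rhs


def simulate(
    geometry: AggregateGeometry,
    medium: MediumProperties,
    model: ModelParams | None = None,
    schedule: SourceSchedule | None = None,
    initial: float | str | np.ndarray | RadialSolution = "ambient",
    t_end_s: float | None = None,
    n_inside: int = 40,
    far_factor: float = 10.0,
    output_dt_s: float = 1.0,
    far_boundary: str = "dirichlet",
    rtol: float = 1e-6,
    atol: float = 1e-3,
) -> TransientSolution:
    """Integrate the radial diffusion-reaction equation under a light schedule.

    Parameters
    ----------
    schedule
        Piecewise-constant source protocol; defaults to zero source for
        ``t_end_s`` seconds.
    initial
        ``"ambient"`` (uniform C_inf), ``"steady"`` (analytic steady state of
        the first segment's source), a scalar concentration in umol L^-1
        applied inside the aggregate with C_inf outside, an explicit array on
        the cell centers, or a :class:`RadialSolution` to sample.
    n_inside
        Number of finite-volume shells spanning the aggregate radius.
    far_boundary
        ``"dirichlet"`` pins C = C_inf at the outer edge; ``"reflecting"``
        closes the domain (zero flux) for mass-balance checks.
    """
    if model is None:
        model = ModelParams()
    if schedule is None:
        if t_end_s is None:
            raise ValueError("provide a schedule or t_end_s")
        schedule = SourceSchedule.constant(0.0, t_end_s)
    if far_boundary not in ("dirichlet", "reflecting"):
        raise ValueError(f"unknown far_boundary {far_boundary!r}")

    grid = _Grid(geometry, medium, model, n_inside, far_factor)
    c_inf = medium.c_sat  # umol/L

    if isinstance(initial, str):
        if initial == "ambient":
            c0 = np.full(grid.n, c_inf)
        elif initial == "steady":
            sol = solve_steady(geometry, schedule.segments[0].q_umol_cm3_h, medium, model)
            c0 = np.asarray(sol.at(grid.centers), dtype=float) * 1e3
        else:
            raise ValueError(f"unknown initial condition {initial!r}")
    elif isinstance(initial, RadialSolution):
        c0 = np.asarray(initial.at(grid.centers), dtype=float) * 1e3
    elif np.ndim(initial) == 0:
        c0 = np.where(grid.inside, float(initial), c_inf)
    else:
        c0 = np.asarray(initial, dtype=float)
        if c0.shape != (grid.n,):
            raise ValueError(f"explicit initial profile must have shape ({grid.n},)")

    # rescale as in the steady model so Q refers to the working volume
    vol_ratio = geometry.volume_mm3 / geometry.sphere_volume_mm3

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    c = c0.copy()
    for k, seg in enumerate(schedule.segments):
        q_umol_l_s = seg.q_umol_cm3_h * vol_ratio * 1e3 / 3600.0
        rhs = _rhs_factory(grid, c_inf, q_umol_l_s, far_boundary == "dirichlet")
        t_eval = np.arange(seg.t_start_s, seg.t_end_s, output_dt_s)
        if t_eval.size == 0 or t_eval[0] > seg.t_start_s:
            t_eval = np.insert(t_eval, 0, seg.t_start_s)
        res = solve_ivp(
            rhs,
            (seg.t_start_s, seg.t_end_s),
            c,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            lband=1,
            uband=1,
        )
        if not res.success:
            raise RuntimeError(
                f"transient solve failed in segment {k} "
                f"[{seg.t_start_s}, {seg.t_end_s}] s: {res.message}"
            )
        times.append(res.t)
        states.append(res.y.T)
        c = res.y[:, -1].copy()
    # append the final instant
    times.append(np.array([schedule.t_end_s]))
    states.append(c[None, :])

    t_all = np.concatenate(times)
    y_all = np.clip(np.concatenate(states, axis=0), 0.0, None)
    return TransientSolution(
        time_s=t_all,
        radius_cm=grid.centers,
        o2_umol_l=y_all,
        geometry=geometry,
        medium=medium,
        model=model,
        schedule=schedule,
        cell_volumes_cm3=grid.volumes,
    )


def time_to_anoxia(trace: TransientTrace, threshold_umol_l: float = 1.0) -> float:
    """Minutes until the trace first drops below threshold.

    Linear interpolation between samples; returns ``math.inf`` if the trace
    never crosses.
    """
    c = trace.o2_umol_l
    t = trace.time_s
    below = np.nonzero(c < threshold_umol_l)[0]
    if below.size == 0:
        return math.inf
    i = below[0]
    if i == 0:
        return float(t[0] / 60.0)
    t_cross = t[i - 1] + (threshold_umol_l - c[i - 1]) * (t[i] - t[i - 1]) / (c[i] - c[i - 1])
    return float(t_cross / 60.0)
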