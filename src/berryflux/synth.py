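"""Synthetic microsensor data from the forward models.

Emulates the raw inputs the estimators consume — steady-state depth
profiles, light-dark point traces and incubation tables — by sampling the
forward models and adding i.i.d. Gaussian sensor noise.  Everything is
deterministic under a fixed seed, so generator/estimator pairs can be tested
as exact inverses at sigma = 0 and statistically under noise.

The default scenario reproduces the study conditions for the green-berry
aggregates: ESD 1.7 mm with a 2.8 mm^3 working volume, 24 C / S 35 water,
theta 0.95, PQ 1.2, dark respiration 6.8 umol cm^-3 h^-1 and net production
4.8 / 11 umol cm^-3 h^-1 at 170 / 320 uE m^-2 s^-1, sampled at 50 um depth
steps and 1 Hz with sigma = 2 umol L^-1 sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import AggregateGeometry
from .steady import solve_steady
from .transient import SourceSchedule, TransientTrace, simulate
from .profiles import RadialProfile
from .units import MediumProperties, ModelParams

__all__ = [
    "ScenarioSpec",
    "green_berry_scenario",
    "generate_profile",
    "generate_ld_trace",
    "generate_incubation_table",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to synthesize one aggregate's measurements."""

    geometry: AggregateGeometry
    medium: MediumProperties
    model: ModelParams = field(default_factory=ModelParams)
    dark_respiration_umol_cm3_h: float = 6.8
    net_production_umol_cm3_h: dict = field(
        default_factory=lambda: {170.0: 4.8, 320.0: 11.0}
    )
    surface_depth_um: float = 2000.0
    profile_step_um: float = 50.0
    trace_hz: float = 1.0
    noise_sigma_umol_l: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_step_um <= 0:
            raise ValueError("profile_step_um must be positive")
        if self.trace_hz <= 0:
            raise ValueError("trace_hz must be positive")
        if self.noise_sigma_umol_l < 0:
            raise ValueError("noise_sigma_umol_l must be >= 0")

    def with_(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)

    def net_rate(self, light_ue: float) -> float:
        """Volumetric source for a light level: net production in the light,
        minus dark respiration at zero light."""
        if light_ue == 0:
            return -self.dark_respiration_umol_cm3_h
        try:
            return self.net_production_umol_cm3_h[float(light_ue)]
        except KeyError:
            raise KeyError(
                f"no net production configured for light level {light_ue}"
            ) from None


def green_berry_scenario(seed: int = 0, noise_sigma_umol_l: float = 2.0) -> ScenarioSpec:
    """The default green-berry study scenario (see module docstring)."""
    return ScenarioSpec(
        geometry=AggregateGeometry(esd_mm=1.7, volume_mm3=2.8),
        medium=MediumProperties.for_conditions(temperature_c=24.0, salinity=35.0),
        model=ModelParams(theta=0.95, pq=1.2),
        seed=seed,
        noise_sigma_umol_l=noise_sigma_umol_l,
    )


def generate_profile(spec: ScenarioSpec, light_ue: float) -> RadialProfile:
    """Steady-state depth profile through the aggregate center for one light
    level, with additive Gaussian sensor noise.

    Depths run from the water surface to the far side of the aggregate in
    ``profile_step_um`` steps; each depth maps to the radial distance from
    the aggregate center.
    """
    q = spec.net_rate(light_ue)
    sol = solve_steady(spec.geometry, q, spec.medium, spec.model)
    esd_um = spec.geometry.esd_mm * 1000.0
    center_um = spec.surface_depth_um + esd_um / 2.0
    depth = np.arange(0.0, spec.surface_depth_um + esd_um + 0.5 * spec.profile_step_um,
                      spec.profile_step_um)
    r_cm = np.abs(center_um - depth) * 1e-4
    o2 = np.asarray(sol.at(r_cm), dtype=float) * 1e3  # umol/L
    if spec.noise_sigma_umol_l > 0:
        rng = np.random.default_rng(spec.seed)
        o2 = o2 + rng.normal(0.0, spec.noise_sigma_umol_l, size=o2.shape)
    return RadialProfile(
        depth_um=depth,
        o2_umol_l=np.clip(o2, 0.0, None),
        surface_depth_um=spec.surface_depth_um,
        light_ue=float(light_ue),
        temperature_c=spec.medium.temperature_c,
        salinity=spec.medium.salinity,
    )


def generate_ld_trace(
    spec: ScenarioSpec,
    schedule: SourceSchedule,
    dark_onset_s: float | None = None,
    initial: str = "steady",
    n_inside: int = 40,
) -> TransientTrace:
    """Center-point light-dark trace: transient forward model sampled at
    ``trace_hz`` plus Gaussian sensor noise.

    ``dark_onset_s`` defaults to the start of the first segment whose source
    is lower than its predecessor's (the first darkening).
    """
    sol = simulate(
        spec.geometry,
        spec.medium,
        spec.model,
        schedule=schedule,
        initial=initial,
        n_inside=n_inside,
        output_dt_s=1.0 / spec.trace_hz,
    )
    if dark_onset_s is None:
        segs = schedule.segments
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.q_umol_cm3_h < prev.q_umol_cm3_h:
                dark_onset_s = nxt.t_start_s
                break
    trace = sol.center_trace(dark_onset_s=dark_onset_s)
    o2 = trace.o2_umol_l
    if spec.noise_sigma_umol_l > 0:
        rng = np.random.default_rng(spec.seed)
        o2 = np.clip(o2 + rng.normal(0.0, spec.noise_sigma_umol_l, size=o2.shape), 0.0, None)
    return TransientTrace(
        time_s=trace.time_s,
        o2_umol_l=o2,
        radius_cm=trace.radius_cm,
        dark_onset_s=dark_onset_s,
    )


def generate_incubation_table(
    n_bottles: int,
    true_rate_nmol_mg_h: float,
    dry_masses_mg,
    seed: int = 0,
    rel_noise: float = 0.05,
    span_h: float = 48.0,
    dark_h_per_day: float = 10.0,
) -> pd.DataFrame:
    """Synthetic acetylene-reduction bottle table.

    Ethylene per bottle is true_rate x mass x dark hours elapsed, perturbed
    by multiplicative Gaussian noise of relative magnitude ``rel_noise``.
    """
    if n_bottles <= 0 or true_rate_nmol_mg_h < 0:
        raise ValueError("n_bottles must be positive and true rate >= 0")
    masses = np.broadcast_to(np.asarray(dry_masses_mg, dtype=float), (n_bottles,))
    if np.any(masses <= 0):
        raise ValueError("dry masses must be positive")
    full, rem = divmod(span_h, 24.0)
    dark_hours = full * dark_h_per_day + max(0.0, rem - (24.0 - dark_h_per_day))
    rng = np.random.default_rng(seed)
    factor = 1.0 + rng.normal(0.0, rel_noise, size=n_bottles) if rel_noise > 0 else np.ones(n_bottles)
    ethylene = np.clip(true_rate_nmol_mg_h * masses * dark_hours * factor, 0.0, None)
    return pd.DataFrame(
        {
            "bottle_id": [f"bottle_{i + 1}" for i in range(n_bottles)],
            "ethylene_nmol": ethylene,
            "span_h": span_h,
            "dark_h_per_day": dark_h_per_day,
            "dry_mass_mg": masses,
        }
    )
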