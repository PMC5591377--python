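"""TOML configuration for medium and model parameters.

Example::

    [medium]
    temperature_c = 24.0
    salinity = 35.0
    # d_w_cm2_s = 2.175e-5      # optional override
    # c_sat_umol_l = 215.0      # optional override

    [model]
    theta = 0.95
    pq = 1.2
    # dbl_um = 300.0            # omit for a stagnant infinite medium
    anoxia_umol_l = 1.0

The salinity entry deliberately stays explicit: the O2 solubility of the
bathing water differs by ~20% between a brackish S = 3.5 and a seawater
S = 35 reading, and both are legitimate configurations.
"""

from __future__ import annotations

import math
import tomllib
from pathlib import Path

from .units import MediumProperties, ModelParams

__all__ = ["load_config", "default_config"]

_DEFAULT_MEDIUM = {"temperature_c": 24.0, "salinity": 35.0}
_DEFAULT_MODEL = {"theta": 0.95, "pq": 1.2, "anoxia_umol_l": 1.0}


def _build(medium_cfg: dict, model_cfg: dict) -> tuple[MediumProperties, ModelParams]:
    medium = MediumProperties.for_conditions(
        temperature_c=medium_cfg.get("temperature_c", _DEFAULT_MEDIUM["temperature_c"]),
        salinity=medium_cfg.get("salinity", _DEFAULT_MEDIUM["salinity"]),
        d_w=medium_cfg.get("d_w_cm2_s"),
        c_sat=medium_cfg.get("c_sat_umol_l"),
    )
    model = ModelParams(
        theta=model_cfg.get("theta", _DEFAULT_MODEL["theta"]),
        pq=model_cfg.get("pq", _DEFAULT_MODEL["pq"]),
        dbl_um=model_cfg.get("dbl_um", math.inf),
        anoxia_umol_l=model_cfg.get("anoxia_umol_l", _DEFAULT_MODEL["anoxia_umol_l"]),
    )
    return medium, model


def default_config() -> tuple[MediumProperties, ModelParams]:
    """The package defaults: 24 C / S 35 water, theta 0.95, PQ 1.2,
    stagnant infinite external medium, 1 umol/L anoxia threshold."""
    return _build({}, {})


def load_config(path) -> tuple[MediumProperties, ModelParams]:
    """Load ``[medium]`` and ``[model]`` sections from a TOML file; missing
    keys fall back to the package defaults."""
    with open(Path(path), "rb") as fh:
        cfg = tomllib.load(fh)
    return _build(cfg.get("medium", {}), cfg.get("model", {}))
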