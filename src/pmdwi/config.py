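"""Flat key/value configuration files (YAML).

Schema (all keys optional; defaults in parentheses):

    tissue_T1: ms (400)            tissue_T2: ms (45)
    tissue_D: mm^2/s (0.08e-3)
    gamma: rad/s/T (2.6752e8)      G_max: mT/m (38)
    T_dead: ms (5)                 T_acq_cap: ms (30)
    ssfp_TR_min: ms (10)           ssfp_TR_max: ms (200)
    se_TR_min: ms (150)            se_TR_max: ms (3000)

Unknown keys are rejected to catch typos.  Values round-trip at full float
precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from .constants import PhysicalConstants
from .params import TissueParams

__all__ = ["DEFAULTS", "load_config", "save_config", "tissue_from_config", "constants_from_config"]

DEFAULTS = {
    "tissue_T1": 400.0,
    "tissue_T2": 45.0,
    "tissue_D": 0.08e-3,
    "gamma": 2.6752e8,
    "G_max": 38.0,
    "T_dead": 5.0,
    "T_acq_cap": 30.0,
    "ssfp_TR_min": 10.0,
    "ssfp_TR_max": 200.0,
    "se_TR_min": 150.0,
    "se_TR_max": 3000.0,
}


def load_config(path: Union[str, Path, None]) -> dict:
    """Defaults overridden by the flat YAML file at ``path`` (None: defaults)."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a flat key/value mapping")
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update({k: float(v) for k, v in user.items()})
    return cfg


def save_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in cfg.items()}, fh, sort_keys=True)


def tissue_from_config(cfg: dict) -> TissueParams:
    return TissueParams(T1=cfg["tissue_T1"], T2=cfg["tissue_T2"], D=cfg["tissue_D"])


def constants_from_config(cfg: dict) -> PhysicalConstants:
    return PhysicalConstants(gamma=cfg["gamma"], G_max=cfg["G_max"])
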