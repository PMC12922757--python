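"""Layered YAML run configuration with strict key checking.

Every parameter defaults to the value used by the owning analysis module;
unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .device import DeviceGeometry
from .errors import ConfigError
from .synthetic_data import PHENOTYPE_PRESETS, PhenotypeParams

__all__ = ["default_config", "load_config", "merge_config", "config_hash",
           "geometry_from_config", "phenotype_from_config", "dump_config"]


def default_config() -> dict:
    phenos = {}
    for name, p in PHENOTYPE_PRESETS.items():
        phenos[name] = {
            "base_speed": p.base_speed,
            "persistence": p.persistence,
            "gradient_bias": p.gradient_bias,
            "noise_sigma": p.noise_sigma,
            "post_speed_factor": p.post_speed_factor,
            "post_directionality_factor": p.post_directionality_factor,
            "spike_prob": p.spike_prob,
            "polarity_loss_prob": p.polarity_loss_prob,
            "dwell_mean_frames": p.dwell_mean_frames,
            "vesicle_median_pre": p.vesicle_median_pre,
            "vesicle_median_post": p.vesicle_median_post,
            "step_jitter_cv": p.step_jitter_cv,
        }
    return {
        "device": {
            "chamber_length": 300.0,
            "chamber_height": 5.0,
            "constriction_x": 100.0,
            "pillar_extent": 20.0,
            "gap_width": 3.0,
            "cell_length": 25.0,
            "saturation_x": 250.0,
            "chamber_width": 300.0,
        },
        "gradient": {
            "D": 5.0e-6,  # cm^2/s
            "t_end": 1800.0,
            "dx": 1.0,
            "dt": 1.0,
            "tolerance": 0.10,
        },
        "phenotypes": phenos,
        "simulate": {
            "phenotype": "control",
            "n_cells": 300,
            "dt": 30.0,
            "n_frames": 180,
            "seed": 0,
        },
        "traces": {
            "baseline": 100.0,
            "noise_cv": 0.05,
            "spike_amp": 400.0,
            "spike_decay": 90.0,
            "seed": 1,
        },
        "vesicles": {"seed": 2, "dispersion": 5.0},
        "render": {
            "enabled": True,
            "pixel_size": 0.5,
            "cortical_ratio": 2.0,
            "n_frames": 3,
            "seed": 3,
            "noise_sd": 0.0,
        },
        "analysis": {
            "min_final_x": 100.0,
            "n_boot": 2000,
            "bootstrap_seed": 4,
            "k_mad": 5.0,
            "band_width": 3,
            "ne_band": 2,
            "keratocyte_thresholds": {
                "orientation": 45.0,
                "eccentricity": 0.75,
                "solidity": 0.9,
            },
            "exclude_saturated": True,
        },
    }


def merge_config(base: dict, override: dict, path: str = "") -> dict:
    """Deep-merge ``override`` into ``base``; unknown keys raise ConfigError."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            # phenotype blocks may introduce new named phenotypes
            if path == "phenotypes":
                out[key] = copy.deepcopy(val)
                continue
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = merge_config(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Defaults overlaid with an optional user YAML file."""
    cfg = default_config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ConfigError("configuration root must be a mapping")
    return merge_config(cfg, user)


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def geometry_from_config(cfg: dict) -> DeviceGeometry:
    return DeviceGeometry(**cfg["device"])


def phenotype_from_config(cfg: dict, name: str | None = None) -> PhenotypeParams:
    name = name or cfg["simulate"]["phenotype"]
    if name not in cfg["phenotypes"]:
        raise ConfigError(f"unknown phenotype: {name}")
    return PhenotypeParams(label=name, **cfg["phenotypes"][name])
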