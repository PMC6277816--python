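"""Pipeline configuration schema and defaults.

A config is a nested mapping validated against the default template:
unknown keys are rejected, missing keys take defaults. Units are fixed
package-wide (mm, ms, mV, S/cm, pA/pF) and declared in the config for
the manifest.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "units": {"length": "mm", "time": "ms", "potential": "mV", "conductivity": "S/cm"},
    "phantom": {
        "cavity_radius": 8.0,
        "wall_thickness": 1.5,
        "spacing": 0.4,
        "mean_wall": 250.0,
        "sd_wall": 30.0,
        "mean_cavity": 450.0,
        "sd_cavity": 40.0,
    },
    "shell": {
        "radii": [15.0, 13.0, 12.0],
        "n_theta": 16,
        "n_phi": 32,
        "n_layers": 2,
        "thickness_top": 1.0,
        "thickness_bottom": 3.0,
    },
    "segmentation": {
        "max_thickness": 3.0,
        "min_dilations": 1,
        "median_radius": 1,
    },
    "smoothing": {
        "target_spacing": 0.1,
        "max_displacement_fraction": 0.5,
        "iterations": 50,
    },
    "fibers_surface": {"band_width": 2, "passes": 3},
    "fibers_volume": {"scheme": "linear"},
    "cv_fit": {
        "cv_l": 1.2,
        "cv_t": 0.4,
        "resolution": 0.2,
        "dt": 0.01,
        "n_beats": 50,
        "bcl": 1000.0,
        "cable_length": 20.0,
        "tolerance": 0.005,
        "max_iter": 10,
    },
    "simulate": {
        "t_end": 40.0,
        "dt": 0.02,
        "stim_amplitude": 50.0,
        "stim_duration": 2.0,
        "stim_landmark": "body_top_1",
        "stim_radius": 3.0,
        "lat_threshold": -20.0,
    },
}


def _merge(template: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(template)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in template:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(template[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(template[key], val, here)
        else:
            out[key] = val
    return out


def validate_config(user: dict | None) -> dict:
    return _merge(DEFAULT_CONFIG, user or {})


def load_config(path: str | None) -> dict:
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return validate_config(doc)
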