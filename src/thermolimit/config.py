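"""Run configuration: defaults, YAML file loading, CLI overrides, echoing.

Precedence (lowest to highest): built-in defaults < config file < CLI flags.
Every command writes its effective configuration to ``config_echo.yaml`` in
its output directory; re-running a command from the echo reproduces the
outputs byte-identically given the same seed.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "detector": {
        "v_thresh": 0.03,
        "w": 280,
        "alignment": "centered",
        "crossing_mode": "first",
        "max_missing_frac": 0.5,
    },
    "grid": {
        "kind": "default",  # default | coarse | explicit
        "v_thresh_values": None,
        "w_values": None,
    },
    "model": {
        "form": "additive",
        "reference_level": None,
        "include_blocks": False,
    },
    "censoring": {
        "policy": "end_of_record",
        "max_censored_frac": 0.1,
    },
    "simulate": {
        "preset": "calibration",
        "n_per_treatment": 315,
        "overrides": {},
    },
    "io": {
        "delimiter": ",",
        "sample_rate": None,  # expected rate cross-check, optional
    },
    "optimize": {
        "workers": 1,
        "max_plot_v_thresh": None,
    },
}


def deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    """Recursive dict merge; override values win, nested dicts merge."""
    out = copy.deepcopy(dict(base))
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Defaults merged with an optional YAML config file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config file must hold a mapping")
        cfg = deep_merge(cfg, loaded)
    return cfg


def echo_config(cfg: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Write the effective configuration next to the outputs it produced."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "config_echo.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True, default_flow_style=False)
    return path
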