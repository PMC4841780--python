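"""Declarative YAML configuration for the pipeline.

A single config file names the inputs (or a simulation spec), the output
directory and every stage parameter.  Unknown keys are errors; every
default is echoed into the run log so a report is auditable without the
config in hand.
"""

from __future__ import annotations

from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "seed": None,              # auto-generated (and logged) when omitted
    "output_dir": None,        # required
    "simulate": {
        "n_queries": 1000,
        "n_targets": 1,
        "noise_sigma": 0.2,
        "n_spis": 20,
        "effect_min": 0.3,
        "effect_max": 0.7,
        "gradient_coeffs": None,
        "controls_per_plate": 0,
        "base_size": 200.0,
    },
    "inputs": {                # alternative to `simulate`
        "fusion": None,
        "control_target_only": None,
        "control_gbp_only": None,
        "layout_dir": None,
    },
    "normalize": {"mode": "plate_median"},
    "score": {"min_finite": 30},
    "smoothing": {"window": 3, "statistic": "median"},
    "retest": {
        "max_candidates": 80,
        "batch_size": 20,
        "stop_fdr": 0.40,
        "tau": 0.15,
        "alpha": 0.05,
        "require": "both",
        "replicate_count": 16,
        "controls_per_plate": 16,
        "noise_sigma": 0.2,
    },
    "cluster": {"enabled": "auto"},  # auto: cluster when >= 3 targets
}


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        if isinstance(default, dict) and key in given and isinstance(given[key], dict):
            out[key] = _merge(default, given[key], f"{path}{key}.")
        elif key in given:
            out[key] = given[key]
        else:
            out[key] = default
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(path + k for k in unknown)}")
    return out


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML config, merging defaults for omitted keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    cfg = _merge(DEFAULTS, raw)
    if cfg["output_dir"] is None:
        raise ConfigError("config must set output_dir")
    return cfg


def flatten(cfg: dict, prefix: str = "") -> list[tuple[str, object]]:
    """Flatten a nested config to sorted (dotted.key, value) pairs for logging."""
    items: list[tuple[str, object]] = []
    for key in sorted(cfg):
        value = cfg[key]
        if isinstance(value, dict):
            items.extend(flatten(value, f"{prefix}{key}."))
        else:
            items.append((f"{prefix}{key}", value))
    return items
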