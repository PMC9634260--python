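"""Experiment configuration: YAML schema, validation and seed management.

A single global seed expands deterministically into independent
per-component seeds (weight initialization, epoch shuffling, Poisson
sampling, noise injection), so any one source of randomness can be varied
without disturbing the others.  A resolved copy of the configuration is
written into every run directory, which makes deterministic runs
bit-reproducible from the saved file alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .neurons import ConfigurationError

__all__ = ["load_config", "resolve_config", "component_seed", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "seeds": None,  # list of run seeds; defaults to [seed]
    "outdir": "results",
    "synthetic": {
        "n_classes": 5, "height": 10, "width": 10, "fg_intensity": 255,
        "flip_prob": 0.1, "n_train": 3000, "n_test": 1000, "seed": 0,
    },
    "network": {
        "n_out": 30, "rule": "vdsp", "lr": 5e-2, "inc_n": 0.01,
        "out_gain": 4.0, "epochs": 1,
    },
    "encoder": {
        "mode": "constant_current", "current_scale": 1.0,
        "poisson_max_rate": 60.0, "noise_sigma": 0.0,
    },
    "window": {
        "currents": [1.5, 2.0, 3.0, 5.0], "lr": 1e-3, "w0": 0.5,
        "dt": 0.05, "t_ref": 2.0,
    },
    "equivalence": {
        "currents": [1.5, 2.0, 4.0], "dt": 0.01, "n_obs": 1000,
        "duration": 2000.0,
    },
    "freq": {
        "scales": [0.5, 1.0, 2.0, 4.0], "rules": ["vdsp", "stdp"],
        "base_current_scale": 1.0, "n_out": 10,
    },
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    bad = []
    for key, value in user.items():
        if key not in defaults:
            bad.append(f"{path}{key}")
            continue
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    if bad:
        raise ConfigurationError(f"unknown configuration keys: {', '.join(bad)}")
    return out


def resolve_config(user: dict | None) -> dict:
    """Merge a user configuration over the defaults, rejecting unknown keys."""
    cfg = _merge(DEFAULTS, user or {})
    if cfg["seeds"] is None:
        cfg["seeds"] = [cfg["seed"]]
    return cfg


def load_config(path: str | Path | None) -> dict:
    """Load and validate a YAML experiment configuration."""
    if path is None:
        return resolve_config({})
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigurationError("configuration file must contain a mapping")
    return resolve_config(user)


def component_seed(run_seed: int, component: str) -> int:
    """Deterministic per-component seed below 2**31 derived from the run seed."""
    ss = np.random.SeedSequence([int(run_seed), abs(hash_component(component))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def hash_component(name: str) -> int:
    """Stable (process-independent) small integer hash of a component name."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


def dump_resolved(cfg: dict, outdir: Path) -> None:
    """Write the exact resolved configuration into the run directory."""
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.resolved.json").write_text(json.dumps(cfg, indent=2))
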