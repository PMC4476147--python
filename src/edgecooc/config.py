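"""Pipeline configuration: YAML-serializable, hashed into every artifact.

A run is fully determined by its config plus its inputs and seeds; the
short hash of the canonicalized config is stamped into edge-list sidecars
and histogram files so that downstream stages can refuse to mix artifacts
produced under incompatible settings (different binning, bank, ...).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .cooccurrence import Binning, default_binning
from .filterbank import FilterParams

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "config_hash",
    "make_filter_params",
    "make_binning",
]


def default_config() -> dict:
    return {
        "filterbank": {
            "n_orientations": 8,
            "n_scales": 5,
            "base_frequency": 0.25,
            "scale_ratio": 2.0,
            "bandwidth_freq": 0.4,
            "bandwidth_theta": float(np.pi / 16),
            "dtype": "complex128",
        },
        "sparse": {"n_edges": 2048, "residual_target": 0.05},
        "mask": {"radius_fraction": 0.45},
        "binning": {
            "n_d": 6,
            "d_min": 2.0,
            "n_psi": 12,
            "n_theta": 12,
            "n_sigma": 5,
            "sigma_max": 2.0,
            "normalize_distance": False,
            "weighting": "amplitude",
        },
        "classify": {"n_resamples": 20, "test_size": 0.2, "C": 10.0, "noise_snr": 1.0},
        "seed": 0,
    }


def load_config(path: Optional[str | Path]) -> dict:
    """Load a YAML config, filling unspecified fields from the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if isinstance(values, dict):
            unknown = set(values) - set(cfg[section])
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Short stable hash of the analysis-relevant sections (bank, sparse
    coding, mask, binning) — the parts that determine whether two
    histogram artifacts are comparable."""
    relevant = {k: copy.deepcopy(cfg[k]) for k in ("filterbank", "sparse", "mask", "binning")}
    relevant["filterbank"].pop("dtype", None)  # numerical precision, not semantics
    blob = json.dumps(relevant, sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def make_filter_params(cfg: dict, image_shape: Tuple[int, int]) -> FilterParams:
    fb = cfg["filterbank"]
    return FilterParams(image_shape=tuple(image_shape), **fb)


def make_binning(cfg: dict, mask_radius: float) -> Binning:
    b = dict(cfg["binning"])
    b.pop("weighting", None)
    return default_binning(mask_radius, **b)
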