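"""Structured run configuration: YAML/JSON parsing, validation, seed expansion.

A run configuration is a mapping with optional blocks ``model``, ``train``,
``window``, ``augment``, ``weights``, ``loss`` and ``phantom``, each feeding
the corresponding dataclass.  Unknown fields raise errors naming the field.
All randomness flows from one top-level ``seed``, expanded into per-component
child seeds with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import yaml

from .augmentation import AugmentConfig
from .model_zoo import ModelConfig
from .synthetic import PhantomConfig
from .training import LossParams, TrainConfig
from .weight_maps import EdgeWeightParams
from .windowing import WindowSpec

_TUPLE_FIELDS = {
    "shape",
    "encoder_channels",
    "crop_margin",
    "input_shape",
    "output_shape",
    "spacing",
    "flip_axes",
    "elastic_grid",
    "voxel_size_nm",
}
_INT_KEY_DICTS = {"organelle_density", "intensity_means"}

BLOCK_TYPES = {
    "model": ModelConfig,
    "train": TrainConfig,
    "window": WindowSpec,
    "augment": AugmentConfig,
    "weights": EdgeWeightParams,
    "loss": LossParams,
    "phantom": PhantomConfig,
}


def load_config(path: str) -> dict:
    """Read a YAML (or JSON) configuration file into a dict."""
    with open(path) as f:
        text = f.read()
    cfg = yaml.safe_load(text)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def build_block(name: str, values: dict | None, **overrides):
    """Instantiate one config dataclass with field-level validation messages."""
    cls = BLOCK_TYPES[name]
    values = dict(values or {})
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(cls)}
    for key in values:
        if key not in known:
            raise ValueError(f"unknown field {key!r} in config block {name!r}")
    coerced = {}
    for key, val in values.items():
        if key in _TUPLE_FIELDS and isinstance(val, (list, tuple)):
            coerced[key] = tuple(val)
        elif key in _INT_KEY_DICTS and isinstance(val, dict):
            coerced[key] = {int(k): float(v) for k, v in val.items()}
        elif key == "window_spec" and isinstance(val, dict):
            coerced[key] = build_block("window", val)
        elif key == "augment" and isinstance(val, dict):
            coerced[key] = build_block("augment", val)
        elif key == "class_sets" and isinstance(val, dict):
            coerced[key] = {k: frozenset(v) for k, v in val.items()}
        else:
            coerced[key] = val
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config block {name!r}: {exc}") from exc


def expand_seed(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2^31) from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def config_to_json(obj) -> str:
    """Serialize a config dataclass (or dict of them) for provenance sidecars."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (frozenset, set)):
            return sorted(o)
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        raise TypeError(f"cannot serialize {type(o).__name__}")

    return json.dumps(obj, default=default, indent=2, sort_keys=True)
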