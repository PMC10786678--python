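"""TOML run configuration with validated defaults.

Sections and keys::

    [input]   path | id | cache_dir
    [model]   kind ("uenm") | cutoff (15 for anm, 7.5 otherwise)
              | gamma (1.0) | f_anm (0.5) | beta_bb (10.0)
    [nma]     n_modes (200) | rigid_tol (1e-8)
    [qrc]     cluster_min (4) | cluster_max (100) | method ("discretize")
              | seed (0) | pair_radius (2x cutoff) | dense_pairs (false)
              | kernel_bandwidth_factor (1.0) | force_k
    [output]  dir ("shellmech_out")

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict

from .elastic_models import DEFAULT_CUTOFF, MODEL_KINDS

__all__ = ["RunConfig", "ConfigError", "load_config", "load_config_file"]


class ConfigError(Exception):
    """Invalid run configuration; the message names the offending key."""


@dataclass
class RunConfig:
    input_path: str | None = None
    input_id: str | None = None
    cache_dir: str = "."
    model_kind: str = "uenm"
    cutoff: float | None = None
    gamma: float = 1.0
    f_anm: float = 0.5
    beta_bb: float = 10.0
    n_modes: int = 200
    rigid_tol: float = 1e-8
    cluster_min: int = 4
    cluster_max: int = 100
    method: str = "discretize"
    seed: int = 0
    pair_radius: float | None = None
    dense_pairs: bool = False
    kernel_bandwidth_factor: float = 1.0
    force_k: int | None = None
    output_dir: str = "shellmech_out"

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ConfigError(f"model.kind: unknown model {self.model_kind!r}")
        if self.cutoff is None:
            self.cutoff = DEFAULT_CUTOFF[self.model_kind]
        if self.cutoff <= 0:
            raise ConfigError("model.cutoff: must be positive")
        if self.gamma <= 0:
            raise ConfigError("model.gamma: must be positive")
        if not 0.0 <= self.f_anm <= 1.0:
            raise ConfigError("model.f_anm: must lie in [0, 1]")
        if self.beta_bb < 1.0:
            raise ConfigError("model.beta_bb: must be >= 1")
        if self.n_modes < 1:
            raise ConfigError("nma.n_modes: must be >= 1")
        if self.rigid_tol <= 0:
            raise ConfigError("nma.rigid_tol: must be positive")
        if self.cluster_min < 2:
            raise ConfigError("qrc.cluster_min: must be >= 2")
        if self.cluster_max < self.cluster_min:
            raise ConfigError("qrc.cluster_max: must be >= qrc.cluster_min")
        if self.method not in ("discretize", "kmeans"):
            raise ConfigError(f"qrc.method: unknown method {self.method!r}")
        if self.pair_radius is None:
            self.pair_radius = 2.0 * self.cutoff
        if self.pair_radius <= 0:
            raise ConfigError("qrc.pair_radius: must be positive")
        if self.kernel_bandwidth_factor <= 0:
            raise ConfigError("qrc.kernel_bandwidth_factor: must be positive")
        if self.force_k is not None and not (
            self.cluster_min <= self.force_k <= self.cluster_max
        ):
            raise ConfigError("qrc.force_k: must lie within [cluster_min, cluster_max]")

    def as_dict(self) -> dict:
        return asdict(self)


_SCHEMA: dict[str, dict[str, str]] = {
    "input": {"path": "input_path", "id": "input_id", "cache_dir": "cache_dir"},
    "model": {
        "kind": "model_kind",
        "cutoff": "cutoff",
        "gamma": "gamma",
        "f_anm": "f_anm",
        "beta_bb": "beta_bb",
    },
    "nma": {"n_modes": "n_modes", "rigid_tol": "rigid_tol"},
    "qrc": {
        "cluster_min": "cluster_min",
        "cluster_max": "cluster_max",
        "method": "method",
        "seed": "seed",
        "pair_radius": "pair_radius",
        "dense_pairs": "dense_pairs",
        "kernel_bandwidth_factor": "kernel_bandwidth_factor",
        "force_k": "force_k",
    },
    "output": {"dir": "output_dir"},
}

_TYPES: dict[str, tuple] = {
    "input_path": (str,),
    "input_id": (str,),
    "cache_dir": (str,),
    "model_kind": (str,),
    "cutoff": (int, float),
    "gamma": (int, float),
    "f_anm": (int, float),
    "beta_bb": (int, float),
    "n_modes": (int,),
    "rigid_tol": (int, float),
    "cluster_min": (int,),
    "cluster_max": (int,),
    "method": (str,),
    "seed": (int,),
    "pair_radius": (int, float),
    "dense_pairs": (bool,),
    "kernel_bandwidth_factor": (int, float),
    "force_k": (int,),
    "output_dir": (str,),
}


def load_config(text: str) -> RunConfig:
    """Parse TOML text into a validated :class:`RunConfig` with defaults."""
    try:
        raw = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML: {exc}") from exc

    kwargs: dict = {}
    for section, table in raw.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section [{section}]")
        if not isinstance(table, dict):
            raise ConfigError(f"[{section}] must be a table")
        for key, value in table.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown config key {section}.{key}")
            attr = _SCHEMA[section][key]
            expected = _TYPES[attr]
            if isinstance(value, bool) and bool not in expected:
                raise ConfigError(f"{section}.{key}: expected {expected[0].__name__}")
            if not isinstance(value, expected):
                raise ConfigError(
                    f"{section}.{key}: expected {expected[0].__name__}, "
                    f"got {type(value).__name__}"
                )
            kwargs[attr] = float(value) if expected == (int, float) else value
    return RunConfig(**kwargs)


def load_config_file(path) -> RunConfig:
    with open(path, "r") as fh:
        return load_config(fh.read())
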