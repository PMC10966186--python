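"""Pipeline configuration with published defaults.

Flat dotted keys (``logistic.threshold``) or nested YAML mappings are both
accepted; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .logistic import LogisticModel

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    logistic: LogisticModel = field(default_factory=LogisticModel)
    #: extra time (Myr) added above the root for the 'equal' algorithm
    root_buffer: float = 10.0
    #: minimum branch duration (Myr) for the 'mbl' algorithm
    min_len: float = 1.0
    #: Mk model form: "ER" or "ARD"
    mk_model: str = "ER"
    #: Mk root prior: "flat" or "stationary"
    root_prior: str = "flat"
    #: repetitions per dating algorithm
    reps: int = 100
    #: base RNG seed; repetition r uses seed + r
    seed: int = 0

    def with_updates(self, **kwargs: Any) -> "PipelineConfig":
        return replace(self, **kwargs)


_LOGISTIC_KEYS = {"coefficient", "intercept", "threshold"}
_TOP_KEYS = {"root_buffer", "min_len", "mk_model", "root_prior", "reps", "seed"}


def _flatten(mapping: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, value in mapping.items():
        full = f"{prefix}{key}"
        if isinstance(value, Mapping):
            out.update(_flatten(value, prefix=f"{full}."))
        else:
            out[full] = value
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Build a config from an optional YAML file plus dotted overrides."""
    flat: dict[str, Any] = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: config must be a mapping")
        flat.update(_flatten(data))
    if overrides:
        flat.update(_flatten(dict(overrides)))

    logi: dict[str, float] = {}
    top: dict[str, Any] = {}
    for key, value in flat.items():
        if key.startswith("logistic."):
            sub = key.split(".", 1)[1]
            if sub not in _LOGISTIC_KEYS:
                raise ValueError(f"unknown config key {key!r}")
            logi[sub] = float(value)
        elif key in _TOP_KEYS:
            top[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")

    cfg = PipelineConfig(logistic=LogisticModel(**logi), **top)
    if cfg.reps < 1:
        raise ValueError("reps must be >= 1")
    return cfg
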