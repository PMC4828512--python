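"""Run configuration: YAML-backed, validated, round-trippable.

Defaults mirror the selected operating point of the method: T = 150 boosting
rounds, learning rate 0.1, target minority percentage N = 50%, depth-3 trees,
a 2x2x2 rVOI dilation kernel and 8 GLCM gray levels.  The plain-Adaboost
preset is the same loop with undersampling disabled and T = 400.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .errors import InvalidArgumentError
from .phantom import PhantomSpec

__all__ = ["BoostingConfig", "FeatureConfig", "VoiConfig", "CVConfig",
           "RunConfig", "load_config", "dump_config"]


@dataclass
class BoostingConfig:
    T: int = 150
    N: float = 0.5
    eta: float = 0.1
    max_depth: int = 3
    eps_floor: float = 1e-10
    rus_enabled: bool = True

    def __post_init__(self):
        if self.T < 1:
            raise InvalidArgumentError("T must be >= 1")
        if not (0.0 < self.N <= 1.0):
            raise InvalidArgumentError("N must be in (0, 1]")
        if not (0.0 < self.eta <= 1.0):
            raise InvalidArgumentError("eta must be in (0, 1]")
        if self.max_depth < 1:
            raise InvalidArgumentError("max_depth must be >= 1")


@dataclass
class FeatureConfig:
    glcm_levels: int = 8

    def __post_init__(self):
        if self.glcm_levels < 2:
            raise InvalidArgumentError("glcm_levels must be >= 2")


@dataclass
class VoiConfig:
    dilation_kernel: Tuple[int, int, int] = (2, 2, 2)
    box_origin: Optional[Tuple[int, int, int]] = None

    def __post_init__(self):
        self.dilation_kernel = tuple(int(k) for k in self.dilation_kernel)
        if any(k < 1 for k in self.dilation_kernel):
            raise InvalidArgumentError("dilation kernel entries must be >= 1")
        if self.box_origin is not None:
            self.box_origin = tuple(int(o) for o in self.box_origin)


@dataclass
class CVConfig:
    m: int = 10
    rounds: int = 10
    max_voxels_per_subject: Optional[int] = None

    def __post_init__(self):
        if self.m < 1 or self.rounds < 1:
            raise InvalidArgumentError("m and rounds must be >= 1")


@dataclass
class RunConfig:
    boosting: BoostingConfig = field(default_factory=BoostingConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    voi: VoiConfig = field(default_factory=VoiConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0
    side: str = "left"

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise InvalidArgumentError("side must be 'left' or 'right'")


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidArgumentError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML path, YAML string, or dict."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, str):
        data = yaml.safe_load(source) or {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        raise InvalidArgumentError(f"cannot load config from {type(source)}")
    sections = {
        "boosting": BoostingConfig,
        "features": FeatureConfig,
        "voi": VoiConfig,
        "cv": CVConfig,
        "phantom": PhantomSpec,
    }
    unknown = set(data) - set(sections) - {"seed", "side"}
    if unknown:
        raise InvalidArgumentError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {
        name: _build(cls, data.get(name, {}) or {}) for name, cls in sections.items()
    }
    return RunConfig(seed=int(data.get("seed", 0)),
                     side=data.get("side", "left"), **kwargs)


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialise the fully resolved config to YAML (and optionally a file)."""

    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [plain(x) for x in obj]
        return obj

    text = yaml.safe_dump(plain(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
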