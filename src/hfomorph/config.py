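"""Run configuration: nested parameter bundle loadable from YAML.

Unknown keys are rejected so typos in config files fail loudly instead of
silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .classifier import DEFAULT_SWEEP_MS, MorphParams
from .staba import DetectorParams

__all__ = ["CVConfig", "IOConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class CVConfig:
    n_repeats: int = 10
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class IOConfig:
    input: str | None = None
    events: str | None = None
    output_dir: str = "."


@dataclass(frozen=True)
class RunConfig:
    detector: DetectorParams = field(default_factory=DetectorParams)
    morph: MorphParams = field(default_factory=MorphParams)
    sweep_windows_ms: tuple[float, ...] = DEFAULT_SWEEP_MS
    cv: CVConfig = field(default_factory=CVConfig)
    io: IOConfig = field(default_factory=IOConfig)


def _build(cls, mapping: Mapping[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {unknown}")
    kwargs = dict(mapping)
    if cls is DetectorParams and "band" in kwargs:
        kwargs["band"] = tuple(kwargs["band"])
    return cls(**kwargs)


def config_from_mapping(mapping: Mapping[str, Any]) -> RunConfig:
    known = {"detector", "morph", "sweep_windows_ms", "cv", "io"}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ValueError(f"unknown RunConfig keys: {unknown}")
    return RunConfig(
        detector=_build(DetectorParams, mapping.get("detector", {})),
        morph=_build(MorphParams, mapping.get("morph", {})),
        sweep_windows_ms=tuple(mapping.get("sweep_windows_ms", DEFAULT_SWEEP_MS)),
        cv=_build(CVConfig, mapping.get("cv", {})),
        io=_build(IOConfig, mapping.get("io", {})),
    )


def load_config(path: str | Path | None) -> RunConfig:
    """YAML file -> RunConfig; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_mapping(data)
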