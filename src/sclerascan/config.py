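"""Run configuration: dataclass defaults, YAML loading, serialization.

Every tunable of the pipeline lives here so that a run's effective
configuration can be embedded verbatim in its output report. YAML keys
mirror the module structure::

    compensation: {method: shades_of_gray, minkowski_p: 6.0}
    denoise:      {kernel: 3}
    segmentation: {sclera_l_min: ..., margin: ...}
    mask:         {s_min: ..., l_min: ..., l_max: ..., min_pixels: ...}
    histogram:    {bin_width: 1.0}
    model:        {cutoff_mhd: 40.8, peak_mhd: 56.3, ...}
    seed:         0
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, ParameterError, SclerascanError
from .model import ModelParams
from .segmentation import MaskParams, SegmentationParams

__all__ = ["CompensationConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class CompensationConfig:
    method: str = "shades_of_gray"  # shades_of_gray | gray_world
    minkowski_p: float = 6.0


@dataclass(frozen=True)
class RunConfig:
    compensation: CompensationConfig = field(default_factory=CompensationConfig)
    denoise_kernel: int = 3
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    mask: MaskParams = field(default_factory=MaskParams)
    bin_width: float = 1.0
    model: ModelParams = field(default_factory=ModelParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["denoise"] = {"kernel": d.pop("denoise_kernel")}
        d["histogram"] = {"bin_width": d.pop("bin_width")}
        return d


_SECTIONS = {
    "compensation": (CompensationConfig, "compensation"),
    "segmentation": (SegmentationParams, "segmentation"),
    "mask": (MaskParams, "mask"),
    "model": (ModelParams, "model"),
}


def _build(cls, section: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"unknown {name} option(s): {sorted(unknown)}")
    try:
        return cls(**section)
    except (ParameterError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name} configuration: {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file and/or apply a nested override mapping."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        try:
            loaded = yaml.safe_load(path.read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config {path} must be a mapping")
            data = loaded
    for k, v in (overrides or {}).items():
        if isinstance(v, dict):
            data.setdefault(k, {}).update(v)
        else:
            data[k] = v

    known = set(_SECTIONS) | {"denoise", "histogram", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    kwargs: dict = {}
    for key, (cls, attr) in _SECTIONS.items():
        if key in data:
            section = data[key]
            if not isinstance(section, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            kwargs[attr] = _build(cls, section, key)
    if "denoise" in data:
        kwargs["denoise_kernel"] = int(data["denoise"].get("kernel", 3))
    if "histogram" in data:
        kwargs["bin_width"] = float(data["histogram"].get("bin_width", 1.0))
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    try:
        return RunConfig(**kwargs)
    except SclerascanError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
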