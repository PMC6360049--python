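"""Study configuration: schema, validation, YAML loading, provenance hash.

A single config object drives the full pipeline (phantom -> simulate ->
reconstruct -> IDIF -> report) so that a study is reproducible from one
file plus a seed. Unknown keys are rejected rather than ignored — silent
typos in a config are the classic way to lose a week.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .acquisition import (DEFAULT_COUNTS_SCALE, DEFAULT_RANDOMS_FRACTION,
                          DEFAULT_SCATTER_FRACTION, DEFAULT_SCATTER_WIDTH_BINS)
from .kernel import KernelParams
from .phantom import DEFAULT_FRAME_SPEC, PhantomConfig

__all__ = ["GeometryConfig", "AcquisitionConfig", "ReconConfig", "IdifConfig",
           "StudyConfig", "config_hash"]


@dataclass(frozen=True)
class GeometryConfig:
    n_angles: int = 96
    ray_step_fraction: float = 0.5


@dataclass(frozen=True)
class AcquisitionConfig:
    n_realisations: int = 10
    base_seed: int = 1
    counts_scale: float = DEFAULT_COUNTS_SCALE
    randoms_fraction: float = DEFAULT_RANDOMS_FRACTION
    scatter_fraction: float = DEFAULT_SCATTER_FRACTION
    scatter_width_bins: float = DEFAULT_SCATTER_WIDTH_BINS
    randoms_reference: str = "trues"


@dataclass(frozen=True)
class ReconConfig:
    algorithms: tuple[str, ...] = ("osem", "osem-g", "kem", "hkem")
    n_subsets: int = 21
    n_iterations: int = 10
    postfilter_fwhm_mm: float = 3.0
    kernel: KernelParams = field(default_factory=KernelParams)


@dataclass(frozen=True)
class IdifConfig:
    threshold_fraction: float = 0.75
    roi_source: str = "self"  # self | hkem | truth


@dataclass(frozen=True)
class StudyConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    idif: IdifConfig = field(default_factory=IdifConfig)
    frame_spec: tuple[tuple[int, float], ...] = tuple(
        (c, d) for c, d in DEFAULT_FRAME_SPEC
    )

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        return _from_dict(cls, raw, "study")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return _to_jsonable(dataclasses.asdict(self))


_NESTED = {
    "phantom": PhantomConfig,
    "geometry": GeometryConfig,
    "acquisition": AcquisitionConfig,
    "recon": ReconConfig,
    "idif": IdifConfig,
    "kernel": KernelParams,
}


def _from_dict(cls, raw: dict, context: str):
    if not isinstance(raw, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(raw).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        if name in _NESTED and isinstance(value, dict):
            kwargs[name] = _from_dict(_NESTED[name], value, f"{context}.{name}")
        elif name in ("algorithms",):
            kwargs[name] = tuple(value)
        elif name == "frame_spec":
            kwargs[name] = tuple((int(c), float(d)) for c, d in value)
        elif name in ("aorta_offset_mm", "kidney_offset_mm", "stomach_offset_mm"):
            kwargs[name] = tuple(float(v) for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_hash(config: StudyConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
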