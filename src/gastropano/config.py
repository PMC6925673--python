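"""Run configuration: YAML schema, validation, provenance records.

Every stage reads its parameters from one nested mapping; unknown keys
are rejected so a typo cannot silently fall back to a default, and the
resolved configuration is echoed into a ``run.json`` provenance record
next to every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class SceneConfig:
    edge_mm: float = 60.0
    tex_pitch: float = 3.0
    n_vessels: int = 6
    polyps: list = field(default_factory=list)  # [{face, center_uv, radius_mm, amplitude}]


@dataclass
class CameraConfig:
    fx: float = 130.0
    fy: float = 130.0
    cx: float = 79.5
    cy: float = 59.5
    width: int = 160
    height: int = 120
    k: list = field(default_factory=lambda: [0.0, 0.0, 0.0, 0.0])
    distortion: str = "none"


@dataclass
class TrajectoryConfig:
    face_id: str = "A-y"
    n_frames: int = 9
    distance_mm: float = 25.0
    u_range: list = field(default_factory=lambda: [0.35, 0.65])
    v_center: float = 0.5


@dataclass
class RenderConfig:
    noise_scalar: float = 0.0
    specular_count: int = 0


@dataclass
class RegistrationSection:
    max_features: int = 200
    ratio: float = 0.8
    ransac_iters: int = 500
    ransac_px: float = 2.0
    kl_threshold: float = 0.15
    min_patch_px: int = 16
    max_depth: int = 4
    reproj_px: float = 2.0
    c_dog: float = 0.004
    detect_sigma: float = 0.0


@dataclass
class ChainSection:
    reproj_px: float = 2.0
    max_rounds: int = 10
    model: str = "similarity"


@dataclass
class FusionSection:
    beta: float = 1e-3
    max_alt_iters: int = 10
    tol: float = 1e-6
    stride: int = 2
    literal_regularizer: bool = False


@dataclass
class ProjectionSection:
    pitch: float = 2.0
    gutter_px: int = 2


@dataclass
class DetectionSection:
    channels: int = 12
    scales: list = field(default_factory=lambda: [10.0, 18.0])
    ratio: float = 3.0
    mining: str = "selective"
    epochs: int = 20
    lr: float = 2e-3
    conf_threshold: float = 0.5
    nms_iou: float = 0.5


@dataclass
class RunConfig:
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    registration: RegistrationSection = field(default_factory=RegistrationSection)
    chain: ChainSection = field(default_factory=ChainSection)
    fusion: FusionSection = field(default_factory=FusionSection)
    projection: ProjectionSection = field(default_factory=ProjectionSection)
    detection: DetectionSection = field(default_factory=DetectionSection)
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def write_provenance(self, out_dir) -> None:
        from . import __version__

        rec = {
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            "gastropano_version": __version__,
            "seed": self.seed,
        }
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "run.json").write_text(json.dumps(rec, indent=1))


_SECTIONS = {
    "scene": SceneConfig,
    "camera": CameraConfig,
    "trajectory": TrajectoryConfig,
    "render": RenderConfig,
    "registration": RegistrationSection,
    "chain": ChainSection,
    "fusion": FusionSection,
    "projection": ProjectionSection,
    "detection": DetectionSection,
}


def _build_section(cls, data: dict, path: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {path}: {sorted(unknown)}")
    return cls(**data)


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a YAML run configuration (strict keys)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(path_or_dict or {})
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    top_allowed = set(_SECTIONS) | {"seed", "schema_version"}
    unknown = set(data) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if int(data.get("schema_version", SCHEMA_VERSION)) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version (expected {SCHEMA_VERSION})")
    kwargs = {"seed": int(data.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        sect = data.get(name, {})
        if not isinstance(sect, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, sect, name)
    return RunConfig(**kwargs)
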