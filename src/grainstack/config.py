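"""Pipeline configuration: schema, defaults, YAML round-trip.

Every default mirrors the protocol's stated value where one exists: DoG
sigmas 0.7/2 (pixels), threshold step 25 intensity units, grain gate
0.03-0.1 um^3, >= 20 grains (60x rule), >= 10 clusters (20x rule), counting
frames ~68 x 68 um at 60x and ~250 x 250 um at 20x.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import AcquisitionGeometry, preset_20x, preset_60x
from .segmentation import DoGParams, GateParams
from .synthetic import SimParams

__all__ = ["PipelineConfig", "DEFAULT_FRAME_UM"]

DEFAULT_FRAME_UM = {"60x": 68.0, "20x": 250.0}


@dataclass
class PipelineConfig:
    """End-to-end study configuration."""

    geometry_preset: str = "60x"  # "60x" | "20x" | "custom"
    n_xy: int = 1024
    n_z: int = 57
    custom_geometry: dict | None = None  # AcquisitionGeometry kwargs if "custom"

    dog: DoGParams = field(default_factory=DoGParams)
    gate: GateParams = field(default_factory=GateParams)
    connectivity: int = 26
    lipofuscin_on_dog: bool = True

    frame_width_um: float | None = None  # default chosen by preset
    frame_height_um: float | None = None
    exclusion_edges: tuple[str, str] = ("left", "bottom")

    min_grains: int = 20  # 60x classification rule
    min_clusters: int = 10  # 20x classification rule
    cluster_link_radius_um: float = 1.5
    min_z_planes: int = 3
    classification_mode: str | None = None  # default: follow the preset

    covariates: tuple[str, ...] = ("pmi", "rin", "ph")
    reference_group: str = "young"
    alpha: float = 0.05

    sim: SimParams = field(default_factory=SimParams)
    n_per_group: int = 5
    n_stacks: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry_preset not in ("60x", "20x", "custom"):
            raise ValueError(f"unknown geometry preset {self.geometry_preset!r}")
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")
        if self.classification_mode not in (None, "60x", "20x"):
            raise ValueError(f"classification_mode must be '60x' or '20x'")

    # -- derived ------------------------------------------------------------
    def geometry(self) -> AcquisitionGeometry:
        if self.geometry_preset == "60x":
            return preset_60x(self.n_xy, self.n_z)
        if self.geometry_preset == "20x":
            return preset_20x(self.n_xy, self.n_z)
        return AcquisitionGeometry(**(self.custom_geometry or {}))

    def frame_size_um(self) -> tuple[float, float]:
        default = DEFAULT_FRAME_UM.get(self.geometry_preset, 68.0)
        geom = self.geometry()

        def fit(default_um: float, field_um: float) -> float:
            # shrink only when the nominal frame cannot sit inside the field
            return default_um if default_um <= field_um - 1.0 else 0.75 * field_um

        w = self.frame_width_um if self.frame_width_um is not None else fit(default, geom.field_x_um)
        h = self.frame_height_um if self.frame_height_um is not None else fit(default, geom.field_y_um)
        return w, h

    def mode(self) -> str:
        if self.classification_mode is not None:
            return self.classification_mode
        return "20x" if self.geometry_preset == "20x" else "60x"

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dog"] = dataclasses.asdict(self.dog)
        d["gate"] = dataclasses.asdict(self.gate)
        d["sim"] = dataclasses.asdict(self.sim)
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "dog" in d and isinstance(d["dog"], dict):
            d["dog"] = DoGParams(**d["dog"])
        if "gate" in d and isinstance(d["gate"], dict):
            d["gate"] = GateParams(**d["gate"])
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            for key in ("grain_volume_range", "lipofuscin_volume_range", "group_effects"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["sim"] = SimParams(**sim)
        for key in ("exclusion_edges", "covariates"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
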