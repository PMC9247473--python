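"""Configuration schema for the end-to-end pipeline.

One config drives everything: geometry of the synthetic buckle, analysis
constants, composition, sorting-model slopes and seeds.  Files may be TOML
(read via tomllib), YAML or JSON; unknown keys are rejected and a config
round-trips losslessly through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core_model import Composition, CompositionEntry, LEAFLETS
from .errors import ConfigError
from .species import (
    default_registry,
    plasma_membrane_composition,
    symmetric_composition,
)
from .synthetic import SortingModel


@dataclass
class GeometryConfig:
    """Synthetic membrane geometry (all lengths nm)."""

    x0: float = 40.0          # unbuckled box length along x
    gamma: float = 0.1        # compressional strain
    ly: float = 20.0
    lz: float = 20.0
    d_half: float = 2.0       # leaflet offset from the midplane
    sigma_z: float = 0.3      # headgroup placement noise
    bead_spacing: float = 0.3


@dataclass
class AnalysisConfig:
    """Fixed analysis constants."""

    bin_width: float = 0.05        # curvature bin width, 1/nm
    occupancy_frac: float = 0.05   # low-occupancy mask threshold
    n_blocks: int = 4
    contact_cutoff: float = 1.0    # nm
    extreme_threshold: float = 0.1 # 1/nm
    x_bin: float = 1.0             # localization bin width, nm
    roughness: float = 0.5         # spline roughness scale, nm
    leaflet_bin: float = 2.0       # leaflet-assignment x bin, nm


@dataclass
class PipelineConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    composition: str | dict = "plasma_membrane"
    slopes: dict[str, float] = field(default_factory=dict)
    headgroup_beads: dict[str, str] = field(default_factory=dict)
    seed: int = 1
    n_frames: int = 100

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        cfg = cls()
        for section, klass in (("geometry", GeometryConfig),
                               ("analysis", AnalysisConfig)):
            if section in data:
                sub = data.pop(section)
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(sub) - known
                if unknown:
                    raise ConfigError(
                        f"unknown {section} keys: {sorted(unknown)}")
                setattr(cfg, section, klass(**sub))
        known = {f.name for f in dataclasses.fields(cls)} - {"geometry", "analysis"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, val in data.items():
            setattr(cfg, key, val)
        for key in cfg.slopes:
            if ":" not in key or key.split(":", 1)[0] not in LEAFLETS:
                raise ConfigError(
                    f"slope key {key!r} must look like 'leaflet:SPECIES'")
        return cfg

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "analysis": dataclasses.asdict(self.analysis),
            "composition": self.composition,
            "slopes": dict(self.slopes),
            "headgroup_beads": dict(self.headgroup_beads),
            "seed": self.seed,
            "n_frames": self.n_frames,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    # -- derived objects ---------------------------------------------------

    def build_registry(self):
        reg = default_registry()
        for name, bead in self.headgroup_beads.items():
            if name not in reg:
                raise ConfigError(f"headgroup override for unknown species {name!r}")
            reg[name] = dataclasses.replace(reg[name], headgroup_bead=bead)
        return reg

    def build_composition(self) -> Composition:
        if self.composition == "plasma_membrane":
            return plasma_membrane_composition()
        if self.composition == "symmetric":
            return symmetric_composition()
        if isinstance(self.composition, dict):
            leaflets = {}
            for leaflet, entries in self.composition.items():
                leaflets[leaflet] = tuple(
                    CompositionEntry(
                        species=e["species"],
                        fraction=e.get("fraction"),
                        count=e.get("count"),
                    ) for e in entries
                )
            return Composition(leaflets=leaflets)
        raise ConfigError(f"unknown composition {self.composition!r}")

    def build_sorting_model(self) -> SortingModel:
        slopes = {}
        for key, val in self.slopes.items():
            leaflet, species = key.split(":", 1)
            slopes[(leaflet, species)] = float(val)
        g = self.geometry
        return SortingModel(slopes=slopes, d_half=g.d_half,
                            sigma_z=g.sigma_z, bead_spacing=g.bead_spacing)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from TOML, YAML or JSON by file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        data = tomllib.loads(path.read_text())
    elif suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text()) or {}
    elif suffix == ".json":
        data = json.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config format {suffix!r}")
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    """Write the config as YAML (round-trips through load_config)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path
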