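"""Geometric cutoffs and run-level configuration.

The hydrogen-bond cutoffs (3.5 angstrom donor-acceptor distance, 50 degree
deviation from linearity) are the calibrated values of the detection protocol;
the remaining cutoffs are the conventional defaults of geometric interaction
detection. Every value is configurable and serialisable as YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import UsageError


@dataclass
class GeometryConfig:
    """Cutoffs for the seven interaction types (distances in angstrom,
    angles in degrees)."""

    hbond_max_da_dist: float = 3.5
    hbond_max_deviation: float = 50.0
    hydrophobic_max_cc_dist: float = 4.0
    pipi_max_centroid_dist: float = 7.5
    pipi_max_plane_angle: float = 30.0
    pipi_projection_padding: float = 0.75
    tstack_max_centroid_dist: float = 5.0
    tstack_plane_angle_window: float = 30.0
    catpi_max_dist: float = 6.0
    saltbridge_max_dist: float = 5.5
    sulfur_acceptors: bool = False     # treat S as an H-bond acceptor
    zinc_cation: bool = True           # zinc ion counts as a cationic center

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if f.name.endswith(("_dist", "_padding")) or "dist" in f.name:
                if v <= 0:
                    raise UsageError(f"{f.name} must be positive, got {v}")
            elif "angle" in f.name or "deviation" in f.name or "window" in f.name:
                if not 0 < v <= 180:
                    raise UsageError(f"{f.name} must be in (0, 180], got {v}")

    @classmethod
    def from_dict(cls, data: dict) -> "GeometryConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"unknown geometry config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeometryConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


@dataclass
class RunConfig:
    """Pipeline-level parameters: consensus support, clustering threshold and
    the RMSD success criterion."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    min_support: int = 3
    tc_threshold: float = 0.40
    rmsd_threshold: float = 2.0
    site_cutoff: float = 7.0
    symmetry_aware: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise UsageError("min_support must be >= 1")
        if not 0 < self.tc_threshold <= 1:
            raise UsageError("tc_threshold must be in (0, 1]")
        if self.rmsd_threshold <= 0 or self.site_cutoff <= 0:
            raise UsageError("thresholds must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        geo = data.pop("geometry", {})
        known = {f.name for f in fields(cls)} - {"geometry"}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"unknown run config keys: {sorted(unknown)}")
        return cls(geometry=GeometryConfig.from_dict(geo), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
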