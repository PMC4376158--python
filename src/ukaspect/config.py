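"""Region-box configuration.

The localization scheme fixes *which* regions exist; their physical extent
is a site-level choice.  :class:`BoxConfig` holds every dimension in mm
with defaults sized for an adult knee, loadable from TOML.  Unknown keys
are rejected — a silently ignored typo in a box dimension would corrupt
every downstream number.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Literal, Optional

from .errors import ConfigError

__all__ = ["BoxConfig"]


@dataclass(frozen=True)
class BoxConfig:
    """Dimensions (mm) of the anatomically anchored voxel boxes.

    Femoral and tibial boxes tile two axial slabs (inferior/superior) of
    ``*_slab_mm`` thickness each, split medial/lateral into zones of
    ``zone_width_mm`` and anterior/posterior at the frame's AP origin plane
    with ``ap_extent_mm`` total depth.  Tibial zone 3 is a central box of
    ``zone3_ml_width_mm`` straddling the stem axis.  The background box
    sits on the femoral mechanical axis at ``background_fraction`` of the
    knee-to-head distance.
    """

    femoral_slab_mm: float = 10.0
    tibial_slab_mm: float = 10.0
    zone_width_mm: float = 25.0
    ap_extent_mm: float = 40.0
    zone3_ml_width_mm: float = 15.0
    femoral_si_offset_mm: float = 0.0
    tibial_si_offset_mm: float = 0.0
    patella_ml_mm: float = 30.0
    patella_ap_mm: float = 20.0
    patella_si_mm: float = 24.0
    background_box_mm: tuple[float, float, float] = (20.0, 20.0, 30.0)
    background_fraction: float = 0.5
    # None -> per-region defaults from the scheme table; "max"/"mean" -> global
    statistic_override: Optional[Literal["max", "mean"]] = None
    # which statistic feeds the ratio denominator
    background_statistic: Literal["mean", "max"] = "mean"

    def __post_init__(self) -> None:
        object.__setattr__(self, "background_box_mm", tuple(float(v) for v in self.background_box_mm))
        positive = (
            "femoral_slab_mm", "tibial_slab_mm", "zone_width_mm", "ap_extent_mm",
            "zone3_ml_width_mm", "patella_ml_mm", "patella_ap_mm", "patella_si_mm",
        )
        for name in positive:
            if not float(getattr(self, name)) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if len(self.background_box_mm) != 3 or any(v <= 0 for v in self.background_box_mm):
            raise ConfigError(f"background_box_mm must be three positive lengths, got {self.background_box_mm}")
        if not 0.0 < float(self.background_fraction) < 1.0:
            raise ConfigError(f"background_fraction must lie in (0, 1), got {self.background_fraction}")
        if self.statistic_override not in (None, "max", "mean"):
            raise ConfigError(f"statistic_override must be 'max', 'mean' or omitted, got {self.statistic_override!r}")
        if self.background_statistic not in ("mean", "max"):
            raise ConfigError(f"background_statistic must be 'mean' or 'max', got {self.background_statistic!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "BoxConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}")
        return cls(**data)

    @classmethod
    def from_toml(cls, path: str | Path) -> "BoxConfig":
        with open(path, "rb") as fh:
            try:
                data = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"invalid TOML in {path}: {exc}") from exc
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["background_box_mm"] = list(self.background_box_mm)
        return d

    @property
    def config_hash(self) -> str:
        """Short stable hash recorded in every report for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
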