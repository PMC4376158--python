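"""Volumetric tracer-uptake quantification in scheme regions.

The delayed-phase SPECT volume is sampled inside oriented boxes anchored to
the anatomical frames.  A voxel belongs to a box when its *center*, mapped
into the box frame, lies within the half-extents — inclusive on the min
face, exclusive on the max face — so boxes that share a face partition
their voxels and no interpolation or partial-volume weighting enters the
statistics.  Each scored region reports its summary statistic (max or mean
per the scheme) as an absolute intensity and as a ratio against the mean
background activity in the proximal femoral mid-shaft box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .config import BoxConfig
from .errors import BackgroundError, GeometryError, QuantificationError, VolumeError
from .geometry import AnatomicalFrame, LandmarkSet, femoral_frame, tibial_frame
from .scheme import (
    AuxiliaryRegion,
    Bone,
    RegionCode,
    Statistic,
    Zone,
    enumerate_scored_regions,
    statistic_map,
)

__all__ = [
    "IntensityVolume",
    "RegionBox",
    "UptakeRecord",
    "build_region_boxes",
    "quantify_region",
    "background_reference",
    "uptake_report",
    "BACKGROUND_KEY",
]

BACKGROUND_KEY = AuxiliaryRegion.FEMORAL_SHAFT_BACKGROUND.value


@dataclass(frozen=True)
class IntensityVolume:
    """3D scalar uptake grid with world-space placement.

    ``direction`` is the orthonormal index→scanner axis matrix; the world
    position of voxel index (i, j, k) is
    ``origin + direction @ (spacing * (i, j, k))``.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise VolumeError(f"expected a 3D volume, got {vox.ndim}D")
        if any(s < 2 for s in vox.shape):
            raise VolumeError(f"need at least 2 voxels per axis, got shape {vox.shape}")
        spacing = np.asarray(self.spacing, dtype=float)
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise VolumeError(f"spacing must be three positive lengths, got {self.spacing!r}")
        origin = np.asarray(self.origin, dtype=float)
        if origin.shape != (3,) or not np.all(np.isfinite(origin)):
            raise VolumeError(f"origin must be 3 finite coordinates, got {self.origin!r}")
        direction = np.asarray(self.direction, dtype=float)
        if direction.shape != (3, 3) or not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
            raise VolumeError("direction must be an orthonormal 3x3 matrix (within 1e-6)")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of every voxel center, shape (n_voxels, 3).

        Computed once and cached; volumes are immutable.
        """
        cached = self.__dict__.get("_centers")
        if cached is None:
            idx = np.stack(
                np.meshgrid(*(np.arange(n) for n in self.voxels.shape), indexing="ij"),
                axis=-1,
            ).reshape(-1, 3)
            cached = (idx * self.spacing) @ self.direction.T + self.origin
            object.__setattr__(self, "_centers", cached)
        return cached

    @property
    def affine(self) -> np.ndarray:
        """4x4 index→world affine (NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction * self.spacing
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class RegionBox:
    """Oriented box: a scheme region anchored to an anatomical frame.

    ``center`` is in scanner mm; ``half_extents`` are along the frame's
    (ml, ap, si) axes.
    """

    region: str
    frame: AnatomicalFrame
    center: np.ndarray
    half_extents: np.ndarray

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        half = np.asarray(self.half_extents, dtype=float)
        if center.shape != (3,) or not np.all(np.isfinite(center)):
            raise GeometryError(f"box center must be 3 finite mm coordinates, got {self.center!r}")
        if half.shape != (3,) or np.any(half <= 0):
            raise GeometryError(f"half extents must be three positive lengths, got {self.half_extents!r}")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "half_extents", half)

    def frame_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Box interval [lo, hi) in frame coordinates, snapped to 1e-9 mm.

        Snapping makes boxes that share a face hold *identical* boundary
        floats, so the half-open membership test partitions voxels exactly
        instead of double-counting centers that land on a shared plane.
        """
        c_local = (self.center - self.frame.origin) @ self.frame.rotation
        lo = np.round((c_local - self.half_extents) * 1e9) / 1e9
        hi = np.round((c_local + self.half_extents) * 1e9) / 1e9
        return lo, hi

    def contains(self, world_points: np.ndarray) -> np.ndarray:
        """Membership mask for world points: min face inclusive, max face exclusive.

        Points are mapped once into frame coordinates and compared against
        the snapped interval bounds, so adjacent same-frame boxes never
        both claim a boundary voxel.
        """
        lo, hi = self.frame_bounds()
        local = self.frame.to_frame(np.atleast_2d(world_points))
        return np.all((local >= lo) & (local < hi), axis=1)


@dataclass(frozen=True)
class UptakeRecord:
    """Per-region result: summary statistic as absolute intensity and background ratio."""

    region: str
    statistic: Statistic
    absolute: float
    ratio: float


def _slab_bounds(offset: float, thickness: float, level: str) -> tuple[float, float]:
    """SI interval [lo, hi) of the inferior or superior slab, distal edge at ``offset``."""
    if level == "i":
        return offset, offset + thickness
    return offset + thickness, offset + 2.0 * thickness


def _interval_box(ml: tuple[float, float], ap: tuple[float, float], si: tuple[float, float],
                  frame: AnatomicalFrame, label: str) -> RegionBox:
    lo = np.array([ml[0], ap[0], si[0]])
    hi = np.array([ml[1], ap[1], si[1]])
    center = frame.origin + frame.rotation @ ((lo + hi) / 2.0)
    return RegionBox(region=label, frame=frame, center=center, half_extents=(hi - lo) / 2.0)


def _ml_interval(zone: Zone, zone_width: float, zone3_width: float, has_zone3: bool) -> tuple[float, float]:
    """ML interval of a zone; medial is negative ml.  Tibial zones flank the central stem box."""
    inner = zone3_width / 2.0 if has_zone3 else 0.0
    if zone is Zone.MEDIAL:
        return (-inner - zone_width, -inner)
    if zone is Zone.LATERAL:
        return (inner, inner + zone_width)
    return (-inner, inner)  # zone 3: central, straddling the stem axis


def build_region_boxes(
    landmarks: LandmarkSet,
    config: BoxConfig | None = None,
) -> dict[str, RegionBox]:
    """One oriented box per scored region plus the femoral shaft background box.

    Femoral boxes tile the distal femur from the femoral frame origin
    upward (two slabs), split medial/lateral at the frame origin and
    anterior/posterior at the AP origin plane.  Tibial boxes tile the
    proximal tibia downward from the tibial frame origin, with zone 3 a
    central box straddling the stem axis and zones 1/2 flanking it.
    Patellar boxes (built when a ``patella_center`` landmark is present)
    split the patella medial/lateral and superior/inferior using the
    femoral frame orientation.  Boxes within one bone are pairwise
    disjoint by construction (half-open interval tiling).
    """
    config = config or BoxConfig()
    fem = femoral_frame(landmarks)
    tib = tibial_frame(landmarks)

    ap_half = config.ap_extent_mm / 2.0
    boxes: dict[str, RegionBox] = {}
    for region in enumerate_scored_regions():
        if region.bone is Bone.PATELLA:
            continue  # handled below; needs the optional patella landmark
        if region.bone is Bone.FEMUR:
            frame, thick, offset, si_dir = fem, config.femoral_slab_mm, config.femoral_si_offset_mm, +1.0
            has_zone3 = False
        else:
            frame, thick, offset, si_dir = tib, config.tibial_slab_mm, config.tibial_si_offset_mm, -1.0
            has_zone3 = True
        ml_lo, ml_hi = _ml_interval(region.zone, config.zone_width_mm, config.zone3_ml_width_mm, has_zone3)
        ap_int = (0.0, ap_half) if region.sagittal and region.sagittal.value == "a" else (-ap_half, 0.0)
        if si_dir > 0:  # femur: slabs stack superiorly from the joint line
            si_lo, si_hi = _slab_bounds(offset, thick, region.axial.value)
        else:  # tibia: slabs stack distally, the superior slab adjacent to the joint line
            flipped = "i" if region.axial.value == "s" else "s"
            lo_f, hi_f = _slab_bounds(offset, thick, flipped)
            si_lo, si_hi = -hi_f, -lo_f
        boxes[region.label] = _interval_box((ml_lo, ml_hi), ap_int, (si_lo, si_hi), frame, region.label)

    if "patella_center" in landmarks:
        pc = landmarks["patella_center"]
        ml_h, ap_h, si_h = config.patella_ml_mm / 2.0, config.patella_ap_mm / 2.0, config.patella_si_mm / 2.0
        pat_frame = AnatomicalFrame(origin=pc, ml_axis=fem.ml_axis, ap_axis=fem.ap_axis, si_axis=fem.si_axis)
        for region in enumerate_scored_regions():
            if region.bone is not Bone.PATELLA:
                continue
            ml_int = (-ml_h, 0.0) if region.zone is Zone.MEDIAL else (0.0, ml_h)
            si_int = (0.0, si_h) if region.axial.value == "s" else (-si_h, 0.0)
            boxes[region.label] = _interval_box(ml_int, (-ap_h, ap_h), si_int, pat_frame, region.label)

    head = landmarks["femoral_head_center"]
    knee = landmarks["knee_center_femur"]
    bg_center = knee + config.background_fraction * (head - knee)
    boxes[BACKGROUND_KEY] = RegionBox(
        region=BACKGROUND_KEY,
        frame=fem,
        center=bg_center,
        half_extents=np.asarray(config.background_box_mm) / 2.0,
    )
    return boxes


def quantify_region(
    volume: IntensityVolume,
    box: RegionBox,
    statistic: Statistic | str,
) -> float:
    """Max or mean intensity over the voxels whose centers fall inside the box.

    No interpolation: a voxel contributes fully or not at all.  An empty
    box (no voxel center inside) raises a
    :class:`~ukaspect.errors.QuantificationError` naming the region.
    """
    statistic = Statistic(statistic)
    mask = box.contains(volume.voxel_centers())
    if not mask.any():
        raise QuantificationError(f"region {box.region!r}: no voxel centers inside the box")
    values = volume.voxels.reshape(-1)[mask]
    if statistic is Statistic.MAX:
        return float(values.max())
    return float(values.mean())


def background_reference(
    volume: IntensityVolume,
    landmarks: LandmarkSet,
    config: BoxConfig | None = None,
    boxes: Optional[Mapping[str, RegionBox]] = None,
) -> float:
    """Background tracer activity in the proximal femoral mid-shaft box.

    Mean intensity (by default) over a box centered on the femoral
    mechanical axis at ``config.background_fraction`` of the knee-to-head
    distance.  A non-positive result blocks ratio computation.
    """
    config = config or BoxConfig()
    if boxes is None:
        boxes = build_region_boxes(landmarks, config)
    box = boxes[BACKGROUND_KEY]
    try:
        value = quantify_region(volume, box, config.background_statistic)
    except QuantificationError as exc:
        raise BackgroundError(str(exc)) from exc
    if value <= 0:
        raise BackgroundError(
            f"background activity must be positive to form ratios, got {value}"
        )
    return value


def uptake_report(
    volume: IntensityVolume,
    boxes: Mapping[str, RegionBox],
    background: float,
    statistics: Optional[Mapping[str, Statistic | str]] = None,
) -> list[UptakeRecord]:
    """One :class:`UptakeRecord` per scored region, in scheme enumeration order.

    ``statistics`` maps region label → statistic; by default the scheme's
    per-region mapping is used.  ``ratio = absolute / background`` exactly.
    """
    if not background > 0:
        raise BackgroundError(f"background must be > 0, got {background}")
    stats = dict(statistic_map()) if statistics is None else dict(statistics)
    records: list[UptakeRecord] = []
    for region in enumerate_scored_regions():
        label = region.label
        if label not in boxes:
            raise QuantificationError(f"region {label!r}: no box provided")
        stat = Statistic(stats.get(label, statistic_map()[label]))
        absolute = quantify_region(volume, boxes[label], stat)
        records.append(
            UptakeRecord(region=label, statistic=stat, absolute=absolute, ratio=absolute / background)
        )
    return records
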