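"""Readers, writers and the full-case pipeline.

All interfaces speak scanner (world) millimeter coordinates; voxel indices
never cross a module boundary.  Volumes travel as NIfTI-1, landmarks as a
JSON object mapping name → [x, y, z] with a ``space`` field, uptake and
angle results as CSV with a JSON sidecar carrying full precision and
provenance (input hashes, config hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .config import BoxConfig
from .errors import UkaspectError, VolumeError
from .geometry import (
    AngleReport,
    LandmarkSet,
    component_frame_from_landmarks,
    femoral_component_angles,
    femoral_frame,
    rotational_mismatch,
    tibial_component_angles,
    tibial_frame,
    tibiofemoral_angle,
)
from .uptake import (
    BACKGROUND_KEY,
    IntensityVolume,
    UptakeRecord,
    background_reference,
    build_region_boxes,
    uptake_report,
)
from .scheme import statistic_map

__all__ = [
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "CaseReport",
    "run_case",
    "measure_angles",
    "angles_to_frame",
    "uptake_to_frame",
]

# Anatomical landmark names the schema recognises; extra names pass through
# but are flagged so typos surface.
KNOWN_LANDMARKS = frozenset(
    [
        "femoral_head_center",
        "knee_center_femur",
        "medial_epicondyle",
        "lateral_epicondyle",
        "knee_center_tibia",
        "ankle_center",
        "tibia_posterior_condyle_medial",
        "tibia_posterior_condyle_lateral",
        "patella_center",
    ]
    + [
        f"{c}_component_{s}"
        for c in ("femoral", "tibial")
        for s in ("origin", "ml", "ap")
    ]
)


def read_volume(path: str | Path) -> IntensityVolume:
    """Load a 3D NIfTI-1 volume, decomposing its affine into spacing/origin/direction.

    Rejects 4D data and affines whose rotational part is not orthogonal
    (after removing spacing) within 1e-3: sheared volumes would silently
    distort box membership.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0):
        raise VolumeError(f"{path}: degenerate affine (zero-length axis)")
    direction = linear / spacing
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-3):
        raise VolumeError(f"{path}: non-orthonormal direction matrix (shear beyond 1e-3)")
    # re-orthonormalize residual float error so downstream tolerance is 1e-9
    u, _, vt = np.linalg.svd(direction)
    return IntensityVolume(
        voxels=np.asarray(data, dtype=float),
        spacing=spacing,
        origin=affine[:3, 3],
        direction=u @ vt,
    )


def write_volume(volume: IntensityVolume, path: str | Path) -> Path:
    """Write an :class:`IntensityVolume` as NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), volume.affine)
    nib.save(img, str(path))
    return path


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Load a landmark JSON file: {"space": ..., "landmarks": {name: [x,y,z]}}.

    A flat {name: [x,y,z]} mapping is also accepted.  Unknown names are
    preserved but collected in ``read_landmarks.unknown`` for the caller
    to warn about.
    """
    path = Path(path)
    if not path.exists():
        raise UkaspectError(f"landmark file not found: {path}")
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise UkaspectError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise UkaspectError(f"{path}: expected a JSON object")
    space = raw.get("space", "scanner")
    mapping = raw.get("landmarks", raw)
    if "space" in mapping:
        mapping = {k: v for k, v in mapping.items() if k != "space"}
    lm = LandmarkSet(mapping, space=str(space))
    read_landmarks.unknown = sorted(set(lm.names()) - KNOWN_LANDMARKS)  # type: ignore[attr-defined]
    return lm


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "space": landmarks.space,
        "landmarks": {k: [float(c) for c in v] for k, v in landmarks.points.items()},
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class CaseReport:
    """Everything measured for one case, with provenance.

    Serializes losslessly to/from JSON; the CSV exports are formatted
    views of the same numbers.
    """

    case_id: str
    background: float
    uptake: tuple[UptakeRecord, ...]
    femoral_angles: AngleReport
    tibial_angles: AngleReport
    rotational_mismatch: float
    tibiofemoral_angle: float
    provenance: dict

    def __post_init__(self) -> None:
        if not self.provenance or not all(self.provenance.values()):
            raise UkaspectError("provenance fields must be non-empty")

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "background": self.background,
            "uptake": [dataclasses.asdict(r) | {"statistic": r.statistic.value} for r in self.uptake],
            "femoral_angles": _report_dict(self.femoral_angles),
            "tibial_angles": _report_dict(self.tibial_angles),
            "rotational_mismatch": self.rotational_mismatch,
            "tibiofemoral_angle": self.tibiofemoral_angle,
            "provenance": dict(self.provenance),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "CaseReport":
        from .scheme import Statistic

        return cls(
            case_id=d["case_id"],
            background=float(d["background"]),
            uptake=tuple(
                UptakeRecord(
                    region=r["region"],
                    statistic=Statistic(r["statistic"]),
                    absolute=float(r["absolute"]),
                    ratio=float(r["ratio"]),
                )
                for r in d["uptake"]
            ),
            femoral_angles=_report_from_dict(d["femoral_angles"]),
            tibial_angles=_report_from_dict(d["tibial_angles"]),
            rotational_mismatch=float(d["rotational_mismatch"]),
            tibiofemoral_angle=float(d["tibiofemoral_angle"]),
            provenance=dict(d["provenance"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CaseReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _report_dict(r: AngleReport) -> dict:
    return {
        "component": r.component.value,
        "varus_valgus": r.varus_valgus,
        "sagittal_angle": r.sagittal_angle,
        "axial_rotation": r.axial_rotation,
    }


def _report_from_dict(d: dict) -> AngleReport:
    return AngleReport(
        component=d["component"],
        varus_valgus=float(d["varus_valgus"]),
        sagittal_angle=float(d["sagittal_angle"]),
        axial_rotation=float(d["axial_rotation"]),
    )


def measure_angles(landmarks: LandmarkSet) -> tuple[AngleReport, AngleReport, float, float]:
    """Both component angle reports, their rotational mismatch, and the tibiofemoral angle."""
    fem_frame = femoral_frame(landmarks)
    tib_frame = tibial_frame(landmarks)
    fem = femoral_component_angles(fem_frame, component_frame_from_landmarks(landmarks, "femoral"))
    tib = tibial_component_angles(tib_frame, component_frame_from_landmarks(landmarks, "tibial"))
    return fem, tib, rotational_mismatch(fem, tib), tibiofemoral_angle(landmarks)


def run_case(
    volume_path: str | Path,
    landmarks_path: str | Path,
    config: Optional[BoxConfig] = None,
    case_id: Optional[str] = None,
) -> CaseReport:
    """Full-case pipeline: frames → boxes → background → uptake → angles.

    Any stage error aborts the whole case (no partial report).  Output is
    deterministic for fixed inputs and config.
    """
    config = config or BoxConfig()
    volume_path, landmarks_path = Path(volume_path), Path(landmarks_path)
    volume = read_volume(volume_path)
    landmarks = read_landmarks(landmarks_path)

    boxes = build_region_boxes(landmarks, config)
    background = background_reference(volume, landmarks, config, boxes=boxes)
    records = uptake_report(volume, boxes, background, statistic_map(config.statistic_override))
    fem, tib, mismatch, tfa = measure_angles(landmarks)

    provenance = {
        "volume_sha256": _file_sha256(volume_path),
        "landmarks_sha256": _file_sha256(landmarks_path),
        "config_hash": config.config_hash,
        "package_version": __version__,
    }
    return CaseReport(
        case_id=case_id or volume_path.stem.replace(".nii", ""),
        background=background,
        uptake=tuple(records),
        femoral_angles=fem,
        tibial_angles=tib,
        rotational_mismatch=mismatch,
        tibiofemoral_angle=tfa,
        provenance=provenance,
    )


def uptake_to_frame(report: CaseReport) -> pd.DataFrame:
    """Uptake records as a DataFrame (region, statistic, absolute, ratio)."""
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "statistic": r.statistic.value,
                "absolute": r.absolute,
                "ratio": r.ratio,
            }
            for r in report.uptake
        ]
    )


def angles_to_frame(report: CaseReport) -> pd.DataFrame:
    """Angle measurements as one row per (component, angle), signed degrees."""
    rows = []
    for rep in (report.femoral_angles, report.tibial_angles):
        comp = rep.component.value
        rows += [
            {"component": comp, "angle": "varus_valgus", "degrees": rep.varus_valgus},
            {"component": comp, "angle": "sagittal", "degrees": rep.sagittal_angle},
            {"component": comp, "angle": "axial_rotation", "degrees": rep.axial_rotation},
        ]
    rows.append({"component": "combined", "angle": "rotational_mismatch", "degrees": report.rotational_mismatch})
    rows.append({"component": "limb", "angle": "tibiofemoral", "degrees": report.tibiofemoral_angle})
    return pd.DataFrame(rows)
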