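"""Digital phantoms with known ground truth for every pipeline stage.

Three generators mirror the three measurement stages:

* :func:`generate_uptake_phantom` — a volume whose voxels inside each
  region box carry that region's true intensity level (plus optional
  additive Gaussian noise, clipped at zero), so recovered ratios can be
  compared against ``level / background`` exactly in the noiseless case;
* :func:`generate_landmark_case` — a landmark set whose component
  fiducials encode prescribed component angles by inverting the projection
  measurement (the superior axis is built from the tangents of the target
  coronal and sagittal angles, the ml axis from the target axial azimuth),
  so the geometry module recovers the angles to numerical precision;
* :func:`simulate_ratings` — rater tables drawn from the additive
  two-way model value(i, r, s) = mu + b_i + c_r + e_irs with prescribed
  variance components, whose analytic one-way ICC
  item_var / (item_var + rater_var + residual_var) is attached.

All generators are pure functions of (parameters, seed).

The template anatomy is an upright leg: femoral mechanical axis along +z
(femur length 400 mm), transepicondylar axis along +x (width 90 mm), tibia
below (length 380 mm).  Dimensions are overridable; no claim of matching
any individual patient is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import PhantomError
from .geometry import (
    AngleReport,
    AnatomicalFrame,
    Component,
    DEFAULT_SIGNS,
    LandmarkSet,
    SignConvention,
    femoral_frame,
    tibial_frame,
)
from .reliability import RatingsTable
from .scheme import enumerate_scored_regions
from .uptake import BACKGROUND_KEY, IntensityVolume, RegionBox

__all__ = [
    "TemplateAnatomy",
    "PhantomTruth",
    "default_truth",
    "template_landmarks",
    "generate_landmark_case",
    "generate_uptake_phantom",
    "phantom_grid",
    "simulate_ratings",
    "SimulatedRatings",
]

_MAX_ANGLE_DEG = 60.0  # inverse construction is well-posed for |angle| < 90; stay clinical


@dataclass(frozen=True)
class TemplateAnatomy:
    """Scale parameters (mm) of the template leg."""

    femur_length: float = 400.0
    epicondylar_width: float = 90.0
    tibia_length: float = 380.0
    joint_gap: float = 10.0           # femoral to tibial knee center
    condyle_ml_halfwidth: float = 25.0
    condyle_ap_offset: float = 20.0   # posterior condyles sit posterior to the axis
    condyle_si_offset: float = 5.0    # below the tibial knee center
    patella_ap_offset: float = 45.0
    fiducial_arm: float = 30.0        # component fiducial distance from its origin

    def __post_init__(self) -> None:
        for name in ("femur_length", "epicondylar_width", "tibia_length", "fiducial_arm"):
            if not float(getattr(self, name)) > 0:
                raise PhantomError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth behind one synthetic case.

    Intensity levels are in arbitrary counts; integer-valued defaults make
    in-box means exactly representable, so noiseless recovery is exact.
    """

    region_levels: Mapping[str, float]
    background_level: float
    base_level: float
    femoral_angles: AngleReport
    tibial_angles: AngleReport
    tibiofemoral: float
    rater_components: Mapping[str, float] = field(
        default_factory=lambda: {"item_var": 9.0, "rater_var": 0.0, "residual_var": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        levels = {str(k): float(v) for k, v in dict(self.region_levels).items()}
        if any(v < 0 for v in levels.values()):
            raise PhantomError("region uptake levels must be >= 0")
        if not self.background_level > 0:
            raise PhantomError(f"background level must be > 0, got {self.background_level}")
        if self.base_level < 0:
            raise PhantomError(f"base level must be >= 0, got {self.base_level}")
        object.__setattr__(self, "region_levels", levels)


def default_truth(seed: int = 0) -> PhantomTruth:
    """A reproducible whole-pipeline truth: integer uptake levels, moderate angles.

    Region levels are drawn uniformly from 20–200 counts against a
    background of 50 and an off-region base of 10, spanning cold regions
    (ratio < 1) through markedly hot ones (ratio 4), the range seen around
    knee arthroplasties.  Component angles are a few degrees of varus,
    flexion and rotation — typical implantation values.
    """
    rng = np.random.default_rng(seed)
    levels = {r.label: float(rng.integers(20, 201)) for r in enumerate_scored_regions()}
    fem = AngleReport(Component.FEMORAL, varus_valgus=2.0, sagittal_angle=8.0, axial_rotation=-4.0)
    tib = AngleReport(Component.TIBIAL, varus_valgus=3.0, sagittal_angle=-6.0, axial_rotation=-5.0)
    return PhantomTruth(
        region_levels=levels,
        background_level=50.0,
        base_level=10.0,
        femoral_angles=fem,
        tibial_angles=tib,
        tibiofemoral=-2.0,
        seed=seed,
    )


def _aligned_component_fiducials(frame: AnatomicalFrame, arm: float) -> dict[str, np.ndarray]:
    return {
        "origin": frame.origin.copy(),
        "ml": frame.origin + arm * frame.ml_axis,
        "ap": frame.origin + arm * frame.ap_axis,
    }


def template_landmarks(anatomy: TemplateAnatomy | None = None) -> LandmarkSet:
    """The upright template leg with component fiducials aligned to the bone frames."""
    a = anatomy or TemplateAnatomy()
    w = a.epicondylar_width / 2.0
    knee_t = np.array([0.0, 0.0, -a.joint_gap])
    points: dict[str, np.ndarray] = {
        "femoral_head_center": np.array([0.0, 0.0, a.femur_length]),
        "knee_center_femur": np.array([0.0, 0.0, 0.0]),
        "medial_epicondyle": np.array([-w, 0.0, 0.0]),
        "lateral_epicondyle": np.array([w, 0.0, 0.0]),
        "knee_center_tibia": knee_t,
        "ankle_center": knee_t + np.array([0.0, 0.0, -a.tibia_length]),
        "tibia_posterior_condyle_medial": knee_t + np.array(
            [-a.condyle_ml_halfwidth, -a.condyle_ap_offset, -a.condyle_si_offset]
        ),
        "tibia_posterior_condyle_lateral": knee_t + np.array(
            [a.condyle_ml_halfwidth, -a.condyle_ap_offset, -a.condyle_si_offset]
        ),
        "patella_center": np.array([0.0, a.patella_ap_offset, 0.0]),
    }
    lm = LandmarkSet(points)
    for comp, frame in (("femoral", femoral_frame(lm)), ("tibial", tibial_frame(lm))):
        for suffix, p in _aligned_component_fiducials(frame, a.fiducial_arm).items():
            points[f"{comp}_component_{suffix}"] = p
    return LandmarkSet(points)


def _check_angle(name: str, value: float) -> float:
    v = float(value)
    if not -_MAX_ANGLE_DEG < v < _MAX_ANGLE_DEG:
        raise PhantomError(f"{name}: {v} deg outside the supported ({-_MAX_ANGLE_DEG}, {_MAX_ANGLE_DEG}) range")
    return v


def _component_axes_from_raw(raw_cor: float, raw_sag: float, raw_ax: float) -> np.ndarray:
    """Component triad (columns ml, ap, si) in anatomical-frame coordinates.

    Inverts the projection measurement: the superior axis is fixed by the
    tangents of the coronal and sagittal projection angles, the ml axis by
    the axial azimuth subject to orthogonality, ap completes the
    right-handed triad.
    """
    rc, rs, ra = np.radians([raw_cor, raw_sag, raw_ax])
    si = np.array([-np.tan(rc), -np.tan(rs), 1.0])
    si /= np.linalg.norm(si)
    u = np.array([-np.sin(ra), np.cos(ra), 0.0])
    ml = np.cross(u, si)
    ml /= np.linalg.norm(ml)
    ap = np.cross(si, ml)
    return np.column_stack([ml, ap, si])


def _place_component(
    points: dict[str, np.ndarray],
    name: str,
    anat: AnatomicalFrame,
    report: AngleReport,
    signs: SignConvention,
    arm: float,
) -> None:
    s_cor, s_sag, s_ax = signs.for_component(Component(report.component))
    raw = (
        _check_angle("varus_valgus", report.varus_valgus) / s_cor,
        _check_angle("sagittal_angle", report.sagittal_angle) / s_sag,
        _check_angle("axial_rotation", report.axial_rotation) / s_ax,
    )
    axes_local = _component_axes_from_raw(*raw)
    axes_world = anat.rotation @ axes_local
    origin = anat.origin
    points[f"{name}_component_origin"] = origin.copy()
    points[f"{name}_component_ml"] = origin + arm * axes_world[:, 0]
    points[f"{name}_component_ap"] = origin + arm * axes_world[:, 1]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def generate_landmark_case(
    true_fem: AngleReport,
    true_tib: AngleReport,
    true_tfa: float,
    anatomy: TemplateAnatomy | None = None,
    seed: int = 0,
    signs: SignConvention = DEFAULT_SIGNS,
    rigid_jitter: bool = False,
) -> LandmarkSet:
    """Landmarks encoding prescribed component angles and tibiofemoral angle.

    The ankle center is displaced in the femoral coronal plane to realize
    ``true_tfa``; the tibial frame (and hence the tibial component) is
    built from the displaced anatomy, so all angles are mutually
    consistent.  With ``rigid_jitter`` the whole set is moved by a seeded
    random rigid transform, which leaves every measured angle unchanged.
    Measuring the result recovers all prescribed angles to ~1e-12 degrees.
    """
    a = anatomy or TemplateAnatomy()
    tfa = _check_angle("tibiofemoral", true_tfa)
    points = dict(template_landmarks(a).points)

    lm0 = LandmarkSet(points)
    fem = femoral_frame(lm0)

    # ankle displaced so the tibial mechanical axis makes the raw coronal
    # angle with the femoral mechanical axis
    raw_tfa = np.radians(tfa / signs.tibiofemoral)
    tib_dir_local = np.array([-np.sin(raw_tfa), 0.0, np.cos(raw_tfa)])  # (ml, ap, si)
    tib_dir = fem.rotation @ tib_dir_local
    knee_t = points["knee_center_tibia"]
    points["ankle_center"] = knee_t - a.tibia_length * tib_dir

    lm1 = LandmarkSet(points)
    _place_component(points, "femoral", fem, true_fem, signs, a.fiducial_arm)
    _place_component(points, "tibial", tibial_frame(lm1), true_tib, signs, a.fiducial_arm)

    case = LandmarkSet(points)
    if rigid_jitter:
        rng = np.random.default_rng(seed)
        case = case.transformed(_random_rotation(rng), rng.uniform(-100.0, 100.0, size=3))
    return case


def phantom_grid(
    boxes: Mapping[str, RegionBox],
    spacing: float = 2.0,
    pad_mm: float = 10.0,
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Axis-aligned (shape, origin) of a grid covering every box, padded."""
    corners = []
    signs = np.array([[i, j, k] for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)], dtype=float)
    for box in boxes.values():
        corners.append(box.center + (signs * box.half_extents) @ box.frame.rotation.T)
    pts = np.vstack(corners)
    lo = pts.min(axis=0) - pad_mm
    hi = pts.max(axis=0) + pad_mm
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return shape, lo


def generate_uptake_phantom(
    truth: PhantomTruth,
    boxes: Mapping[str, RegionBox],
    noise_sd: float = 0.0,
    shape: Optional[tuple[int, int, int]] = None,
    spacing: float | tuple[float, float, float] = 2.0,
    origin: Optional[np.ndarray] = None,
    direction: Optional[np.ndarray] = None,
) -> IntensityVolume:
    """A volume carrying the truth's level inside each box, plus optional noise.

    Voxels inside a region box take that region's true level, the
    background box takes ``truth.background_level``, everything else
    ``truth.base_level``; Gaussian noise of sd ``noise_sd`` is added and
    the result clipped at zero.  Boxes whose voxel sets overlap raise a
    :class:`~ukaspect.errors.PhantomError` — overlapping truth would be
    ambiguous.  Deterministic given ``truth.seed``.
    """
    if noise_sd < 0:
        raise PhantomError(f"noise_sd must be >= 0, got {noise_sd}")
    spacing3 = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if shape is None or origin is None:
        auto_shape, auto_origin = phantom_grid(boxes, float(spacing3.max()))
        shape = shape or auto_shape
        origin = origin if origin is not None else auto_origin
    volume = IntensityVolume(
        voxels=np.zeros(shape),
        spacing=spacing3,
        origin=np.asarray(origin, dtype=float),
        direction=np.eye(3) if direction is None else np.asarray(direction, dtype=float),
    )
    centers = volume.voxel_centers()
    flat = np.full(centers.shape[0], truth.base_level, dtype=float)
    assigned = np.zeros(centers.shape[0], dtype=bool)

    levels = dict(truth.region_levels)
    levels[BACKGROUND_KEY] = truth.background_level
    for label, box in boxes.items():
        if label not in levels:
            raise PhantomError(f"no true level specified for box {label!r}")
        mask = box.contains(centers)
        clash = mask & assigned
        if clash.any():
            raise PhantomError(
                f"box {label!r} overlaps a previously assigned box on {int(clash.sum())} voxels"
            )
        flat[mask] = levels[label]
        assigned |= mask

    if noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        flat = np.clip(flat + noise_sd * rng.standard_normal(flat.shape), 0.0, None)
    return IntensityVolume(
        voxels=flat.reshape(shape),
        spacing=volume.spacing,
        origin=volume.origin,
        direction=volume.direction,
    )


@dataclass(frozen=True)
class SimulatedRatings:
    """A simulated rater table plus the variance components that produced it."""

    table: RatingsTable
    analytic_icc: float
    components: dict[str, float]
    seed: int


def simulate_ratings(
    n_items: int,
    n_raters: int = 2,
    sessions: int = 1,
    components: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    mu: float = 0.0,
) -> SimulatedRatings:
    """Draw a ratings table from the additive two-way random-effects model.

    value(i, r, s) = mu + b_i + c_r + e_irs with independent zero-mean
    Gaussian item, rater and residual effects of the given variances
    (defaults item_var 9, rater_var 0, residual_var 1).  The analytic
    one-way ICC item_var / (item_var + rater_var + residual_var) rides
    along as metadata.
    """
    comp = {"item_var": 9.0, "rater_var": 0.0, "residual_var": 1.0}
    comp.update(components or {})
    if n_items < 2:
        raise PhantomError(f"need at least 2 items, got {n_items}")
    if n_raters < 1 or sessions < 1:
        raise PhantomError("need at least one rater and one session")
    if any(v < 0 for v in comp.values()):
        raise PhantomError(f"variance components must be >= 0, got {comp}")

    rng = np.random.default_rng(seed)
    b = np.sqrt(comp["item_var"]) * rng.standard_normal(n_items)
    c = np.sqrt(comp["rater_var"]) * rng.standard_normal(n_raters)
    e = np.sqrt(comp["residual_var"]) * rng.standard_normal((n_items, n_raters, sessions))
    values = mu + b[:, None, None] + c[None, :, None] + e
    columns = [(f"U{r + 1}", s + 1) for r in range(n_raters) for s in range(sessions)]
    matrix = values.reshape(n_items, n_raters * sessions)
    table = RatingsTable(tuple(range(1, n_items + 1)), columns, matrix)
    total = comp["item_var"] + comp["rater_var"] + comp["residual_var"]
    analytic = comp["item_var"] / total if total > 0 else float("nan")
    return SimulatedRatings(table=table, analytic_icc=analytic, components=comp, seed=seed)
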