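"""Anatomical coordinate frames and component-orientation angles.

Component position after unicondylar knee arthroplasty is measured as
signed projected angles between a component frame (built from three
fiducials on the implant) and an anatomical frame:

* femur — superior axis along the mechanical femoral axis (knee center →
  femoral head center), medio-lateral axis from the transepicondylar axis
  orthogonalized against it;
* tibia — superior axis along the tibial mechanical axis (ankle center →
  knee center), medio-lateral axis from the tibial posterior condylar axis.

A frame is a right-handed orthonormal triad (ml, ap, si) = (medial→lateral,
posterior→anterior, inferior→superior) with ``ml × ap = si``.  The three
clinical angles are planar projections:

* varus–valgus — component si axis projected into the coronal (ml–si) plane;
* flexion–extension / slope — component si axis in the sagittal (ap–si) plane;
* internal–external rotation — component ml axis in the axial (ml–ap) plane,
  the femur against the transepicondylar axis and the tibia against the
  posterior condylar axis.

Raw projected angles follow the right-hand rule about the plane normal (the
remaining frame axis).  Clinical sign conventions (varus positive, femoral
flexion positive, posterior tibial slope negative, internal rotation
negative for a right knee under the template anatomy) are applied through a
single :class:`SignConvention` table so a user can flip any convention
without touching the math.  All angles are degrees in (-180, 180].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import GeometryError, MissingLandmarkError

__all__ = [
    "LandmarkSet",
    "AnatomicalFrame",
    "AngleReport",
    "SignConvention",
    "DEFAULT_SIGNS",
    "Plane",
    "FEMORAL_LANDMARKS",
    "TIBIAL_LANDMARKS",
    "femoral_frame",
    "tibial_frame",
    "component_frame",
    "component_frame_from_landmarks",
    "projected_angle",
    "femoral_component_angles",
    "tibial_component_angles",
    "rotational_mismatch",
    "tibiofemoral_angle",
    "wrap_degrees",
]

_PARALLEL_TOL_RAD = 1e-6  # axes closer than this to parallel are degenerate
_COINCIDENT_TOL_MM = 1e-6

FEMORAL_LANDMARKS = (
    "femoral_head_center",
    "knee_center_femur",
    "medial_epicondyle",
    "lateral_epicondyle",
)
TIBIAL_LANDMARKS = (
    "knee_center_tibia",
    "ankle_center",
    "tibia_posterior_condyle_medial",
    "tibia_posterior_condyle_lateral",
)


def _as_point(value: Iterable[float], name: str = "point") -> np.ndarray:
    p = np.asarray(value, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise GeometryError(f"{name}: expected 3 finite coordinates, got {value!r}")
    return p


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D fiducials in scanner space (mm).

    Anatomical names (``femoral_head_center`` …) define the bone frames;
    ``{femoral,tibial}_component_{origin,ml,ap}`` triples define component
    pose.  Unknown names are carried along untouched so site-specific extra
    landmarks survive a round-trip.
    """

    points: Mapping[str, np.ndarray]
    space: str = "scanner"

    def __post_init__(self) -> None:
        clean = {str(k): _as_point(v, str(k)) for k, v in dict(self.points).items()}
        object.__setattr__(self, "points", clean)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> list[str]:
        return list(self.points)

    def require(self, names: Iterable[str]) -> None:
        for n in names:
            if n not in self.points:
                raise MissingLandmarkError(n)

    def transformed(self, rotation: np.ndarray, translation: Iterable[float]) -> "LandmarkSet":
        """Apply a rigid transform ``p -> R p + t`` to every landmark."""
        R = np.asarray(rotation, dtype=float)
        t = _as_point(translation, "translation")
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise GeometryError("rotation: expected a proper 3x3 rotation matrix")
        return LandmarkSet({k: R @ p + t for k, p in self.points.items()}, space=self.space)


class Plane(str, enum.Enum):
    CORONAL = "coronal"    # ml–si plane, normal ap
    SAGITTAL = "sagittal"  # ap–si plane, normal ml
    AXIAL = "axial"        # ml–ap plane, normal si


class Component(str, enum.Enum):
    FEMORAL = "femoral"
    TIBIAL = "tibial"


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal triad (ml, ap, si) with an origin in mm."""

    origin: np.ndarray
    ml_axis: np.ndarray
    ap_axis: np.ndarray
    si_axis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _as_point(self.origin, "origin"))
        for name in ("ml_axis", "ap_axis", "si_axis"):
            object.__setattr__(self, name, _as_point(getattr(self, name), name))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes are not orthonormal within 1e-9")
        if np.linalg.det(R) < 0:
            raise GeometryError("frame is left-handed (det = -1)")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with columns (ml, ap, si): maps frame coords to world."""
        return np.column_stack([self.ml_axis, self.ap_axis, self.si_axis])

    def axis(self, name: str) -> np.ndarray:
        return {"ml": self.ml_axis, "ap": self.ap_axis, "si": self.si_axis}[name]

    def to_frame(self, world_points: np.ndarray) -> np.ndarray:
        """World mm coordinates -> frame coordinates (vectorized over rows)."""
        return (np.asarray(world_points, dtype=float) - self.origin) @ self.rotation


@dataclass(frozen=True)
class SignConvention:
    """Multipliers mapping raw right-hand-rule projected angles to clinical signs.

    Defaults give, for the template (right-knee-like) anatomy: varus
    positive on both bones, femoral flexion positive, posterior tibial
    slope negative, and external rotation positive (hence internal rotation
    negative).
    """

    femoral_coronal: float = -1.0
    femoral_sagittal: float = -1.0
    femoral_axial: float = 1.0
    tibial_coronal: float = 1.0
    tibial_sagittal: float = -1.0
    tibial_axial: float = 1.0
    tibiofemoral: float = -1.0

    def for_component(self, component: Component) -> tuple[float, float, float]:
        if component is Component.FEMORAL:
            return (self.femoral_coronal, self.femoral_sagittal, self.femoral_axial)
        return (self.tibial_coronal, self.tibial_sagittal, self.tibial_axial)


DEFAULT_SIGNS = SignConvention()


@dataclass(frozen=True)
class AngleReport:
    """Signed component-orientation angles in degrees.

    ``sagittal_angle`` is flexion(+)/extension(-) for the femoral component
    and slope for the tibial component (posterior slope negative).
    ``axial_rotation`` is negative for internal rotation.
    """

    component: Component
    varus_valgus: float
    sagittal_angle: float
    axial_rotation: float

    def __post_init__(self) -> None:
        for name in ("varus_valgus", "sagittal_angle", "axial_rotation"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or not (-180.0 < v <= 180.0):
                raise GeometryError(f"{name}: {v} outside (-180, 180]")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "component", Component(self.component))


def wrap_degrees(angle: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = float(np.mod(-angle + 180.0, 360.0))
    return -(wrapped - 180.0) + 0.0  # + 0.0 normalizes -0.0


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _COINCIDENT_TOL_MM:
        raise GeometryError(f"{what}: defining points coincide (norm {n:.2e} mm)")
    return v / n


def _orthogonalize(v: np.ndarray, against: np.ndarray, what: str) -> np.ndarray:
    """Unit component of v orthogonal to the unit vector ``against``."""
    u = _unit(v, what)
    w = u - np.dot(u, against) * against
    n = np.linalg.norm(w)
    # |sin(angle between axes)| = n; degenerate when (anti)parallel
    if n < _PARALLEL_TOL_RAD:
        raise GeometryError(f"{what}: axis is parallel to the reference axis within 1e-6 rad")
    return w / n


def femoral_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Femoral anatomical frame from the mechanical and transepicondylar axes.

    si: knee center → femoral head center (mechanical axis);
    ml: medial → lateral epicondyle, orthogonalized against si;
    ap completes the right-handed triad; origin at the femoral knee center.
    """
    landmarks.require(FEMORAL_LANDMARKS)
    knee = landmarks["knee_center_femur"]
    si = _unit(landmarks["femoral_head_center"] - knee, "mechanical femoral axis")
    tea = landmarks["lateral_epicondyle"] - landmarks["medial_epicondyle"]
    ml = _orthogonalize(tea, si, "transepicondylar axis")
    ap = np.cross(si, ml)
    return AnatomicalFrame(origin=knee, ml_axis=ml, ap_axis=ap, si_axis=si)


def tibial_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Tibial anatomical frame from the mechanical and posterior condylar axes.

    si: ankle center → tibial knee center (mechanical axis);
    ml: medial → lateral posterior condyle, orthogonalized against si.
    """
    landmarks.require(TIBIAL_LANDMARKS)
    knee = landmarks["knee_center_tibia"]
    si = _unit(knee - landmarks["ankle_center"], "mechanical tibial axis")
    pca = landmarks["tibia_posterior_condyle_lateral"] - landmarks["tibia_posterior_condyle_medial"]
    ml = _orthogonalize(pca, si, "posterior condylar axis")
    ap = np.cross(si, ml)
    return AnatomicalFrame(origin=knee, ml_axis=ml, ap_axis=ap, si_axis=si)


def component_frame(origin, ml_point, ap_point) -> AnatomicalFrame:
    """Component frame from three fiducials.

    ml: origin → ml_point; ap: component of origin → ap_point orthogonal to
    ml; si completes the right-handed triad.  Collinear fiducials raise a
    :class:`~ukaspect.errors.GeometryError`.
    """
    o = _as_point(origin, "origin")
    ml = _unit(_as_point(ml_point, "ml_point") - o, "component ml axis")
    ap = _orthogonalize(_as_point(ap_point, "ap_point") - o, ml, "component ap axis")
    si = np.cross(ml, ap)
    return AnatomicalFrame(origin=o, ml_axis=ml, ap_axis=ap, si_axis=si)


def component_frame_from_landmarks(landmarks: LandmarkSet, component: Component | str) -> AnatomicalFrame:
    """Build a component frame from the ``{name}_component_{origin,ml,ap}`` triple."""
    name = Component(component).value
    names = [f"{name}_component_{suffix}" for suffix in ("origin", "ml", "ap")]
    landmarks.require(names)
    return component_frame(*(landmarks[n] for n in names))


_PLANE_BASIS = {
    # plane -> ordered in-plane axes; positive angles run from the first
    # toward the second (the oriented normal is their cross product, which
    # is the remaining frame axis up to sign)
    Plane.CORONAL: ("ml", "si"),
    Plane.SAGITTAL: ("ap", "si"),
    Plane.AXIAL: ("ml", "ap"),
}


def projected_angle(
    v: np.ndarray,
    frame: AnatomicalFrame,
    plane: Plane | str,
    reference: str,
) -> float:
    """Signed angle (degrees) of v projected into a frame plane.

    The vector is projected into the named plane and the angle measured
    from the ``reference`` frame axis ("ml", "ap" or "si", which must lie
    in the plane), counterclockwise about the plane's oriented normal —
    the remaining frame axis, oriented so the plane's ordered axis pair
    (ml→si coronal, ap→si sagittal, ml→ap axial) spans positive angles.
    Result in (-180, 180].
    """
    plane = Plane(plane)
    in_plane = _PLANE_BASIS[plane]
    if reference not in in_plane:
        raise GeometryError(f"reference axis {reference!r} does not lie in the {plane.value} plane")
    v = _as_point(v, "vector")
    n = np.cross(frame.axis(in_plane[0]), frame.axis(in_plane[1]))
    r = frame.axis(reference)
    t = np.cross(n, r)  # in-plane axis 90 deg CCW from the reference about n
    x, y = float(np.dot(v, r)), float(np.dot(v, t))
    if np.hypot(x, y) < 1e-9:
        raise GeometryError(f"vector is orthogonal to the {plane.value} plane (projection norm < 1e-9)")
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def _component_angles(
    anat: AnatomicalFrame,
    comp: AnatomicalFrame,
    component: Component,
    signs: SignConvention,
) -> AngleReport:
    s_cor, s_sag, s_ax = signs.for_component(component)
    vv = s_cor * projected_angle(comp.si_axis, anat, Plane.CORONAL, "si")
    sag = s_sag * projected_angle(comp.si_axis, anat, Plane.SAGITTAL, "si")
    rot = s_ax * projected_angle(comp.ml_axis, anat, Plane.AXIAL, "ml")
    return AngleReport(
        component=component,
        varus_valgus=wrap_degrees(vv),
        sagittal_angle=wrap_degrees(sag),
        axial_rotation=wrap_degrees(rot),
    )


def femoral_component_angles(
    anat: AnatomicalFrame,
    comp: AnatomicalFrame,
    signs: SignConvention = DEFAULT_SIGNS,
) -> AngleReport:
    """Varus–valgus, flexion–extension and axial rotation of the femoral component.

    Coronal and sagittal angles are carried by the component's superior
    axis against the femoral mechanical axis; axial rotation by the
    component's ml axis against the transepicondylar axis.
    """
    return _component_angles(anat, comp, Component.FEMORAL, signs)


def tibial_component_angles(
    anat: AnatomicalFrame,
    comp: AnatomicalFrame,
    signs: SignConvention = DEFAULT_SIGNS,
) -> AngleReport:
    """Varus–valgus, slope and axial rotation of the tibial component.

    ``sagittal_angle`` is the tibial slope (posterior slope negative under
    the default convention); axial rotation is measured against the tibial
    posterior condylar axis.
    """
    return _component_angles(anat, comp, Component.TIBIAL, signs)


def rotational_mismatch(fem: AngleReport, tib: AngleReport) -> float:
    """Femoral minus tibial axial rotation, wrapped into (-180, 180] degrees."""
    if Component(fem.component) is not Component.FEMORAL or Component(tib.component) is not Component.TIBIAL:
        raise GeometryError("rotational_mismatch expects a femoral and a tibial report, in that order")
    return wrap_degrees(fem.axial_rotation - tib.axial_rotation)


def tibiofemoral_angle(
    landmarks: LandmarkSet,
    signs: SignConvention = DEFAULT_SIGNS,
) -> float:
    """Coronal-plane mechanical tibiofemoral angle in degrees (varus positive).

    Signed angle, in the femoral frame's coronal plane, between the femoral
    mechanical axis and the tibial mechanical axis (ankle → tibial knee
    center).  Collinear axes give 0.
    """
    frame = femoral_frame(landmarks)
    landmarks.require(("knee_center_tibia", "ankle_center"))
    tib_mech = _unit(
        landmarks["knee_center_tibia"] - landmarks["ankle_center"], "mechanical tibial axis"
    )
    return wrap_degrees(signs.tibiofemoral * projected_angle(tib_mech, frame, Plane.CORONAL, "si"))
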