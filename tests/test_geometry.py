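"""Frame construction, projected angles, and component-angle measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_rotation
from ukaspect.errors import GeometryError, MissingLandmarkError
from ukaspect.geometry import (
    AngleReport,
    Component,
    DEFAULT_SIGNS,
    LandmarkSet,
    Plane,
    component_frame,
    femoral_component_angles,
    femoral_frame,
    projected_angle,
    rotational_mismatch,
    tibial_component_angles,
    tibial_frame,
    tibiofemoral_angle,
    wrap_degrees,
)
from ukaspect.io import measure_angles
from ukaspect.phantom import generate_landmark_case, template_landmarks

RNG = np.random.default_rng(42)


def axis_aligned_femoral():
    return LandmarkSet(
        {
            "femoral_head_center": [0, 0, 400],
            "knee_center_femur": [0, 0, 0],
            "medial_epicondyle": [-45, 0, 0],
            "lateral_epicondyle": [45, 0, 0],
        }
    )


def test_femoral_frame_axis_aligned():
    frame = femoral_frame(axis_aligned_femoral())
    np.testing.assert_allclose(frame.ml_axis, [1, 0, 0], atol=1e-12)
    np.testing.assert_allclose(frame.si_axis, [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(frame.ap_axis, [0, 1, 0], atol=1e-12)
    np.testing.assert_allclose(frame.origin, [0, 0, 0], atol=1e-12)


def test_femoral_frame_rotation_equivariance():
    """Rigidly rotating all landmarks rotates the frame axes identically."""
    base = axis_aligned_femoral()
    frame0 = femoral_frame(base)
    for _ in range(20):
        R = random_rotation(RNG)
        t = RNG.uniform(-50, 50, 3)
        frame = femoral_frame(base.transformed(R, t))
        np.testing.assert_allclose(frame.rotation, R @ frame0.rotation, atol=1e-9)
        np.testing.assert_allclose(frame.origin, R @ frame0.origin + t, atol=1e-9)


def test_femoral_frame_degenerate_parallel_axes():
    lm = LandmarkSet(
        {
            "femoral_head_center": [0, 0, 400],
            "knee_center_femur": [0, 0, 0],
            "medial_epicondyle": [0, 0, -45],
            "lateral_epicondyle": [0, 0, 45],  # epicondylar axis parallel to mechanical axis
        }
    )
    with pytest.raises(GeometryError):
        femoral_frame(lm)


def test_femoral_frame_coincident_points():
    lm = LandmarkSet(
        {
            "femoral_head_center": [0, 0, 0],
            "knee_center_femur": [0, 0, 0],
            "medial_epicondyle": [-45, 0, 0],
            "lateral_epicondyle": [45, 0, 0],
        }
    )
    with pytest.raises(GeometryError):
        femoral_frame(lm)


def test_missing_landmark_named():
    with pytest.raises(MissingLandmarkError, match="ankle_center"):
        tibial_frame(LandmarkSet({"knee_center_tibia": [0, 0, 0]}))


def test_tibial_frame_orthonormal_on_random_landmarks():
    """Gram-matrix oracle: frames from 1000 random valid landmark sets are
    orthonormal right-handed triads."""
    for _ in range(1000):
        knee = RNG.uniform(-100, 100, 3)
        ankle = knee + RNG.uniform(300, 450) * -_unit(RNG.normal(size=3))
        ml_dir = _unit(RNG.normal(size=3))
        lm = LandmarkSet(
            {
                "knee_center_tibia": knee,
                "ankle_center": ankle,
                "tibia_posterior_condyle_medial": knee - 25 * ml_dir + [0, -20, -5],
                "tibia_posterior_condyle_lateral": knee + 25 * ml_dir + [0, -20, -5],
            }
        )
        try:
            frame = tibial_frame(lm)
        except GeometryError:
            continue  # ml direction drawn (anti)parallel to the mechanical axis
        R = frame.rotation
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) > 0


def _unit(v):
    return v / np.linalg.norm(v)


def test_tibial_frame_coincident_condyles():
    lm = LandmarkSet(
        {
            "knee_center_tibia": [0, 0, 0],
            "ankle_center": [0, 0, -380],
            "tibia_posterior_condyle_medial": [5, -20, -5],
            "tibia_posterior_condyle_lateral": [5, -20, -5],
        }
    )
    with pytest.raises(GeometryError):
        tibial_frame(lm)


def test_component_frame_identity_and_rotated():
    frame = component_frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
    np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-12)
    for _ in range(50):
        R = random_rotation(RNG)
        rotated = component_frame([0, 0, 0], R @ [1.0, 0, 0], R @ [0.0, 1, 0])
        np.testing.assert_allclose(rotated.rotation, R, atol=1e-9)


def test_component_frame_collinear_fiducials():
    with pytest.raises(GeometryError):
        component_frame([0, 0, 0], [1, 0, 0], [2, 0, 0])


def test_projected_angle_reference_and_constructed():
    frame = component_frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
    assert projected_angle(frame.ml_axis, frame, Plane.CORONAL, "ml") == 0.0
    v = np.cos(np.radians(30)) * frame.ml_axis + np.sin(np.radians(30)) * frame.si_axis
    assert projected_angle(v, frame, Plane.CORONAL, "ml") == pytest.approx(30.0, abs=1e-12)


def test_projected_angle_orthogonal_vector_errors():
    frame = component_frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
    with pytest.raises(GeometryError):
        projected_angle(frame.ap_axis, frame, Plane.CORONAL, "ml")


def test_projected_angle_matches_explicit_oracle():
    """Independent oracle: explicit projection onto the plane + atan2 about
    the plane normal, on random frames and vectors."""
    for _ in range(10_000 // 4):
        R = random_rotation(RNG)
        frame = component_frame([0, 0, 0], R @ [1.0, 0, 0], R @ [0.0, 1, 0])
        v = RNG.normal(size=3)
        for plane, axes in {
            Plane.CORONAL: ("ml", "si"),
            Plane.SAGITTAL: ("ap", "si"),
            Plane.AXIAL: ("ml", "ap"),
        }.items():
            n = np.cross(frame.axis(axes[0]), frame.axis(axes[1]))
            v_proj = v - np.dot(v, n) * n
            if np.linalg.norm(v_proj) < 1e-6:
                continue
            for ref in axes:
                r = frame.axis(ref)
                cos_part = np.dot(v_proj, r)
                sin_part = np.dot(np.cross(r, v_proj), n)
                expected = wrap_degrees(np.degrees(np.arctan2(sin_part, cos_part)))
                got = projected_angle(v, frame, plane, ref)
                assert got == pytest.approx(expected, abs=1e-9)


def test_component_angles_identity_is_zero(template):
    fem, tib, mismatch, tfa = measure_angles(template)
    for rep in (fem, tib):
        assert rep.varus_valgus == 0.0
        assert rep.sagittal_angle == 0.0
        assert rep.axial_rotation == 0.0
    assert mismatch == 0.0
    assert tfa == 0.0


@pytest.mark.parametrize("angle", [7.0, -3.5])
def test_single_axis_coronal_rotation(angle):
    """Rotating the component frame about the anatomical AP axis shows up as
    varus-valgus only (magnitude preserved, sign per convention table)."""
    lm = axis_aligned_femoral()
    anat = femoral_frame(lm)
    theta = np.radians(angle)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])  # rotation about ap = +y
    comp = component_frame([0, 0, 0], R @ anat.ml_axis, R @ anat.ap_axis)
    rep = femoral_component_angles(anat, comp)
    assert abs(rep.varus_valgus) == pytest.approx(abs(angle), abs=1e-9)
    assert rep.sagittal_angle == pytest.approx(0.0, abs=1e-9)
    assert rep.axial_rotation == pytest.approx(0.0, abs=1e-9)


def test_single_axis_sagittal_rotation_tibia():
    lm = template_landmarks()
    anat = tibial_frame(lm)
    theta = np.radians(5.0)
    c, s = np.cos(theta), np.sin(theta)
    Rx = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])  # about anatomical ml = +x
    R = anat.rotation @ Rx @ anat.rotation.T
    comp = component_frame(anat.origin, anat.origin + R @ anat.ml_axis, anat.origin + R @ anat.ap_axis)
    rep = tibial_component_angles(anat, comp)
    assert abs(rep.sagittal_angle) == pytest.approx(5.0, abs=1e-9)
    assert rep.varus_valgus == pytest.approx(0.0, abs=1e-9)
    assert rep.axial_rotation == pytest.approx(0.0, abs=1e-9)


def test_angle_round_trip_random_poses():
    """Forward-generation oracle: landmark cases built from target angles are
    measured back to those targets within 1e-6 degrees."""
    rng = np.random.default_rng(7)
    worst = 0.0
    for i in range(200):
        fem_t = AngleReport(Component.FEMORAL, *rng.uniform(-20, 20, 3))
        tib_t = AngleReport(Component.TIBIAL, *rng.uniform(-20, 20, 3))
        tfa_t = float(rng.uniform(-15, 15))
        case = generate_landmark_case(fem_t, tib_t, tfa_t, seed=i, rigid_jitter=bool(i % 2))
        fem, tib, _, tfa = measure_angles(case)
        errs = [
            fem.varus_valgus - fem_t.varus_valgus,
            fem.sagittal_angle - fem_t.sagittal_angle,
            fem.axial_rotation - fem_t.axial_rotation,
            tib.varus_valgus - tib_t.varus_valgus,
            tib.sagittal_angle - tib_t.sagittal_angle,
            tib.axial_rotation - tib_t.axial_rotation,
            tfa - tfa_t,
        ]
        worst = max(worst, max(abs(e) for e in errs))
    assert worst < 1e-6


@pytest.mark.parametrize(
    "fem_rot,tib_rot,expected",
    [(3.0, 3.0, 0.0), (5.0, -5.0, 10.0), (179.0, -179.0, -2.0)],
)
def test_rotational_mismatch_wraps(fem_rot, tib_rot, expected):
    fem = AngleReport(Component.FEMORAL, 0.0, 0.0, fem_rot)
    tib = AngleReport(Component.TIBIAL, 0.0, 0.0, tib_rot)
    assert rotational_mismatch(fem, tib) == pytest.approx(expected, abs=1e-12)


def test_rotational_mismatch_requires_ordered_components():
    rep = AngleReport(Component.FEMORAL, 0.0, 0.0, 1.0)
    with pytest.raises(GeometryError):
        rotational_mismatch(rep, rep)


def test_tibiofemoral_angle_construction(template):
    assert tibiofemoral_angle(template) == 0.0
    # displace the ankle purely in the coronal plane for a constructed 5 deg
    pts = dict(template.points)
    knee_t = pts["knee_center_tibia"]
    L = 380.0
    theta = np.radians(5.0 / DEFAULT_SIGNS.tibiofemoral)
    pts["ankle_center"] = knee_t - L * np.array([-np.sin(theta), 0.0, np.cos(theta)])
    assert tibiofemoral_angle(LandmarkSet(pts)) == pytest.approx(5.0, abs=1e-9)


def test_all_angles_rigid_transform_invariant(phantom_case, truth):
    """Equivariance: a rigid transform of every landmark leaves all reported
    angles unchanged within 1e-9 degrees."""
    base = measure_angles(phantom_case)
    base_tfa = base[3]
    for s in range(10):
        rng = np.random.default_rng(100 + s)
        moved = phantom_case.transformed(random_rotation(rng), rng.uniform(-200, 200, 3))
        fem, tib, mismatch, tfa = measure_angles(moved)
        assert fem.varus_valgus == pytest.approx(base[0].varus_valgus, abs=1e-9)
        assert fem.sagittal_angle == pytest.approx(base[0].sagittal_angle, abs=1e-9)
        assert fem.axial_rotation == pytest.approx(base[0].axial_rotation, abs=1e-9)
        assert tib.varus_valgus == pytest.approx(base[1].varus_valgus, abs=1e-9)
        assert tib.sagittal_angle == pytest.approx(base[1].sagittal_angle, abs=1e-9)
        assert tib.axial_rotation == pytest.approx(base[1].axial_rotation, abs=1e-9)
        assert mismatch == pytest.approx(base[2], abs=1e-9)
        assert tfa == pytest.approx(base_tfa, abs=1e-9)


@settings(derandomize=True, max_examples=500)
@given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
def test_wrap_degrees_range_and_idempotence(angle):
    w = wrap_degrees(angle)
    assert -180.0 < w <= 180.0
    assert wrap_degrees(w) == w
    # wrapping preserves the angle modulo full turns
    assert abs((angle - w) % 360.0) < 1e-6 or abs((angle - w) % 360.0 - 360.0) < 1e-6


def test_angle_report_rejects_out_of_range():
    with pytest.raises(GeometryError):
        AngleReport(Component.FEMORAL, 181.0, 0.0, 0.0)
    with pytest.raises(GeometryError):
        AngleReport(Component.FEMORAL, float("nan"), 0.0, 0.0)
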