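"""Region boxes, voxel statistics and background-normalized ratios."""

import numpy as np
import pytest

from conftest import random_rotation
from ukaspect.config import BoxConfig
from ukaspect.errors import BackgroundError, ConfigError, QuantificationError
from ukaspect.geometry import AnatomicalFrame
from ukaspect.phantom import phantom_grid
from ukaspect.scheme import statistic_map
from ukaspect.uptake import (
    BACKGROUND_KEY,
    IntensityVolume,
    RegionBox,
    background_reference,
    build_region_boxes,
    quantify_region,
    uptake_report,
)

RNG = np.random.default_rng(123)


def brute_force_statistic(volume, box, statistic):
    """Independent oracle: explicit per-voxel loop with its own membership test."""
    lo, hi = box.frame_bounds()
    R = box.frame.rotation
    origin = box.frame.origin
    values = []
    nx, ny, nz = volume.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = volume.origin + volume.direction @ (volume.spacing * np.array([i, j, k]))
                local = R.T @ (p - origin)
                if all(lo[d] <= local[d] < hi[d] for d in range(3)):
                    values.append(volume.voxels[i, j, k])
    if not values:
        return None
    return max(values) if statistic == "max" else sum(values) / len(values)


def small_volume(shape=(12, 12, 12), spacing=2.0, origin=(-10.0, -10.0, -10.0), values=None):
    vox = RNG.uniform(0, 100, size=shape) if values is None else values
    return IntensityVolume(vox, [spacing] * 3, origin, np.eye(3))


def centered_box(frame=None, center=(0, 0, 0), half=(6, 6, 6), label="F1ia"):
    frame = frame or AnatomicalFrame([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
    return RegionBox(label, frame, np.asarray(center, float), np.asarray(half, float))


def test_uniform_volume_any_box():
    vol = small_volume(values=np.full((12, 12, 12), 7.5))
    box = centered_box()
    assert quantify_region(vol, box, "max") == 7.5
    assert quantify_region(vol, box, "mean") == 7.5


def test_single_hot_voxel_max():
    vox = np.zeros((12, 12, 12))
    vox[5, 5, 5] = 100.0  # world (0, 0, 0): inside the box
    vol = small_volume(values=vox)
    assert quantify_region(vol, centered_box(), "max") == 100.0


def test_empty_box_names_region():
    vol = small_volume()
    far = centered_box(center=(500, 500, 500), label="T3ia")
    with pytest.raises(QuantificationError, match="T3ia"):
        quantify_region(vol, far, "max")


def test_quantify_matches_brute_force_oracle():
    """50 random volume/box pairs: exact agreement for max, <=1e-12 relative
    for mean, against an independent triple-loop oracle."""
    for trial in range(50):
        rng = np.random.default_rng(1000 + trial)
        shape = tuple(rng.integers(6, 14, 3))
        spacing = float(rng.uniform(1.0, 3.0))
        origin = rng.uniform(-15, -5, 3)
        vol = IntensityVolume(rng.uniform(0, 100, shape), [spacing] * 3, origin, np.eye(3))
        R = random_rotation(rng)
        frame = AnatomicalFrame(rng.uniform(-5, 5, 3), R[:, 0], R[:, 1], R[:, 2])
        box = RegionBox("F1ia", frame, rng.uniform(-5, 10, 3), rng.uniform(4, 12, 3))
        expected_max = brute_force_statistic(vol, box, "max")
        if expected_max is None:
            with pytest.raises(QuantificationError):
                quantify_region(vol, box, "max")
            continue
        assert quantify_region(vol, box, "max") == expected_max
        expected_mean = brute_force_statistic(vol, box, "mean")
        assert quantify_region(vol, box, "mean") == pytest.approx(expected_mean, rel=1e-12)


def test_monotonicity_of_max():
    vol = small_volume()
    box = centered_box()
    before = quantify_region(vol, box, "max")
    vox = vol.voxels.copy()
    vox[5, 5, 5] = vox[5, 5, 5] + 50.0
    bumped = IntensityVolume(vox, vol.spacing, vol.origin, vol.direction)
    assert quantify_region(bumped, box, "max") >= before


def test_build_boxes_count_and_disjointness(template, template_boxes):
    assert set(template_boxes) == {r for r in statistic_map()} | {BACKGROUND_KEY}
    assert len(template_boxes) == 25
    shape, origin = phantom_grid(template_boxes, 2.0)
    vol = IntensityVolume(np.zeros(shape), [2.0] * 3, origin, np.eye(3))
    centers = vol.voxel_centers()
    claimed = np.zeros(centers.shape[0], dtype=bool)
    for label, box in template_boxes.items():
        mask = box.contains(centers)
        assert mask.any(), f"box {label} is empty on a 2 mm grid"
        assert not (mask & claimed).any(), f"box {label} overlaps another box"
        claimed |= mask


def test_zone3_width_config_pass_through(template):
    w = 22.0
    boxes = build_region_boxes(template, BoxConfig(zone3_ml_width_mm=w))
    for label in ("T3sp", "T3sa", "T3ia", "T3ip"):
        assert boxes[label].half_extents[0] == pytest.approx(w / 2.0)


def test_boxes_rigid_transform_equivariance(template):
    base = build_region_boxes(template, BoxConfig())
    rng = np.random.default_rng(5)
    R, t = random_rotation(rng), rng.uniform(-100, 100, 3)
    moved = build_region_boxes(template.transformed(R, t), BoxConfig())
    for label, box in base.items():
        np.testing.assert_allclose(moved[label].center, R @ box.center + t, atol=1e-9)
        np.testing.assert_allclose(moved[label].half_extents, box.half_extents, atol=1e-12)


def test_background_box_midpoint(template, template_boxes):
    # head at z=400, knee at z=0, fraction 0.5 -> center z = 200
    np.testing.assert_allclose(template_boxes[BACKGROUND_KEY].center, [0, 0, 200], atol=1e-12)


def test_background_reference_uniform_and_guard(template, template_boxes):
    shape, origin = phantom_grid(template_boxes, 4.0)
    uniform = IntensityVolume(np.full(shape, 50.0), [4.0] * 3, origin, np.eye(3))
    assert background_reference(uniform, template, BoxConfig(), boxes=template_boxes) == 50.0
    zero = IntensityVolume(np.zeros(shape), [4.0] * 3, origin, np.eye(3))
    with pytest.raises(BackgroundError):
        background_reference(zero, template, BoxConfig(), boxes=template_boxes)


def test_uptake_report_ratios(template, template_boxes):
    shape, origin = phantom_grid(template_boxes, 4.0)
    vol = IntensityVolume(np.full(shape, 50.0), [4.0] * 3, origin, np.eye(3))
    records = uptake_report(vol, template_boxes, background=50.0)
    assert [r.region for r in records] == list(statistic_map())
    assert all(r.ratio == 1.0 for r in records)
    assert all(r.statistic == statistic_map()[r.region] for r in records)


def test_ratio_division():
    vol = small_volume(values=np.full((12, 12, 12), 200.0))
    frame = AnatomicalFrame([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
    boxes = {label: centered_box(frame, label=label) for label in statistic_map()}
    records = uptake_report(vol, boxes, background=50.0)
    assert all(r.ratio == 4.0 for r in records)


def test_gain_invariance_of_ratios(template, template_boxes):
    """Scaling the volume by k scales absolutes by k and leaves ratios fixed."""
    shape, origin = phantom_grid(template_boxes, 4.0)
    rng = np.random.default_rng(9)
    vox = rng.uniform(1, 100, shape)
    vol = IntensityVolume(vox, [4.0] * 3, origin, np.eye(3))
    bg = background_reference(vol, template, BoxConfig(), boxes=template_boxes)
    base = uptake_report(vol, template_boxes, bg)
    k = 3.7
    scaled_vol = IntensityVolume(k * vox, [4.0] * 3, origin, np.eye(3))
    bg_k = background_reference(scaled_vol, template, BoxConfig(), boxes=template_boxes)
    scaled = uptake_report(scaled_vol, template_boxes, bg_k)
    for r0, r1 in zip(base, scaled):
        assert r1.absolute == pytest.approx(k * r0.absolute, rel=1e-12)
        assert r1.ratio == pytest.approx(r0.ratio, rel=1e-12)


def test_translation_equivariance_of_records(template, template_boxes):
    """Translating landmarks and volume origin identically leaves records unchanged."""
    shape, origin = phantom_grid(template_boxes, 4.0)
    rng = np.random.default_rng(13)
    vox = rng.uniform(1, 100, shape)
    t = np.array([12.0, -7.0, 31.0])
    vol = IntensityVolume(vox, [4.0] * 3, origin, np.eye(3))
    vol_t = IntensityVolume(vox, [4.0] * 3, origin + t, np.eye(3))
    lm_t = template.transformed(np.eye(3), t)
    boxes_t = build_region_boxes(lm_t, BoxConfig())
    base = uptake_report(vol, template_boxes, 50.0)
    moved = uptake_report(vol_t, boxes_t, 50.0)
    for r0, r1 in zip(base, moved):
        assert r1.absolute == pytest.approx(r0.absolute, rel=1e-12)


def test_config_validation():
    with pytest.raises(ConfigError):
        BoxConfig(zone3_ml_width_mm=-1.0)
    with pytest.raises(ConfigError):
        BoxConfig(background_fraction=1.5)
    with pytest.raises(ConfigError):
        BoxConfig.from_dict({"zone3_width": 10.0})  # unknown key


def test_volume_invariants():
    from ukaspect.errors import VolumeError

    with pytest.raises(VolumeError):
        IntensityVolume(np.zeros((2, 2)), [1, 1, 1], [0, 0, 0], np.eye(3))
    with pytest.raises(VolumeError):
        IntensityVolume(np.zeros((4, 4, 4)), [1, -1, 1], [0, 0, 0], np.eye(3))
    with pytest.raises(VolumeError):
        IntensityVolume(np.zeros((4, 4, 4)), [1, 1, 1], [0, 0, 0], np.ones((3, 3)))
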