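"""Label-map measurements recover the phantom's analytic ground truth."""

import math

import numpy as np
import pytest

import pediplan as pp
from pediplan.anatomy import cylinder_surface_points, _free_wall_boundary_points
from pediplan.errors import (
    MissingStructureError,
    NoIntersectionError,
    NotInPedicleError,
)
from conftest import tube_label_map


def angle_deg(u, v):
    return math.degrees(math.acos(min(1.0, abs(float(np.dot(u, v))))))


# ---------------------------------------------------------------------------
# Axis
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fixture", ["default_phantom", "angled_phantom"])
def test_axis_within_2_degrees_of_truth(fixture, request):
    ph = request.getfixturevalue(fixture)
    for side in ("L", "R"):
        ax = pp.estimate_pedicle_axis(ph.labels, side)
        truth_d = np.asarray(ph.truth.pedicles[side].axis_direction)
        assert angle_deg(ax.d, truth_d) < 2.0
        assert ax.d[1] > 0  # posterior -> anterior orientation


def test_axis_missing_structure():
    ph = pp.make_phantom(pp.PhantomSpec())
    lab = ph.labels.labels.copy()
    lab[lab == pp.PEDICLE_L] = pp.BACKGROUND
    erased = pp.AnatomyLabelMap(
        voxel_spacing_mm=ph.labels.voxel_spacing_mm,
        origin_mm=ph.labels.origin_mm,
        labels=lab,
    )
    with pytest.raises(MissingStructureError):
        pp.estimate_pedicle_axis(erased, "L")


# ---------------------------------------------------------------------------
# Width
# ---------------------------------------------------------------------------

def test_width_recovered_within_one_voxel_at_half_mm(half_mm_phantom):
    ph = half_mm_phantom
    for side in ("L", "R"):
        W = pp.measure_pedicle_width(ph.labels, side)
        assert W == pytest.approx(ph.truth.W, abs=0.5)


def test_width_of_circular_tube_is_diameter():
    labels = tube_label_map(radius_mm=4.0, with_body=False)
    axis = pp.AxisLine((0.0, 10.0, 0.0), (0.0, 1.0, 0.0))
    W = pp.measure_pedicle_width(labels, "L", axis=axis)
    assert W == pytest.approx(8.0, abs=0.5)


def test_width_monotone_in_tube_radius():
    widths = []
    for r in (3.0, 4.0, 5.0):
        labels = tube_label_map(radius_mm=r, with_body=False)
        axis = pp.AxisLine((0.0, 10.0, 0.0), (0.0, 1.0, 0.0))
        widths.append(pp.measure_pedicle_width(labels, "L", axis=axis))
    assert widths[0] <= widths[1] <= widths[2]


def test_width_sweep_error_bounded_by_spacing():
    """Recovery error <= max voxel spacing across the clinical width range."""
    for w in np.linspace(6.0, 14.0, 5):
        ph = pp.make_phantom(
            pp.PhantomSpec(pedicle_width_mm=float(w), pedicle_height_mm=max(12.0, w + 2.0))
        )
        W = pp.measure_pedicle_width(ph.labels, "L")
        assert abs(W - w) <= ph.labels.voxel_spacing_mm.max()


# ---------------------------------------------------------------------------
# Entry candidates
# ---------------------------------------------------------------------------

def test_entry_candidate_count_matches_disc_area(default_phantom):
    cands = pp.entry_candidates(default_phantom.labels, "L", grid_step_mm=1.0)
    # disc radius 3 mm -> area ~28 mm^2 -> 20..40 one-mm bins after voxelization
    assert 20 <= len(cands) <= 40


def test_entry_candidates_within_disc_radius(default_phantom):
    ph = default_phantom
    for side in ("L", "R"):
        cands = pp.entry_candidates(ph.labels, side, 1.0)
        center = np.asarray(ph.truth.pedicles[side].entry_center_mm)
        radius = ph.truth.pedicles[side].entry_radius_mm
        d = np.linalg.norm(cands[:, [0, 2]] - center[[0, 2]], axis=1)
        assert d.max() <= radius + 1e-9


def test_entry_grid_larger_than_disc_gives_single_candidate(default_phantom):
    cands = pp.entry_candidates(default_phantom.labels, "L", grid_step_mm=20.0)
    assert len(cands) == 1
    center = np.asarray(default_phantom.truth.pedicles["L"].entry_center_mm)
    assert np.linalg.norm(cands[0] - center) < 1.0


def test_entry_candidates_missing_disc(default_phantom):
    lab = default_phantom.labels.labels.copy()
    lab[lab == pp.ENTRY_DISC_R] = pp.POSTERIOR_ELEMENTS
    erased = pp.AnatomyLabelMap(
        voxel_spacing_mm=default_phantom.labels.voxel_spacing_mm,
        origin_mm=default_phantom.labels.origin_mm,
        labels=lab,
    )
    with pytest.raises(MissingStructureError):
        pp.entry_candidates(erased, "R")


# ---------------------------------------------------------------------------
# Depth to anterior cortex
# ---------------------------------------------------------------------------

def test_depth_along_axis_matches_truth(default_phantom):
    ph = default_phantom
    for side in ("L", "R"):
        ped = ph.truth.pedicles[side]
        d = pp.depth_to_anterior(ph.labels, ped.entry_center_mm, ped.axis_direction)
        assert d == pytest.approx(
            ped.anterior_depth_mm, abs=ph.labels.voxel_spacing_mm.max()
        )


def test_depth_posterior_ray_raises(default_phantom):
    ped = default_phantom.truth.pedicles["L"]
    start = np.asarray(ped.entry_center_mm) + np.array([0.0, -2.0, 0.0])  # in air
    with pytest.raises(NoIntersectionError):
        pp.depth_to_anterior(default_phantom.labels, start, (0.0, -1.0, 0.0))


def test_depth_decreases_moving_entry_anteriorly(default_phantom):
    ped = default_phantom.truth.pedicles["L"]
    e0 = np.asarray(ped.entry_center_mm)
    d = np.asarray(ped.axis_direction)
    depths = [
        pp.depth_to_anterior(default_phantom.labels, e0 + s * d, d)
        for s in (0.0, 2.0, 5.0, 10.0)
    ]
    assert all(b <= a + 1e-9 for a, b in zip(depths, depths[1:]))


# ---------------------------------------------------------------------------
# Wall clearance
# ---------------------------------------------------------------------------

def clearance_oracle(labels, screw, wall_dir, axis):
    """Brute force: dense cylinder surface sampling, min signed distance to
    the wall-cone boundary voxels (same convention, 10x denser sampling)."""
    from pediplan.volume import CONTAINMENT_LABELS

    b_pts = _free_wall_boundary_points(labels, screw.side)
    tb = (b_pts - axis.p) @ axis.d
    radial = b_pts - axis.p - np.outer(tb, axis.d)
    rn = np.linalg.norm(radial, axis=1)
    rn[rn == 0] = 1
    wall = b_pts[(radial @ wall_dir) / rn >= np.cos(np.pi / 4)]
    pts, normals = cylinder_surface_points(
        screw.entry_mm, screw.direction, screw.length_mm, screw.diameter_mm / 2,
        axial_step_mm=0.04, n_angles=480,
    )
    t = (pts - axis.p) @ axis.d
    wt = (_free_wall_boundary_points(labels, screw.side) - axis.p) @ axis.d
    lo, hi = np.percentile(wt, [10, 90])
    keep = (t >= lo) & (t <= hi) & (normals @ wall_dir >= np.cos(np.pi / 4))
    pts = pts[keep]
    lab = labels.labels_at(pts)
    sign = np.where(np.isin(lab, list(CONTAINMENT_LABELS)), 1.0, -1.0)
    d = np.linalg.norm(pts[:, None, :] - wall[None, :, :], axis=2).min(axis=1)
    half = labels.voxel_spacing_mm.mean() / 2
    return float(np.min(sign * d + half))


def test_clearance_centered_screw_in_circular_tube():
    labels = tube_label_map(radius_mm=4.0, spacing=0.5)
    screw = pp.ScrewSpec("L", (0.0, 0.0, 0.0), (0.0, 1.0, 0.0), 40.0, 6.0)
    rep = pp.wall_clearance(labels, screw)
    expected = (8.0 - 6.0) / 2.0
    assert rep.medial_clearance_mm == pytest.approx(expected, abs=0.6)
    assert rep.inferior_clearance_mm == pytest.approx(expected, abs=0.6)


def test_clearance_shifts_with_medial_translation():
    labels = tube_label_map(radius_mm=4.5, spacing=0.5)
    centered = pp.ScrewSpec("L", (0.0, 0.0, 0.0), (0.0, 1.0, 0.0), 40.0, 5.0)
    shifted = pp.ScrewSpec("L", (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), 40.0, 5.0)
    c0 = pp.wall_clearance(labels, centered)
    c1 = pp.wall_clearance(labels, shifted)
    # medial = +x here (trabecular block centered on the tube axis midline);
    # the medial wall loses ~1 mm, the inferior wall is second-order
    assert (
        c0.medial_clearance_mm - c1.medial_clearance_mm
        == pytest.approx(1.0, abs=0.35)
    )
    assert abs(c0.inferior_clearance_mm - c1.inferior_clearance_mm) < 0.5


def test_clearance_near_zero_at_full_width():
    labels = tube_label_map(radius_mm=4.0, spacing=0.5)
    screw = pp.ScrewSpec("L", (0.0, 0.0, 0.0), (0.0, 1.0, 0.0), 40.0, 8.0)
    rep = pp.wall_clearance(labels, screw)
    assert abs(rep.medial_clearance_mm) < 0.6
    assert abs(rep.inferior_clearance_mm) < 0.6


def test_clearance_matches_dense_oracle(default_phantom):
    ph = default_phantom
    axis = pp.estimate_pedicle_axis(ph.labels, "L")
    ped = ph.truth.pedicles["L"]
    rng = np.random.default_rng(4)
    from pediplan.anatomy import _medial_direction

    medial = _medial_direction(ph.labels, axis)
    for _ in range(5):
        entry = np.asarray(ped.entry_center_mm) + rng.normal(0, 0.8, 3)
        d = np.asarray(ped.axis_direction) + rng.normal(0, 0.03, 3)
        d /= np.linalg.norm(d)
        screw = pp.ScrewSpec("L", tuple(entry), tuple(d), 40.0, 6.0)
        rep = pp.wall_clearance(ph.labels, screw, axis=axis)
        assert rep.medial_clearance_mm == pytest.approx(
            clearance_oracle(ph.labels, screw, medial, axis), abs=0.2
        )
        assert rep.inferior_clearance_mm == pytest.approx(
            clearance_oracle(ph.labels, screw, np.array([0.0, 0.0, -1.0]), axis), abs=0.2
        )


def test_clearance_requires_pedicle_overlap(default_phantom):
    screw = pp.ScrewSpec("L", (0.0, 45.0, 0.0), (0.0, 1.0, 0.0), 10.0, 5.0)
    with pytest.raises(NotInPedicleError):
        pp.wall_clearance(default_phantom.labels, screw)


# ---------------------------------------------------------------------------
# Translation invariance
# ---------------------------------------------------------------------------

def test_measurements_invariant_under_grid_translation():
    """Shifting the world origin leaves all measurements identical."""
    ph = pp.make_phantom(pp.PhantomSpec())
    shifted = pp.AnatomyLabelMap(
        voxel_spacing_mm=ph.labels.voxel_spacing_mm,
        origin_mm=ph.labels.origin_mm + np.array([5.0, -3.0, 2.0]),
        labels=ph.labels.labels.copy(),
    )
    w0 = pp.measure_pedicle_width(ph.labels, "L")
    w1 = pp.measure_pedicle_width(shifted, "L")
    assert w1 == pytest.approx(w0, abs=1e-6)
    a0 = pp.estimate_pedicle_axis(ph.labels, "L")
    a1 = pp.estimate_pedicle_axis(shifted, "L")
    assert np.allclose(a1.d, a0.d, atol=1e-9)
    assert np.allclose(np.asarray(a1.point_mm) - np.asarray(a0.point_mm), [5.0, -3.0, 2.0], atol=1e-6)
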