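"""Measurements on a label map that feed the planner's placement rules.

All quantities are derived from the label map alone (never from phantom
truth): the pedicle axis, the pedicle width W that caps screw diameter at
0.9*W, the admissible entry points, the depth from an entry point to the
outer anterior cortex ("vertebral front end") that caps screw length, and
the medial/inferior wall clearances that must stay >= the safety margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConfigError,
    GridTruncationError,
    MissingStructureError,
    NoIntersectionError,
    NotInPedicleError,
    StructureTooSmallError,
)
from .volume import (
    BACKGROUND,
    CONTAINMENT_LABELS,
    ENTRY_DISC_LABEL,
    PEDICLE_LABEL,
    TRABECULAR_BODY,
    AnatomyLabelMap,
)

INFERIOR = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class AxisLine:
    """A line in world mm: point + unit direction (posterior -> anterior)."""

    point_mm: tuple
    direction: tuple

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("AxisLine direction must be a unit vector")

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.point_mm, dtype=float)

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass(frozen=True)
class ClearanceReport:
    """Min distances (mm) from a screw surface to the medial / inferior
    pedicle walls; negative values encode wall penetration."""

    medial_clearance_mm: float
    inferior_clearance_mm: float


def _pedicle_points(labels: AnatomyLabelMap, side: str) -> np.ndarray:
    def build():
        mask = labels.mask(PEDICLE_LABEL[side])
        if not mask.any():
            raise MissingStructureError(f"pedicle label {side} is empty")
        return labels.voxel_centers(mask)

    return labels.cache(("ped_pts", side), build)


def estimate_pedicle_axis(
    labels: AnatomyLabelMap, side: str, slab_mm: float = 2.0
) -> AxisLine:
    """Fit the pedicle axis as the line through per-slab centroids.

    The voxel cloud's principal direction defines the slab normal; centroids
    of consecutive slabs are then re-fit with a second principal-component
    pass, which removes the bias the raw first pass inherits from the
    asymmetric tube ends.  The direction is oriented posterior -> anterior
    (positive y component).
    """

    def build():
        pts = _pedicle_points(labels, side)
        center = pts.mean(axis=0)
        q = pts - center
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        d0 = vt[0]
        t = q @ d0
        edges = np.arange(t.min(), t.max() + slab_mm, slab_mm)
        centroids, counts = [], []
        for lo in edges[:-1]:
            sel = (t >= lo) & (t < lo + slab_mm)
            if sel.sum() >= 5:
                centroids.append(pts[sel].mean(axis=0))
                counts.append(sel.sum())
        centroids = np.asarray(centroids)
        counts = np.asarray(counts)
        # Keep only slabs with a full tube cross-section: the clipped stubs at
        # the body junction would otherwise drag the fitted line medially.
        if len(counts) >= 3:
            centroids = centroids[counts >= 0.5 * np.median(counts)]
        if len(centroids) < 2:
            raise StructureTooSmallError(
                f"pedicle {side}: fewer than 2 usable slabs for axis fit"
            )
        c0 = centroids.mean(axis=0)
        _, _, vt = np.linalg.svd(centroids - c0, full_matrices=False)
        d = vt[0]
        if d[1] < 0:
            d = -d
        d = d / np.linalg.norm(d)
        return AxisLine(point_mm=tuple(c0), direction=tuple(d))

    return labels.cache(("axis", side, slab_mm), build)


def _inplane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _free_wall_boundary_points(labels: AnatomyLabelMap, side: str) -> np.ndarray:
    """Centers of pedicle voxels with a background 6-neighbor: the free wall
    of the corridor.  Tube ends abutting other bone labels are excluded."""

    def build():
        ped = labels.mask(PEDICLE_LABEL[side])
        if not ped.any():
            raise MissingStructureError(f"pedicle label {side} is empty")
        axis = estimate_pedicle_axis(labels, side)
        bg = labels.labels == BACKGROUND
        boundary = np.zeros_like(ped)
        for ax in range(3):
            # Only radial adjacency defines the wall: background met along
            # the corridor axis (the open tube ends) is not a wall.
            if abs(axis.d[ax]) > 0.7:
                continue
            for shift in (1, -1):
                boundary |= ped & np.roll(bg, shift, axis=ax)
        return labels.voxel_centers(boundary)

    return labels.cache(("wall_boundary", side), build)


def measure_pedicle_width(
    labels: AnatomyLabelMap,
    side: str,
    axis: AxisLine | None = None,
    section_step_mm: float = 0.5,
    n_angles: int = 180,
) -> float:
    """Pedicle width W: the minimum caliper diameter over cross-sections.

    Cross-section planes perpendicular to the axis are sampled at
    ``section_step_mm`` over the middle 80% of the corridor's *free* span
    (where the corridor has background-adjacent walls; sections at the two
    junctions, clipped by the vertebral body or the posterior elements,
    would report sliver widths).  Within each section the footprint is the
    set of voxel boxes whose centers fall in a one-voxel-thick slab; its
    caliper width along an in-plane direction u is (extent of centers along
    u) + the voxel box support width along u, minimised over ``n_angles``
    directions.
    """
    if axis is None:
        axis = estimate_pedicle_axis(labels, side)
    pts = _pedicle_points(labels, side)
    spacing = labels.voxel_spacing_mm
    t = (pts - axis.p) @ axis.d
    b_pts = _free_wall_boundary_points(labels, side)
    t_b = (b_pts - axis.p) @ axis.d
    span = t_b.max() - t_b.min()
    lo, hi = t_b.min() + 0.1 * span, t_b.max() - 0.1 * span
    centers = np.arange(lo, hi + 1e-9, section_step_mm)
    half = max(float(spacing.max()), section_step_mm) / 2.0

    e1, e2 = _inplane_basis(axis.d)
    phis = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    dirs = np.outer(np.cos(phis), e1) + np.outer(np.sin(phis), e2)  # (nphi, 3)
    support = np.abs(dirs) @ (spacing / 2.0) * 2.0  # voxel box width along u

    # A usable section must have its wall boundary all around the axis:
    # where the corridor merges into the body or the posterior elements, part
    # of the wall disappears and the clipped footprint would report a sliver
    # width.  Completeness = every 45-degree sector holds boundary voxels.
    b_rad = b_pts - axis.p - np.outer(t_b, axis.d)
    b_ang = np.arctan2(b_rad @ e2, b_rad @ e1)
    b_sector = ((b_ang + np.pi) / (np.pi / 4.0)).astype(int) % 8

    widths = []
    for tc in centers:
        sel = np.abs(t - tc) <= half
        if sel.sum() < 10:
            continue
        near = np.abs(t_b - tc) <= half + float(spacing.max())
        if len(set(b_sector[near])) < 8:
            continue
        proj = pts[sel] @ dirs.T  # (npts, nphi)
        widths.append(float(np.min(proj.max(axis=0) - proj.min(axis=0) + support)))
    if len(widths) < 3:
        raise StructureTooSmallError(
            f"pedicle {side}: only {len(widths)} usable cross-sections"
        )
    return float(min(widths))


def entry_candidates(
    labels: AnatomyLabelMap, side: str, grid_step_mm: float = 1.0
) -> np.ndarray:
    """Entry-disc voxel centers subsampled on an in-plane grid.

    The grid is anchored at the disc centroid, so a step larger than the disc
    diameter degenerates to the single candidate nearest the center.
    Returns an (n, 3) array of world points, all carrying the disc label.
    """
    if grid_step_mm <= 0:
        raise ConfigError("grid_step_mm must be > 0")
    mask = labels.mask(ENTRY_DISC_LABEL[side])
    if not mask.any():
        raise MissingStructureError(f"entry disc {side} is empty")
    pts = labels.voxel_centers(mask)
    centroid = pts.mean(axis=0)
    # The disc lies on the posterior surface (normal ~ y): bin on x and z.
    # Bin centers sit on a lattice anchored at the disc centroid (rounding,
    # not floor, so a mirrored disc yields mirrored candidates).
    coords = pts[:, [0, 2]]
    bins = np.rint((coords - centroid[[0, 2]]) / grid_step_mm).astype(int)
    out = []
    for b in np.unique(bins, axis=0):
        sel = np.all(bins == b, axis=1)
        target = centroid[[0, 2]] + b * grid_step_mm
        cand = pts[sel]
        out.append(cand[np.argmin(np.sum((cand[:, [0, 2]] - target) ** 2, axis=1))])
    out = np.asarray(out)
    order = np.lexsort((out[:, 2], out[:, 1], out[:, 0]))
    return out[order]


def _last_bone_depths(labels: AnatomyLabelMap, starts, direction, step_mm=None):
    """March k parallel rays; per ray, distance to the LAST bone sample.

    Returns ``(depths, truncated)``: depth is NaN where a ray never meets
    bone; ``truncated`` flags rays whose last in-grid sample is still bone
    (bone may continue beyond the grid).
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if step_mm is None:
        step_mm = float(labels.voxel_spacing_mm.min()) / 2.0
    diag = float(np.linalg.norm(np.asarray(labels.shape) * labels.voxel_spacing_mm))
    ts = np.arange(0.0, diag + step_mm, step_mm)
    pts = starts[:, None, :] + ts[None, :, None] * d  # (k, nt, 3)
    flat = pts.reshape(-1, 3)
    in_grid = labels.in_grid(flat).reshape(len(starts), -1)
    bone = (
        np.isin(labels.labels_at(flat), list(CONTAINMENT_LABELS)).reshape(
            len(starts), -1
        )
        & in_grid
    )
    depths = np.full(len(starts), np.nan)
    truncated = np.zeros(len(starts), dtype=bool)
    for i in range(len(starts)):
        hit = np.nonzero(bone[i])[0]
        if len(hit) == 0:
            continue
        depths[i] = ts[hit[-1]]
        ig = np.nonzero(in_grid[i])[0]
        truncated[i] = len(ig) > 0 and bone[i][ig[-1]]
    return depths, truncated


def depth_to_anterior(
    labels: AnatomyLabelMap, entry, direction, step_mm: float | None = None
) -> float:
    """Distance from ``entry`` to the LAST bone sample along the ray.

    This is the outer anterior surface of the vertebra ("front end"): the
    screw tip must not pass it.  The ray is marched at half the minimum voxel
    spacing with nearest-neighbor label lookup.
    """
    depths, truncated = _last_bone_depths(labels, [entry], direction, step_mm)
    if np.isnan(depths[0]):
        raise NoIntersectionError("ray does not intersect bone")
    if truncated[0]:
        raise GridTruncationError("ray exits the grid while still in bone")
    return float(depths[0])


def effective_anterior_depth(
    labels: AnatomyLabelMap, entry, direction, radius_mm: float, n_rim: int = 8
) -> float:
    """Length bound for a screw of the given radius along this trajectory.

    The anterior surface is curved, so a tip cap sized to the axis-ray depth
    can still protrude where the surface recedes laterally.  The bound is
    therefore the minimum last-bone depth over the axis ray and ``n_rim``
    rays shifted to the cylinder rim.  Axis-ray errors (no intersection,
    grid truncation) propagate; a rim ray that never meets bone bounds the
    length at zero.
    """
    entry = np.asarray(entry, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    e1, e2 = _inplane_basis(d)
    angs = np.linspace(0.0, 2 * np.pi, n_rim, endpoint=False)
    starts = np.vstack(
        [entry, entry + radius_mm * (np.outer(np.cos(angs), e1) + np.outer(np.sin(angs), e2))]
    )
    depths, truncated = _last_bone_depths(labels, starts, d)
    if np.isnan(depths[0]):
        raise NoIntersectionError("axis ray does not intersect bone")
    if truncated[0]:
        raise GridTruncationError("axis ray exits the grid while still in bone")
    depths = np.where(np.isnan(depths), 0.0, depths)
    depths = np.where(truncated, np.inf, depths)
    return float(depths.min())


# ---------------------------------------------------------------------------
# Wall clearance
# ---------------------------------------------------------------------------

def _wall_boundary_trees(labels: AnatomyLabelMap, side: str, axis: AxisLine):
    """KD-trees of medial / inferior free-wall boundary voxel centers.

    A wall-boundary voxel is a pedicle voxel with a background 6-neighbor;
    tube ends abutting other bone labels are thereby excluded.
    """

    def build():
        b_pts = _free_wall_boundary_points(labels, side)
        if len(b_pts) == 0:
            raise MissingStructureError(f"pedicle {side}: no free wall boundary")
        tb = (b_pts - axis.p) @ axis.d
        radial = b_pts - axis.p - np.outer(tb, axis.d)
        rnorm = np.linalg.norm(radial, axis=1)
        rnorm[rnorm == 0] = 1.0
        medial = _medial_direction(labels, axis)
        # Each wall is the boundary patch within a 45-degree cone of its
        # anatomical direction, so the medial and inferior measurements do
        # not collapse onto whichever wall is nearest overall.
        cone = np.cos(np.pi / 4.0)
        med = b_pts[(radial @ medial) / rnorm >= cone]
        inf = b_pts[(radial @ INFERIOR) / rnorm >= cone]
        if len(med) == 0 or len(inf) == 0:
            raise MissingStructureError(f"pedicle {side}: no free wall boundary")
        return cKDTree(med), cKDTree(inf), medial

    return labels.cache(("walls", side), build)


def _medial_direction(labels: AnatomyLabelMap, axis: AxisLine) -> np.ndarray:
    """Unit vector from the pedicle axis toward the midsagittal plane."""
    trab = labels.mask(TRABECULAR_BODY)
    if trab.any():
        mid_x = float(labels.voxel_centers(trab)[:, 0].mean())
    else:
        mid_x = 0.0
    sign = 1.0 if mid_x >= axis.p[0] else -1.0
    return np.array([sign, 0.0, 0.0])


def cylinder_surface_points(
    entry, direction, length_mm, radius_mm, axial_step_mm=0.4, n_angles=48
):
    """Sample the lateral surface of a finite cylinder.

    Returns (points, normals): normals are the outward radial unit vectors.
    """
    entry = np.asarray(entry, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    e1, e2 = _inplane_basis(d)
    ts = np.arange(0.0, length_mm + 1e-9, axial_step_mm)
    angs = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    normals = np.outer(np.cos(angs), e1) + np.outer(np.sin(angs), e2)
    pts = (
        entry[None, None, :]
        + ts[:, None, None] * d[None, None, :]
        + radius_mm * normals[None, :, :]
    ).reshape(-1, 3)
    normals = np.broadcast_to(normals[None, :, :], (len(ts), n_angles, 3)).reshape(-1, 3)
    return pts, normals


def wall_clearance(
    labels: AnatomyLabelMap,
    screw,
    axis: AxisLine | None = None,
) -> ClearanceReport:
    """Medial and inferior clearance of a screw within the pedicle corridor.

    Clearance is the minimum Euclidean distance from the cylinder's lateral
    surface (restricted to the pedicle's middle 80% axial extent, so the
    tube's open ends do not contaminate the measurement) to the free wall
    boundary of the pedicle label on the respective side.  A surface sample
    outside the bone envelope contributes negatively (penetration).

    Distances are measured to wall voxel *centers*, which sit about half a
    voxel inside the label's surface; half the mean spacing is added back so
    the value estimates distance to the label boundary itself.
    """
    side = screw.side
    if axis is None:
        axis = estimate_pedicle_axis(labels, side)
    tree_med, tree_inf, medial = _wall_boundary_trees(labels, side, axis)

    wall_t = (_free_wall_boundary_points(labels, side) - axis.p) @ axis.d
    t_lo, t_hi = np.percentile(wall_t, [10.0, 90.0])

    pts, normals = cylinder_surface_points(
        screw.entry_mm, screw.direction, screw.length_mm, screw.diameter_mm / 2.0
    )
    tp = (pts - axis.p) @ axis.d
    keep = (tp >= t_lo) & (tp <= t_hi)
    if not keep.any():
        raise NotInPedicleError("screw cylinder does not traverse the pedicle")
    pts, normals = pts[keep], normals[keep]
    lab = labels.labels_at(pts)
    if not np.isin(lab, list(CONTAINMENT_LABELS) + [PEDICLE_LABEL[side]]).any():
        raise NotInPedicleError("screw cylinder does not intersect bone in the pedicle")
    in_bone = np.isin(lab, list(CONTAINMENT_LABELS))
    sign = np.where(in_bone, 1.0, -1.0)

    half_voxel = float(labels.voxel_spacing_mm.mean()) / 2.0

    def side_min(tree, wall_dir):
        # only the surface quadrant facing the wall: samples elsewhere on the
        # cylinder have no bearing on this wall's clearance
        facing = normals @ wall_dir >= np.cos(np.pi / 4.0)
        if not facing.any():
            return float("inf")
        dist, _ = tree.query(pts[facing])
        # signed distance to the label surface: +-(center distance) shifted
        # outward by the half voxel between a wall voxel's center and face
        return float(np.min(sign[facing] * dist + half_voxel))

    return ClearanceReport(
        medial_clearance_mm=side_min(tree_med, medial),
        inferior_clearance_mm=side_min(tree_inf, INFERIOR),
    )
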