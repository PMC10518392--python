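"""Gertzbein-Robbins grading of screw placements against a label map.

Breach depth is the maximum distance by which the screw surface protrudes
outside the bone envelope (all bony labels together, so a screw passing from
pedicle into vertebral body is not a breach - only a cortical exit is).
Grades follow the clinical scale with a half-open boundary convention:

    A: depth <= epsilon (no breach, up to sampling resolution)
    B: epsilon < depth < 2 mm
    C: 2 mm <= depth < 4 mm
    D: 4 mm <= depth < 6 mm
    E: depth >= 6 mm
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .anatomy import _inplane_basis
from .errors import OutOfGridError
from .volume import CONTAINMENT_LABELS, AnatomyLabelMap, ImageVolume

GRADES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class GRResult:
    breach_depth_mm: float
    grade: str


@dataclass(frozen=True)
class GradeParams:
    """surface_step_mm: sampling pitch on the screw surface;
    epsilon_mm: grade-A tolerance (default: half the max voxel spacing,
    below which the discrete surface cannot be resolved)."""

    surface_step_mm: float = 0.3
    epsilon_mm: float | None = None

    def resolve_epsilon(self, labels: AnatomyLabelMap) -> float:
        if self.epsilon_mm is not None:
            return self.epsilon_mm
        return float(labels.voxel_spacing_mm.max()) / 2.0


def _bone_tree(labels: AnatomyLabelMap) -> cKDTree:
    def build():
        mask = labels.mask(CONTAINMENT_LABELS)
        return cKDTree(labels.voxel_centers(mask))

    return labels.cache("bone_tree", build)


def screw_surface_samples(screw, step_mm: float) -> np.ndarray:
    """Points on the lateral cylinder surface and the tip cap, pitch <= step.

    The first one-radius-long collar at the entry is excluded: the screw head
    necessarily protrudes through the posterior surface (an oblique entry ring
    dips out of bone by up to r*sin(tilt)), and that protrusion is not a
    pedicle breach.
    """
    entry, d = screw.entry, screw.d
    r = screw.diameter_mm / 2.0
    e1, e2 = _inplane_basis(d)
    pts = []
    t0 = min(r, screw.length_mm / 2.0)
    n_t = max(2, int(np.ceil((screw.length_mm - t0) / step_mm)) + 1)
    ts = np.linspace(t0, screw.length_mm, n_t)
    n_ang = max(8, int(np.ceil(2 * np.pi * r / step_mm)))
    angs = np.linspace(0.0, 2 * np.pi, n_ang, endpoint=False)
    ring = np.outer(np.cos(angs), e1) + np.outer(np.sin(angs), e2)
    pts.append(
        (entry[None, None, :] + ts[:, None, None] * d + r * ring[None, :, :]).reshape(-1, 3)
    )
    # Tip cap: concentric rings out to the full radius.
    tip = entry + screw.length_mm * d
    radii = np.arange(0.0, r + 1e-9, step_mm)
    cap = [tip[None, :]]
    for rr in radii[1:]:
        n = max(6, int(np.ceil(2 * np.pi * rr / step_mm)))
        a = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        cap.append(tip + rr * (np.outer(np.cos(a), e1) + np.outer(np.sin(a), e2)))
    pts.append(np.vstack(cap))
    return np.vstack(pts)


def breach_depth(
    screw, labels: AnatomyLabelMap, surface_step_mm: float = 0.3
) -> float:
    """Maximum protrusion of the screw surface outside the bone envelope.

    Out-of-bone surface samples measure their distance to the nearest bone
    voxel center, minus half a voxel (the gap between a surface voxel's
    center and its face), clamped at zero: an estimate of distance to the
    bone label's surface.  Returns 0 if the screw is fully contained.
    """
    samples = screw_surface_samples(screw, surface_step_mm)
    in_grid = labels.in_grid(samples)
    if not in_grid.any():
        raise OutOfGridError("screw lies entirely outside the grid")
    lab = labels.labels_at(samples)
    outside = ~(np.isin(lab, list(CONTAINMENT_LABELS)) & in_grid)
    if not outside.any():
        return 0.0
    dist, _ = _bone_tree(labels).query(samples[outside])
    half_voxel = float(labels.voxel_spacing_mm.mean()) / 2.0
    return float(max(0.0, np.max(dist) - half_voxel))


def gr_grade(depth_mm: float, epsilon_mm: float = 0.3125) -> str:
    """Map a breach depth to the Gertzbein-Robbins grade (half-open bounds)."""
    if depth_mm < 0:
        raise ValueError("breach depth must be >= 0")
    if depth_mm <= epsilon_mm:
        return "A"
    if depth_mm < 2.0:
        return "B"
    if depth_mm < 4.0:
        return "C"
    if depth_mm < 6.0:
        return "D"
    return "E"


def grade_screw(
    screw, labels: AnatomyLabelMap, params: GradeParams | None = None
) -> GRResult:
    """Breach depth + grade for one screw; deterministic."""
    params = params or GradeParams()
    depth = breach_depth(screw, labels, params.surface_step_mm)
    return GRResult(
        breach_depth_mm=depth, grade=gr_grade(depth, params.resolve_epsilon(labels))
    )


def reslice_along_axis(
    volume: ImageVolume,
    screw,
    n_planes: int = 5,
    fov_mm: float = 30.0,
    pixel_mm: float | None = None,
    fill_value: float = 0.0,
):
    """Multiplanar reconstruction perpendicular to the screw axis.

    ``n_planes`` square images of side ``fov_mm`` are sampled (trilinear)
    on planes evenly spaced along the screw.  Returns ``(stack, flags)``
    where ``flags[i]`` is True if plane i fell fully outside the grid (its
    pixels are then ``fill_value``).
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    if pixel_mm is None:
        pixel_mm = float(volume.voxel_spacing_mm.min())
    e1, e2 = _inplane_basis(screw.d)
    n_half = int(np.floor(fov_mm / 2.0 / pixel_mm))
    coords_1d = (np.arange(2 * n_half + 1) - n_half) * pixel_mm  # centered on axis
    uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    centers = (
        screw.entry[None, :]
        + np.linspace(0.0, screw.length_mm, n_planes)[:, None] * screw.d[None, :]
    )
    stack = np.empty((n_planes, len(coords_1d), len(coords_1d)), dtype=np.float32)
    flags = []
    for i, c in enumerate(centers):
        world = (
            c[None, None, :] + uu[:, :, None] * e1[None, None, :] + vv[:, :, None] * e2[None, None, :]
        )
        idx = volume.world_to_index(world.reshape(-1, 3)).T
        inside = np.all(
            (idx >= -0.5) & (idx <= (np.asarray(volume.shape)[:, None] - 0.5)), axis=0
        )
        plane = map_coordinates(
            volume.intensities, idx, order=1, mode="constant", cval=fill_value
        )
        plane[~inside] = fill_value
        stack[i] = plane.reshape(uu.shape)
        flags.append(not bool(inside.any()))
    return stack, flags
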