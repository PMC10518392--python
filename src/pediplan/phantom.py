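"""Parametric vertebra phantoms with exact ground-truth geometry.

The phantom emulates a segmented thoracolumbar vertebra: an elliptic-cylinder
vertebral body with a cortical shell and superior/inferior endplate slabs,
left/right pedicles modeled as straight elliptic tubes that converge medially
toward the body at a configurable transverse angle, a posterior-element block
the tubes emerge from, and a circular entry region carved into the posterior
cortical surface at each tube mouth.  Because every compartment is an analytic
solid, the generator can emit the exact quantities the measurement and
planning stages are supposed to recover (pedicle axis and width, entry disc,
depth to the anterior cortex, endplate planes).

Intensities are constant per compartment plus i.i.d. Gaussian noise - enough
signal for density-weighted trajectory scoring without simulating CT physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError, GeometryInfeasibleError
from .volume import (
    BACKGROUND,
    CORTICAL_SHELL,
    ENDPLATE_INF,
    ENDPLATE_SUP,
    ENTRY_DISC_LABEL,
    PEDICLE_LABEL,
    POSTERIOR_ELEMENTS,
    TRABECULAR_BODY,
    AnatomyLabelMap,
    ImageVolume,
)

#: Thickness (mm, along y) of the posterior-element block behind the pedicles.
POSTERIOR_BLOCK_MM = 6.0
#: Air margin (mm) between anatomy and the grid boundary.
GRID_MARGIN_MM = 3.0
#: Pedicle mouths sit at +/- this fraction of body width from the midline.
PEDICLE_OFFSET_FRACTION = 0.35

SIDES = ("L", "R")
_SIDE_SIGN = {"L": -1.0, "R": 1.0}  # sign of x at the pedicle mouth


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic vertebra (all lengths in millimetres)."""

    body_width_mm: float = 45.0
    body_depth_mm: float = 35.0
    body_height_mm: float = 30.0
    pedicle_width_mm: float = 9.0
    pedicle_height_mm: float = 12.0
    pedicle_length_mm: float = 12.0
    pedicle_transverse_angle_deg: float = 10.0
    cortex_thickness_mm: float = 1.5
    entry_disc_radius_mm: float = 3.0
    voxel_spacing_mm: tuple = (0.625, 0.625, 0.625)
    intensity_trabecular_hu: float = 250.0
    intensity_cortical_hu: float = 900.0
    intensity_background_hu: float = -400.0
    noise_sd_hu: float = 30.0
    rng_seed: int = 0

    def __post_init__(self):
        dims = (
            self.body_width_mm,
            self.body_depth_mm,
            self.body_height_mm,
            self.pedicle_width_mm,
            self.pedicle_height_mm,
            self.pedicle_length_mm,
            self.cortex_thickness_mm,
            self.entry_disc_radius_mm,
        )
        if not all(d > 0 for d in dims):
            raise ConfigError("all linear dimensions must be > 0")
        if self.pedicle_width_mm >= self.body_width_mm:
            raise ConfigError("pedicle_width_mm must be < body_width_mm")
        if self.pedicle_width_mm > self.pedicle_height_mm:
            # corridor at least as tall as wide, so the width IS the minimum
            # caliper of the cross-section (and matches real pedicle anatomy)
            raise ConfigError("pedicle_width_mm must be <= pedicle_height_mm")
        spacing = np.asarray(self.voxel_spacing_mm, dtype=float)
        if spacing.shape != (3,) or not np.all(spacing > 0):
            raise ConfigError("voxel_spacing_mm must be 3 positive floats")
        if self.cortex_thickness_mm < spacing.min():
            raise ConfigError(
                "cortex_thickness_mm must be at least one voxel along the "
                "thinnest spacing axis"
            )
        if not 0.0 <= self.pedicle_transverse_angle_deg < 45.0:
            raise ConfigError("pedicle_transverse_angle_deg must be in [0, 45)")
        if self.noise_sd_hu < 0:
            raise ConfigError("noise_sd_hu must be >= 0")


@dataclass(frozen=True)
class PedicleTruth:
    """Exact per-side geometry of one pedicle corridor."""

    axis_point_mm: tuple
    axis_direction: tuple  # unit, oriented posterior -> anterior
    width_mm: float
    entry_center_mm: tuple
    entry_radius_mm: float
    anterior_depth_mm: float  # entry-disc center -> outer anterior cortex, along axis


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth emitted alongside the voxelised phantom."""

    spec: PhantomSpec
    pedicles: dict  # side -> PedicleTruth
    endplate_inner_z_mm: tuple  # (inferior, superior) inner slab boundaries
    endplate_outer_z_mm: tuple
    body_center_mm: tuple

    @property
    def W(self) -> float:
        """True pedicle width (identical for both sides by construction)."""
        return self.pedicles["L"].width_mm


class Phantom(NamedTuple):
    volume: ImageVolume
    labels: AnatomyLabelMap
    truth: PhantomTruth


@dataclass(frozen=True)
class _Geometry:
    """Derived analytic geometry shared by voxelisation and truth."""

    axis_point: dict
    axis_dir: dict
    body_center_y: float
    t_max: dict


def _derive_geometry(spec: PhantomSpec) -> _Geometry:
    theta = math.radians(spec.pedicle_transverse_angle_deg)
    x0 = PEDICLE_OFFSET_FRACTION * spec.body_width_mm
    a = spec.body_width_mm / 2.0  # ellipse semi-axis along x
    b = spec.body_depth_mm / 2.0  # along y
    if spec.pedicle_width_mm / 2.0 >= x0:
        raise GeometryInfeasibleError(
            "pedicle tube would cross the midline at its mouth"
        )
    if spec.pedicle_height_mm >= spec.body_height_mm:
        raise GeometryInfeasibleError("pedicle taller than the vertebral body")

    t_enter = POSTERIOR_BLOCK_MM / math.cos(theta) + spec.pedicle_length_mm
    axis_point, axis_dir, t_max = {}, {}, {}
    body_center_y = None
    for side in SIDES:
        s = _SIDE_SIGN[side]
        d = np.array([-s * math.sin(theta), math.cos(theta), 0.0])
        p0 = np.array([s * x0, 0.0, 0.0])
        entry_body = p0 + t_enter * d  # where the axis meets the body surface
        if abs(entry_body[0]) >= 0.9 * a:
            raise GeometryInfeasibleError(
                "pedicle tube converges too far laterally to reach the body"
            )
        yc = entry_body[1] + b * math.sqrt(1.0 - (entry_body[0] / a) ** 2)
        body_center_y = yc  # symmetric: same for both sides
        axis_point[side] = p0
        axis_dir[side] = d
        t_max[side] = t_enter + spec.cortex_thickness_mm + 3.0
    return _Geometry(axis_point, axis_dir, body_center_y, t_max)


def _far_ellipse_intersection(point, direction, a, b, yc):
    """Larger root t of |(x/a, (y-yc)/b)| = 1 along point + t*direction."""
    px, py = point[0], point[1] - yc
    dx, dy = direction[0], direction[1]
    qa = (dx / a) ** 2 + (dy / b) ** 2
    qb = 2.0 * (px * dx / a**2 + py * dy / b**2)
    qc = (px / a) ** 2 + (py / b) ** 2 - 1.0
    disc = qb * qb - 4.0 * qa * qc
    if disc <= 0:
        raise GeometryInfeasibleError("pedicle axis does not intersect the body")
    return (-qb + math.sqrt(disc)) / (2.0 * qa)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelise one phantom; deterministic given ``spec.rng_seed``.

    Returns
    -------
    Phantom
        Named tuple ``(volume, labels, truth)``; the two grids are
        voxel-for-voxel co-registered.
    """
    geo = _derive_geometry(spec)
    spacing = np.asarray(spec.voxel_spacing_mm, dtype=float)
    a = spec.body_width_mm / 2.0
    b = spec.body_depth_mm / 2.0
    hz = spec.body_height_mm / 2.0
    ct = spec.cortex_thickness_mm
    yc = geo.body_center_y

    pe_half_x = PEDICLE_OFFSET_FRACTION * spec.body_width_mm + spec.pedicle_width_mm / 2.0 + 2.0
    pe_half_z = spec.pedicle_height_mm / 2.0 + 3.0
    x_extent = max(a, pe_half_x) + GRID_MARGIN_MM
    y_lo, y_hi = -GRID_MARGIN_MM, yc + b + GRID_MARGIN_MM
    z_extent = max(hz, pe_half_z) + GRID_MARGIN_MM

    shape = tuple(
        int(math.ceil(ext / sp)) + 1
        for ext, sp in zip((2 * x_extent, y_hi - y_lo, 2 * z_extent), spacing)
    )
    # Center x and z so the voxel lattice is mirror-symmetric about the
    # midsagittal and axial mid-planes: left/right anatomy then voxelises
    # identically and planning is symmetric up to tie-breaks.
    origin = np.array(
        [
            -(shape[0] - 1) * spacing[0] / 2.0,
            y_lo,
            -(shape[2] - 1) * spacing[2] / 2.0,
        ]
    )
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")

    labels = np.full(shape, BACKGROUND, dtype=np.uint8)

    # Vertebral body: outer elliptic cylinder, inner trabecular core, endplates.
    in_body = ((xx / a) ** 2 + ((yy - yc) / b) ** 2 <= 1.0) & (np.abs(zz) <= hz)
    in_core = (
        ((xx / (a - ct)) ** 2 + ((yy - yc) / (b - ct)) ** 2 <= 1.0)
        & (np.abs(zz) <= hz - ct)
    )
    labels[in_body] = CORTICAL_SHELL
    labels[in_core] = TRABECULAR_BODY
    labels[in_body & (zz > hz - ct)] = ENDPLATE_SUP
    labels[in_body & (zz < -hz + ct)] = ENDPLATE_INF

    # Pedicle tubes override cortex/background but never the trabecular core
    # or the endplates, so each corridor runs posterior elements -> core.
    pw2, ph2 = spec.pedicle_width_mm / 2.0, spec.pedicle_height_mm / 2.0
    tube_masks = {}
    for side in SIDES:
        p0, d = geo.axis_point[side], geo.axis_dir[side]
        e_h = np.array([d[1], -d[0], 0.0])  # horizontal in-plane normal
        wx, wy, wz = xx - p0[0], yy - p0[1], zz - p0[2]
        t = wx * d[0] + wy * d[1]  # d_z == 0
        u_h = wx * e_h[0] + wy * e_h[1]
        in_tube = (
            (t >= 0.0)
            & (t <= geo.t_max[side])
            & ((u_h / pw2) ** 2 + (wz / ph2) ** 2 <= 1.0)
        )
        tube_masks[side] = in_tube
        writable = in_tube & np.isin(labels, (BACKGROUND, CORTICAL_SHELL))
        labels[writable] = PEDICLE_LABEL[side]

    # Posterior-element block fills remaining space behind the pedicles.
    in_block = (
        (yy >= 0.0)
        & (yy <= POSTERIOR_BLOCK_MM)
        & (np.abs(xx) <= pe_half_x)
        & (np.abs(zz) <= pe_half_z)
    )
    labels[in_block & (labels == BACKGROUND)] = POSTERIOR_ELEMENTS

    # Entry discs: posterior-most bone layer at each tube mouth, re-labeled.
    jy0 = int(np.searchsorted(ys, 0.0))
    pedicles = {}
    for side in SIDES:
        p0, d = geo.axis_point[side], geo.axis_dir[side]
        t_c = ys[jy0] / d[1]
        center = p0 + t_c * d
        layer = labels[:, jy0, :]
        lx, lz = np.meshgrid(xs, zs, indexing="ij")
        in_disc = (lx - center[0]) ** 2 + (lz - center[2]) ** 2 <= spec.entry_disc_radius_mm**2
        carve = in_disc & np.isin(layer, (POSTERIOR_ELEMENTS, PEDICLE_LABEL[side]))
        layer[carve] = ENTRY_DISC_LABEL[side]
        if not carve.any():
            raise GeometryInfeasibleError(f"entry disc {side} fell outside the grid")
        depth = _far_ellipse_intersection(center, d, a, b, yc)
        pedicles[side] = PedicleTruth(
            axis_point_mm=tuple(center),
            axis_direction=tuple(d),
            width_mm=spec.pedicle_width_mm,
            entry_center_mm=tuple(center),
            entry_radius_mm=spec.entry_disc_radius_mm,
            anterior_depth_mm=float(depth),
        )

    # Intensities: compartment constants + Gaussian noise.
    rng = np.random.default_rng(spec.rng_seed)
    intensities = np.full(shape, spec.intensity_background_hu, dtype=np.float32)
    trab_like = np.isin(labels, (TRABECULAR_BODY, PEDICLE_LABEL["L"], PEDICLE_LABEL["R"]))
    cort_like = np.isin(
        labels,
        (
            CORTICAL_SHELL,
            ENDPLATE_SUP,
            ENDPLATE_INF,
            POSTERIOR_ELEMENTS,
            ENTRY_DISC_LABEL["L"],
            ENTRY_DISC_LABEL["R"],
        ),
    )
    intensities[trab_like] = spec.intensity_trabecular_hu
    intensities[cort_like] = spec.intensity_cortical_hu
    if spec.noise_sd_hu > 0:
        intensities += rng.normal(0.0, spec.noise_sd_hu, size=shape).astype(np.float32)

    truth = PhantomTruth(
        spec=spec,
        pedicles=pedicles,
        endplate_inner_z_mm=(-hz + ct, hz - ct),
        endplate_outer_z_mm=(-hz, hz),
        body_center_mm=(0.0, yc, 0.0),
    )
    volume = ImageVolume(
        voxel_spacing_mm=spacing.copy(), origin_mm=origin.copy(), intensities=intensities
    )
    label_map = AnatomyLabelMap(
        voxel_spacing_mm=spacing.copy(), origin_mm=origin.copy(), labels=labels
    )
    return Phantom(volume, label_map, truth)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Default cohort parameter ranges: a lumbar-scale population.  Pedicle widths
#: 7-13 mm span the range over which the full screw catalog is exercised.
DEFAULT_COHORT_RANGES = {
    "body_width_mm": (40.0, 50.0),
    "body_depth_mm": (32.0, 38.0),
    "body_height_mm": (26.0, 32.0),
    "pedicle_width_mm": (7.0, 12.0),
    "pedicle_height_mm": (12.0, 15.0),
    "pedicle_length_mm": (10.0, 14.0),
    "pedicle_transverse_angle_deg": (5.0, 15.0),
}

_RANGEABLE = set(DEFAULT_COHORT_RANGES) | {
    "cortex_thickness_mm",
    "entry_disc_radius_mm",
    "intensity_trabecular_hu",
    "intensity_cortical_hu",
    "noise_sd_hu",
}


def draw_cohort_specs(n, spec_ranges=None, seed=0, base=None) -> list[PhantomSpec]:
    """Draw ``n`` phantom specs with ranged fields uniform over their intervals."""
    if n < 1:
        raise ConfigError("cohort size must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES if spec_ranges is None else spec_ranges)
    for name, rng_pair in ranges.items():
        if name not in _RANGEABLE:
            raise ConfigError(f"unknown or non-rangeable PhantomSpec field: {name}")
        lo, hi = rng_pair
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ConfigError(f"invalid range for {name}: {rng_pair}")
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        draws["rng_seed"] = int(rng.integers(0, 2**31 - 1))
        specs.append(replace(base, **draws))
    return specs


def make_cohort(n, spec_ranges=None, seed=0, base=None) -> list[Phantom]:
    """Generate ``n`` independent phantoms; reproducible from ``seed``."""
    return [make_phantom(s) for s in draw_cohort_specs(n, spec_ranges, seed, base)]


# ---------------------------------------------------------------------------
# Screw perturbation (synthetic "freehand" arm)
# ---------------------------------------------------------------------------

def perturb_screw(screw, translation_sd_mm: float, rotation_sd_deg: float, seed: int):
    """Jitter a screw pose: Gaussian entry translation + Gaussian axis rotation.

    Length and diameter are unchanged; the direction is renormalised.  With
    both standard deviations zero the input is returned unchanged.
    """
    if translation_sd_mm < 0 or rotation_sd_deg < 0:
        raise ConfigError("perturbation standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    entry = np.asarray(screw.entry_mm, dtype=float) + rng.normal(
        0.0, translation_sd_mm, size=3
    )
    rotvec = rng.normal(0.0, math.radians(rotation_sd_deg), size=3)
    direction = Rotation.from_rotvec(rotvec).apply(np.asarray(screw.direction, dtype=float))
    direction = direction / np.linalg.norm(direction)
    return replace(screw, entry_mm=tuple(entry), direction=tuple(direction))
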