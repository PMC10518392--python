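"""Trajectory enumeration, screw sizing, constraint checking and selection.

The placement rules implemented here:

* entry points are restricted to the circular entry region on the posterior
  surface of each pedicle;
* the screw is the longest catalog length not exceeding the distance from
  the entry point to the outer anterior cortex of the vertebral body;
* the screw is the thickest catalog diameter not exceeding 90% of the
  pedicle width W, subject to a safety margin (default >= 1 mm) against the
  medial and inferior pedicle walls;
* the screw must never violate the superior/inferior endplates;
* among feasible candidates the planner keeps the trajectory with the
  highest pullout-force proxy (mean intra-screw density x thread lateral
  surface pi*D*L), a stand-in that is strictly monotone in density, length
  and diameter.

The search is exhaustive over a configurable entry x angle grid and fully
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .anatomy import (
    AxisLine,
    cylinder_surface_points,
    effective_anterior_depth,
    entry_candidates,
    estimate_pedicle_axis,
    measure_pedicle_width,
    wall_clearance,
)
from .errors import (
    ConfigError,
    DegenerateScrewError,
    GridTruncationError,
    NoIntersectionError,
    NotInPedicleError,
    PlanningInfeasibleError,
)
from .volume import ENDPLATE_INF, ENDPLATE_SUP, AnatomyLabelMap, ImageVolume

SIDES = ("L", "R")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScrewCatalog:
    """Available screw sizes.  Defaults span the clinically used ranges
    30-65 mm length (step 5) and 5.0-7.5 mm diameter (step 0.5)."""

    allowed_lengths_mm: tuple = (30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0, 65.0)
    allowed_diameters_mm: tuple = (5.0, 5.5, 6.0, 6.5, 7.0, 7.5)

    def __post_init__(self):
        for name in ("allowed_lengths_mm", "allowed_diameters_mm"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) == 0:
                raise ConfigError(f"{name} must be non-empty")
            if any(v <= 0 for v in vals):
                raise ConfigError(f"{name} must be all > 0")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ConfigError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, vals)

    def longest_at_most(self, limit_mm: float):
        ok = [v for v in self.allowed_lengths_mm if v <= limit_mm]
        return ok[-1] if ok else None

    def diameters_descending(self):
        return tuple(reversed(self.allowed_diameters_mm))


@dataclass(frozen=True)
class ScrewSpec:
    """A placed (or planned) screw: entry point, axis, catalog dimensions."""

    side: str
    entry_mm: tuple
    direction: tuple
    length_mm: float
    diameter_mm: float

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"side must be L or R, got {self.side!r}")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("screw direction must be a unit vector")
        object.__setattr__(self, "direction", tuple(d / n))
        object.__setattr__(self, "entry_mm", tuple(float(v) for v in self.entry_mm))
        if self.length_mm <= 0 or self.diameter_mm <= 0:
            raise ValueError("screw length and diameter must be > 0")

    @property
    def entry(self) -> np.ndarray:
        return np.asarray(self.entry_mm, dtype=float)

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def tip_mm(self) -> np.ndarray:
        return self.entry + self.length_mm * self.d


@dataclass(frozen=True)
class ConstraintReport:
    medial_clearance_mm: float
    inferior_clearance_mm: float
    endplate_violation: bool
    anterior_overrun_mm: float
    feasible: bool


@dataclass(frozen=True)
class TrajectoryScore:
    bmd_mean_hu: float
    pof_proxy: float


@dataclass(frozen=True)
class ScrewPlan:
    screw: ScrewSpec
    score: TrajectoryScore
    constraints: ConstraintReport
    n_candidates_evaluated: int


@dataclass(frozen=True)
class AngleGrid:
    """Symmetric transverse x sagittal angular search grid about the pedicle
    axis (degrees)."""

    transverse_range_deg: float = 15.0
    transverse_step_deg: float = 3.0
    sagittal_range_deg: float = 9.0
    sagittal_step_deg: float = 3.0

    def __post_init__(self):
        if self.transverse_step_deg <= 0 or self.sagittal_step_deg <= 0:
            raise ConfigError("angle grid steps must be > 0")
        if self.transverse_range_deg < 0 or self.sagittal_range_deg < 0:
            raise ConfigError("angle grid ranges must be >= 0")

    def transverse_angles(self) -> np.ndarray:
        r, s = self.transverse_range_deg, self.transverse_step_deg
        return np.arange(-r, r + 1e-9, s) if r > 0 else np.array([0.0])

    def sagittal_angles(self) -> np.ndarray:
        r, s = self.sagittal_range_deg, self.sagittal_step_deg
        return np.arange(-r, r + 1e-9, s) if r > 0 else np.array([0.0])


@dataclass(frozen=True)
class PlanConfig:
    """Everything that parameterises a planning run.

    ``containment_epsilon_mm``: candidates whose breach depth on the
    planning label map exceeds this are rejected even if the named wall
    constraints pass (the lateral and superior walls have no explicit
    margin, so containment is what governs them).  None resolves to half
    the maximum voxel spacing.
    """

    catalog: ScrewCatalog = field(default_factory=ScrewCatalog)
    angle_grid: AngleGrid = field(default_factory=AngleGrid)
    entry_step_mm: float = 1.0
    margin_mm: float = 1.0
    containment_epsilon_mm: float | None = None

    def __post_init__(self):
        if self.entry_step_mm <= 0:
            raise ConfigError("entry_step_mm must be > 0")
        if self.margin_mm < 0:
            raise ConfigError("margin_mm must be >= 0")


#: A coarse search grid: same constraints, ~15x fewer candidates.  Used for
#: sweeps where per-phantom optimality to the finest angular resolution is
#: not the point.
COARSE_CONFIG = PlanConfig(
    angle_grid=AngleGrid(
        transverse_range_deg=10.0,
        transverse_step_deg=5.0,
        sagittal_range_deg=6.0,
        sagittal_step_deg=3.0,
    ),
    entry_step_mm=2.0,
)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def enumerate_trajectories(
    entries, angle_grid: AngleGrid, labels: AnatomyLabelMap, side: str
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cartesian product of entry points x grid directions about the pedicle
    axis; every direction points anteriorly (positive y)."""
    entries = np.atleast_2d(np.asarray(entries, dtype=float))
    if len(entries) == 0:
        raise ConfigError("no entry candidates supplied")
    axis = estimate_pedicle_axis(labels, side)
    d0 = axis.d
    z = np.array([0.0, 0.0, 1.0])
    u_sag = np.cross(d0, z)
    u_sag /= np.linalg.norm(u_sag)
    dirs = []
    for alpha in angle_grid.transverse_angles():
        r_t = Rotation.from_rotvec(z * math.radians(alpha))
        for beta in angle_grid.sagittal_angles():
            r_s = Rotation.from_rotvec(u_sag * math.radians(beta))
            d = r_t.apply(r_s.apply(d0))
            if d[1] <= 0:  # never search posteriorly-pointing directions
                continue
            dirs.append(d / np.linalg.norm(d))
    return [(e, d) for e in entries for d in dirs]


def size_screw(
    entry,
    direction,
    labels: AnatomyLabelMap,
    side: str,
    W: float,
    catalog: ScrewCatalog,
    margin_mm: float = 1.0,
    axis: AxisLine | None = None,
):
    """Maximal catalog sizing for one trajectory, or None if infeasible.

    Length: largest catalog length not exceeding the entry-to-anterior-cortex
    depth.  Diameter: largest catalog diameter d with d <= 0.9*W whose wall
    clearances are both >= ``margin_mm``.

    The length bound is the effective anterior depth for the candidate
    diameter (minimum last-bone depth over axis + rim rays), so the whole
    tip cap stays behind the curved anterior surface.

    Returns ``(length_mm, diameter_mm, depth_mm, clearance_report)`` or None.
    """
    for dia in catalog.diameters_descending():
        if dia > 0.9 * W:
            continue
        try:
            depth = effective_anterior_depth(labels, entry, direction, dia / 2.0)
        except (NoIntersectionError, GridTruncationError):
            return None
        length = catalog.longest_at_most(depth)
        if length is None:
            return None
        screw = ScrewSpec(side, tuple(entry), tuple(direction), length, dia)
        try:
            rep = wall_clearance(labels, screw, axis=axis)
        except NotInPedicleError:
            return None
        if rep.medial_clearance_mm >= margin_mm and rep.inferior_clearance_mm >= margin_mm:
            return length, dia, depth, rep
    return None


def check_constraints(
    screw: ScrewSpec,
    labels: AnatomyLabelMap,
    margin_mm: float = 1.0,
    axis: AxisLine | None = None,
    _depth: float | None = None,
    _clearance=None,
) -> ConstraintReport:
    """Evaluate all placement constraints for a screw; reports, never raises,
    for in-grid screws."""
    if _clearance is None:
        try:
            _clearance = wall_clearance(labels, screw, axis=axis)
        except NotInPedicleError:
            _clearance = None
    med = _clearance.medial_clearance_mm if _clearance else float("-inf")
    inf = _clearance.inferior_clearance_mm if _clearance else float("-inf")

    if _depth is None:
        try:
            _depth = effective_anterior_depth(
                labels, screw.entry_mm, screw.direction, screw.diameter_mm / 2.0
            )
        except NoIntersectionError:
            _depth = 0.0
        except GridTruncationError:
            _depth = float("inf")
    overrun = max(0.0, screw.length_mm - _depth)

    surf, _ = cylinder_surface_points(
        screw.entry_mm, screw.direction, screw.length_mm, screw.diameter_mm / 2.0
    )
    axis_pts = screw.entry[None, :] + np.outer(
        np.arange(0.0, screw.length_mm + 1e-9, 0.4), screw.d
    )
    lab = labels.labels_at(np.vstack([surf, axis_pts]))
    endplate = bool(np.isin(lab, (ENDPLATE_SUP, ENDPLATE_INF)).any())

    feasible = (
        med >= margin_mm and inf >= margin_mm and not endplate and overrun <= 1e-9
    )
    return ConstraintReport(
        medial_clearance_mm=float(med),
        inferior_clearance_mm=float(inf),
        endplate_violation=endplate,
        anterior_overrun_mm=float(overrun),
        feasible=bool(feasible),
    )


def screw_voxel_mask(volume_or_labels, screw: ScrewSpec):
    """Boolean mask of voxels whose centers lie inside the screw cylinder,
    restricted to (and returned with) its bounding index box."""
    g = volume_or_labels
    r = screw.diameter_mm / 2.0
    corners = np.array([screw.entry, screw.tip_mm])
    lo_w = corners.min(axis=0) - r
    hi_w = corners.max(axis=0) + r
    lo = np.maximum(np.floor(g.world_to_index(lo_w)).astype(int), 0)
    hi = np.minimum(np.ceil(g.world_to_index(hi_w)).astype(int) + 1, np.asarray(g.shape))
    if np.any(lo >= hi):
        return None, (lo, hi)
    ii = [np.arange(lo[k], hi[k]) for k in range(3)]
    xx, yy, zz = np.meshgrid(*[g.origin_mm[k] + ii[k] * g.voxel_spacing_mm[k] for k in range(3)], indexing="ij")
    w = np.stack([xx - screw.entry[0], yy - screw.entry[1], zz - screw.entry[2]], axis=-1)
    t = w @ screw.d
    rad2 = np.sum(w * w, axis=-1) - t * t
    mask = (t >= 0.0) & (t <= screw.length_mm) & (rad2 <= r * r)
    return mask, (lo, hi)


def score_trajectory(screw: ScrewSpec, volume: ImageVolume) -> TrajectoryScore:
    """Density score: mean pseudo-HU over voxel centers inside the cylinder;
    pullout proxy: clamped density x lateral thread surface pi*D*L."""
    mask, (lo, hi) = screw_voxel_mask(volume, screw)
    if mask is None or not mask.any():
        raise DegenerateScrewError("screw cylinder contains no voxel centers")
    sub = volume.intensities[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    bmd = float(sub[mask].mean())
    pof = max(bmd, 1.0) * math.pi * screw.diameter_mm * screw.length_mm
    return TrajectoryScore(bmd_mean_hu=bmd, pof_proxy=float(pof))


def plan_side(
    volume: ImageVolume,
    labels: AnatomyLabelMap,
    side: str,
    config: PlanConfig | None = None,
) -> ScrewPlan:
    """Exhaustive deterministic search for the best feasible screw on one side.

    Selection key: pof_proxy, tie-broken by bmd_mean_hu, then smaller angular
    deviation from the pedicle axis, then entry-point lexicographic order
    (the enumeration order, so exact ties keep the earliest candidate).
    """
    config = config or PlanConfig()
    axis = estimate_pedicle_axis(labels, side)
    W = measure_pedicle_width(labels, side, axis=axis)
    entries = entry_candidates(labels, side, config.entry_step_mm)
    candidates = enumerate_trajectories(entries, config.angle_grid, labels, side)

    best = None
    best_key = None
    best_bad = None  # least-infeasible report, for the error path
    n_eval = 0
    for entry, direction in candidates:
        n_eval += 1
        sized = size_screw(
            entry, direction, labels, side, W, config.catalog, config.margin_mm, axis=axis
        )
        if sized is None:
            continue
        length, dia, depth, clear = sized
        screw = ScrewSpec(side, tuple(entry), tuple(direction), length, dia)
        report = check_constraints(
            screw, labels, config.margin_mm, axis=axis, _depth=depth, _clearance=clear
        )
        if not report.feasible:
            if best_bad is None or min(
                report.medial_clearance_mm, report.inferior_clearance_mm
            ) > min(best_bad.medial_clearance_mm, best_bad.inferior_clearance_mm):
                best_bad = report
            continue
        # Containment: the named margins cover only the medial and inferior
        # walls; reject candidates that leave the bone envelope anywhere.
        from .grading import breach_depth

        eps = config.containment_epsilon_mm
        if eps is None:
            eps = float(labels.voxel_spacing_mm.max()) / 2.0
        if breach_depth(screw, labels) > eps:
            if best_bad is None:
                best_bad = report
            continue
        score = score_trajectory(screw, volume)
        ang_dev = math.acos(np.clip(np.dot(direction, axis.d), -1.0, 1.0))
        key = (score.pof_proxy, score.bmd_mean_hu, -ang_dev)
        if best_key is None or key > best_key:
            best, best_key = ScrewPlan(screw, score, report, 0), key
    if best is None:
        raise PlanningInfeasibleError(
            f"no feasible screw for side {side} "
            f"(W={W:.2f} mm, {n_eval} candidates evaluated)",
            best_report=best_bad,
        )
    return ScrewPlan(best.screw, best.score, best.constraints, n_eval)


def plan_vertebra(
    volume: ImageVolume, labels: AnatomyLabelMap, config: PlanConfig | None = None
) -> dict:
    """Plan both sides independently.

    Returns ``{"L": ScrewPlan | PediplanError, "R": ...}``: a side that fails
    carries its error instead of aborting the other side.
    """
    from .errors import PediplanError

    out = {}
    for side in SIDES:
        try:
            out[side] = plan_side(volume, labels, side, config)
        except PediplanError as exc:
            out[side] = exc
    return out
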