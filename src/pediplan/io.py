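"""File formats: NIfTI volumes/label maps, JSON plan documents and truth
files, YAML run configuration, CSV grade tables.

NIfTI-1 is the interchange format for grids (axis-aligned affine: spacing on
the diagonal, origin in the translation column).  Plan documents are JSON
with a schema version, input provenance (paths + SHA-256) and one entry per
side holding either the plan or the error that side produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError
from .grading import GradeParams, GRResult
from .phantom import PhantomSpec, PhantomTruth
from .planner import (
    AngleGrid,
    ConstraintReport,
    PlanConfig,
    ScrewCatalog,
    ScrewPlan,
    ScrewSpec,
    TrajectoryScore,
)
from .volume import LABEL_NAMES, AnatomyLabelMap, ImageVolume

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# NIfTI grids
# ---------------------------------------------------------------------------

def _affine(grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.voxel_spacing_mm)
    aff[:3, 3] = grid.origin_mm
    return aff


def write_volume(volume: ImageVolume, path) -> None:
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), _affine(volume)), str(path))


def write_labels(labels: AnatomyLabelMap, path) -> None:
    nib.save(nib.Nifti1Image(labels.labels.astype(np.uint8), _affine(labels)), str(path))


def _load_grid(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D grid, got {data.ndim}-D")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return data, spacing, origin


def read_volume(path) -> ImageVolume:
    data, spacing, origin = _load_grid(path)
    return ImageVolume(
        voxel_spacing_mm=spacing, origin_mm=origin, intensities=data.astype(np.float32)
    )


def read_labels(path) -> AnatomyLabelMap:
    data, spacing, origin = _load_grid(path)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{path}: label data must be integer-valued")
        data = np.round(data).astype(np.int64)
    unknown = sorted(set(np.unique(data).tolist()) - set(LABEL_NAMES))
    if unknown:
        raise FormatError(f"{path}: unknown label codes {unknown}")
    return AnatomyLabelMap(
        voxel_spacing_mm=spacing, origin_mm=origin, labels=data.astype(np.uint8)
    )


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Phantom truth
# ---------------------------------------------------------------------------

def write_truth(truth: PhantomTruth, path) -> None:
    doc = dataclasses.asdict(truth)
    Path(path).write_text(json.dumps(doc, indent=2, default=list))


# ---------------------------------------------------------------------------
# Run configuration (YAML)
# ---------------------------------------------------------------------------

def load_yaml(path) -> dict:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return doc


def plan_config_from_dict(doc: dict) -> PlanConfig:
    kwargs = {}
    if "catalog" in doc:
        cat = doc["catalog"]
        kwargs["catalog"] = ScrewCatalog(
            allowed_lengths_mm=tuple(cat.get("lengths_mm", ScrewCatalog().allowed_lengths_mm)),
            allowed_diameters_mm=tuple(cat.get("diameters_mm", ScrewCatalog().allowed_diameters_mm)),
        )
    if "angle_grid" in doc:
        kwargs["angle_grid"] = AngleGrid(**doc["angle_grid"])
    for key in ("entry_step_mm", "margin_mm"):
        if key in doc:
            kwargs[key] = float(doc[key])
    return PlanConfig(**kwargs)


def grade_params_from_dict(doc: dict) -> GradeParams:
    kwargs = {}
    if "surface_step_mm" in doc:
        kwargs["surface_step_mm"] = float(doc["surface_step_mm"])
    if "epsilon_mm" in doc:
        kwargs["epsilon_mm"] = float(doc["epsilon_mm"])
    return GradeParams(**kwargs)


def phantom_spec_from_dict(doc: dict, seed=None) -> PhantomSpec:
    fields = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(doc) - fields
    if unknown:
        raise ConfigError(f"unknown phantom spec fields: {sorted(unknown)}")
    if "voxel_spacing_mm" in doc:
        doc = {**doc, "voxel_spacing_mm": tuple(doc["voxel_spacing_mm"])}
    spec = PhantomSpec(**doc)
    if seed is not None:
        spec = dataclasses.replace(spec, rng_seed=int(seed))
    return spec


# ---------------------------------------------------------------------------
# Screws and plans (JSON)
# ---------------------------------------------------------------------------

def screw_to_dict(screw: ScrewSpec) -> dict:
    return {
        "side": screw.side,
        "entry_mm": list(screw.entry_mm),
        "direction": list(screw.direction),
        "length_mm": screw.length_mm,
        "diameter_mm": screw.diameter_mm,
    }


def screw_from_dict(doc: dict) -> ScrewSpec:
    try:
        direction = np.asarray(doc["direction"], dtype=float)
        norm = np.linalg.norm(direction)
        if not 0.5 < norm < 2.0:
            raise ValueError(f"direction norm {norm:.3g} far from 1")
        return ScrewSpec(
            side=doc["side"],
            entry_mm=tuple(doc["entry_mm"]),
            direction=tuple(direction / norm),  # hand-written files may be unnormalised
            length_mm=float(doc["length_mm"]),
            diameter_mm=float(doc["diameter_mm"]),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"invalid screw record: {exc}") from exc


def plan_to_dict(plan: ScrewPlan) -> dict:
    return {
        "screw": screw_to_dict(plan.screw),
        "score": dataclasses.asdict(plan.score),
        "constraints": dataclasses.asdict(plan.constraints),
        "n_candidates_evaluated": plan.n_candidates_evaluated,
    }


def plan_from_dict(doc: dict) -> ScrewPlan:
    return ScrewPlan(
        screw=screw_from_dict(doc["screw"]),
        score=TrajectoryScore(**doc["score"]),
        constraints=ConstraintReport(**doc["constraints"]),
        n_candidates_evaluated=int(doc["n_candidates_evaluated"]),
    )


def make_plan_document(results: dict, volume_path, labels_path, config: PlanConfig) -> dict:
    """Assemble the JSON plan document from per-side results (plan or error)."""
    sides = {}
    for side, res in results.items():
        if isinstance(res, ScrewPlan):
            sides[side] = {"plan": plan_to_dict(res)}
        else:
            sides[side] = {"error": {"code": res.code, "message": str(res)}}
    return {
        "schema_version": SCHEMA_VERSION,
        "created": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            "volume": str(volume_path),
            "labels": str(labels_path),
            "volume_sha256": sha256_of(volume_path),
            "labels_sha256": sha256_of(labels_path),
        },
        "config": {
            "catalog": {
                "lengths_mm": list(config.catalog.allowed_lengths_mm),
                "diameters_mm": list(config.catalog.allowed_diameters_mm),
            },
            "angle_grid": dataclasses.asdict(config.angle_grid),
            "entry_step_mm": config.entry_step_mm,
            "margin_mm": config.margin_mm,
        },
        "sides": sides,
    }


def write_plan(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2))


def read_plan(path) -> dict:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise FormatError(f"{path}: not a plan document (missing schema_version)")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema version {doc['schema_version']!r} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    for key in ("inputs", "config", "sides"):
        if key not in doc:
            raise FormatError(f"{path}: plan document missing {key!r}")
    return doc


def plans_from_document(doc: dict) -> dict:
    """Extract {side: ScrewPlan} for the sides that planned successfully."""
    out = {}
    for side, entry in doc["sides"].items():
        if "plan" in entry:
            out[side] = plan_from_dict(entry["plan"])
    return out


def read_screws(path) -> list[tuple[str, ScrewSpec]]:
    """Read screws from either a plan document or a ``{"screws": [...]}``
    JSON file; returns (id, ScrewSpec) pairs."""
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, dict) and "sides" in raw:
        doc = read_plan(path)
        return [
            (f"plan-{side}", plan.screw) for side, plan in plans_from_document(doc).items()
        ]
    if isinstance(raw, dict) and "screws" in raw:
        out = []
        for i, rec in enumerate(raw["screws"]):
            out.append((str(rec.get("id", i)), screw_from_dict(rec)))
        return out
    raise FormatError(f"{path}: expected a plan document or a 'screws' list")


# ---------------------------------------------------------------------------
# Grade tables (CSV)
# ---------------------------------------------------------------------------

def write_grades_csv(rows, path) -> None:
    """rows: iterables of (id, side, GRResult) or dicts."""
    records = []
    for row in rows:
        if isinstance(row, dict):
            records.append(row)
        else:
            sid, side, res = row
            records.append(
                {"id": sid, "side": side, "depth_mm": res.breach_depth_mm, "grade": res.grade}
            )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_grades_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"id", "side", "grade"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: grade table missing columns {sorted(missing)}")
    return df
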