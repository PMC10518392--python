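"""Voxel-grid containers and the anatomical label vocabulary.

World coordinates are millimetres on axes x = left->right, y = posterior->
anterior, z = inferior->superior.  Voxel indices are 0-based and a voxel's
world position is the position of its *center*::

    world = origin_mm + index * voxel_spacing_mm

A point belongs to the voxel whose center is nearest, i.e. the voxel with
index ``round((world - origin) / spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Anatomical label codes.
BACKGROUND = 0
TRABECULAR_BODY = 1
CORTICAL_SHELL = 2
PEDICLE_L = 3
PEDICLE_R = 4
ENDPLATE_SUP = 5
ENDPLATE_INF = 6
POSTERIOR_ELEMENTS = 7
ENTRY_DISC_L = 8
ENTRY_DISC_R = 9

LABEL_NAMES = {
    BACKGROUND: "BACKGROUND",
    TRABECULAR_BODY: "TRABECULAR_BODY",
    CORTICAL_SHELL: "CORTICAL_SHELL",
    PEDICLE_L: "PEDICLE_L",
    PEDICLE_R: "PEDICLE_R",
    ENDPLATE_SUP: "ENDPLATE_SUP",
    ENDPLATE_INF: "ENDPLATE_INF",
    POSTERIOR_ELEMENTS: "POSTERIOR_ELEMENTS",
    ENTRY_DISC_L: "ENTRY_DISC_L",
    ENTRY_DISC_R: "ENTRY_DISC_R",
}

#: Bony compartments proper.
BONE_LABELS = frozenset(
    {
        TRABECULAR_BODY,
        CORTICAL_SHELL,
        PEDICLE_L,
        PEDICLE_R,
        ENDPLATE_SUP,
        ENDPLATE_INF,
        POSTERIOR_ELEMENTS,
    }
)

#: Bone envelope used for containment / breach tests.  The entry discs are
#: annotated patches of the posterior cortical surface, so a screw surface
#: point inside them is on bone, not outside it.
CONTAINMENT_LABELS = frozenset(BONE_LABELS | {ENTRY_DISC_L, ENTRY_DISC_R})

PEDICLE_LABEL = {"L": PEDICLE_L, "R": PEDICLE_R}
ENTRY_DISC_LABEL = {"L": ENTRY_DISC_L, "R": ENTRY_DISC_R}


def _check_grid(shape, spacing, origin):
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if len(shape) != 3:
        raise ValueError(f"grid must be 3-D, got shape {shape}")
    if spacing.shape != (3,) or not np.all(spacing > 0):
        raise ValueError(f"voxel spacing must be 3 positive floats, got {spacing}")
    if origin.shape != (3,):
        raise ValueError(f"origin must be a 3-vector, got {origin}")
    return shape, spacing, origin


@dataclass
class _Grid:
    """Shared grid geometry of a volume or label map."""

    voxel_spacing_mm: np.ndarray
    origin_mm: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        raise NotImplementedError

    # ---- coordinate transforms -------------------------------------------------
    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for integer or float indices."""
        return self.origin_mm + np.asarray(idx, dtype=float) * self.voxel_spacing_mm

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous (float) voxel index of world points."""
        return (np.asarray(world, dtype=float) - self.origin_mm) / self.voxel_spacing_mm

    def world_to_nearest_voxel(self, world: np.ndarray) -> np.ndarray:
        return np.rint(self.world_to_index(world)).astype(int)

    def in_grid(self, world: np.ndarray) -> np.ndarray:
        """Boolean mask: does each world point fall inside the grid?"""
        idx = self.world_to_nearest_voxel(world)
        shp = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shp), axis=-1)

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        """World coordinates of the centers of voxels where ``mask`` is True."""
        return self.index_to_world(np.argwhere(mask))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))


@dataclass
class ImageVolume(_Grid):
    """3-D scalar intensity grid in pseudo-Hounsfield units."""

    intensities: np.ndarray = field(default=None)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        shape, self.voxel_spacing_mm, self.origin_mm = _check_grid(
            self.intensities.shape, self.voxel_spacing_mm, self.origin_mm
        )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self):
        return self.intensities.shape


@dataclass
class AnatomyLabelMap(_Grid):
    """3-D grid of anatomical label codes, co-registered with an ImageVolume."""

    labels: np.ndarray = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label data must be integer-valued")
        self.labels = self.labels.astype(np.uint8, casting="unsafe")
        shape, self.voxel_spacing_mm, self.origin_mm = _check_grid(
            self.labels.shape, self.voxel_spacing_mm, self.origin_mm
        )
        unknown = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if unknown:
            raise ValueError(f"unknown label codes: {sorted(unknown)}")
        self._caches: dict = {}

    @property
    def shape(self):
        return self.labels.shape

    def mask(self, labels) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given label codes."""
        if np.isscalar(labels):
            return self.labels == labels
        return np.isin(self.labels, list(labels))

    def labels_at(self, world: np.ndarray) -> np.ndarray:
        """Nearest-voxel label lookup for world points; BACKGROUND outside grid."""
        world = np.atleast_2d(np.asarray(world, dtype=float))
        idx = self.world_to_nearest_voxel(world)
        shp = np.asarray(self.shape)
        inside = np.all((idx >= 0) & (idx < shp), axis=-1)
        out = np.full(len(world), BACKGROUND, dtype=np.uint8)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def cache(self, key, builder):
        """Memoise expensive derived geometry (KD-trees, boundary sets)."""
        if key not in self._caches:
            self._caches[key] = builder()
        return self._caches[key]
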