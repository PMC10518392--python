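"""Shared fixtures: phantoms are expensive enough to build once per session."""

import numpy as np
import pytest

import pediplan as pp


@pytest.fixture(scope="session")
def default_phantom():
    """The default lumbar-scale phantom (9 mm pedicles, 0.625 mm voxels)."""
    return pp.make_phantom(pp.PhantomSpec())


@pytest.fixture(scope="session")
def half_mm_phantom():
    """Finer-grid phantom used where sub-voxel agreement is asserted."""
    return pp.make_phantom(pp.PhantomSpec(voxel_spacing_mm=(0.5, 0.5, 0.5)))


@pytest.fixture(scope="session")
def angled_phantom():
    """Phantom with strongly converging pedicles (15 degrees)."""
    return pp.make_phantom(pp.PhantomSpec(pedicle_transverse_angle_deg=15.0))


@pytest.fixture(scope="session")
def coarse_plans(default_phantom):
    """Both-side plans on the default phantom at the coarse search grid."""
    ph = default_phantom
    return {
        side: pp.plan_side(ph.volume, ph.labels, side, pp.COARSE_CONFIG)
        for side in ("L", "R")
    }


@pytest.fixture()
def axis_screw(default_phantom):
    """A well-centered screw along the true left pedicle axis."""
    ped = default_phantom.truth.pedicles["L"]
    return pp.ScrewSpec(
        side="L",
        entry_mm=ped.entry_center_mm,
        direction=ped.axis_direction,
        length_mm=45.0,
        diameter_mm=6.0,
    )


def tube_label_map(
    radius_mm=4.0,
    length_mm=30.0,
    spacing=0.5,
    extent_mm=16.0,
    with_body=True,
):
    """A bare circular corridor along +y, optionally ending in a bone block.

    Analytic construction for clearance/breach oracles: tube of known radius
    surrounded by background, with a trabecular block at the anterior end so
    medial orientation (toward the block's midline) is well defined.
    """
    sp = np.array([spacing] * 3)
    nx = int(round(2 * extent_mm / spacing)) + 1
    ny = int(round((length_mm + (20.0 if with_body else 4.0)) / spacing)) + 1
    origin = np.array([-(nx - 1) * spacing / 2.0, -2.0, -(nx - 1) * spacing / 2.0])
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nx)
    xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")
    labels = np.zeros((nx, ny, nx), dtype=np.uint8)
    tube = (xx**2 + zz**2 <= radius_mm**2) & (yy >= 0) & (yy <= length_mm)
    labels[tube] = pp.PEDICLE_L
    if with_body:
        body = (yy > length_mm) & (yy <= length_mm + 16.0) & (np.abs(xx) < 14) & (np.abs(zz) < 14)
        labels[body] = pp.TRABECULAR_BODY
    return pp.AnatomyLabelMap(voxel_spacing_mm=sp, origin_mm=origin, labels=labels)
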