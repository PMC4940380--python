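"""Shared fixtures: analytic orientation fields with known oracle geometry."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thalatrack.diffusion import OrientationField
from thalatrack.grid import VolumeGrid, centered_grid

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


def make_uniform_field(
    grid: VolumeGrid,
    direction,
    mask: np.ndarray | None = None,
    kappa: float = np.inf,
) -> OrientationField:
    """Single fibre population with one mean direction everywhere."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    shape = grid.shape
    directions = np.zeros(shape + (2, 3))
    directions[..., 0, :] = d
    fractions = np.zeros(shape + (2,))
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    fractions[mask, 0] = 1.0
    kap = np.where(mask, float(kappa), np.nan)
    return OrientationField(
        grid=grid, directions=directions, fractions=fractions, kappa=kap, mask=mask
    )


def make_tube_field(kappa: float = np.inf):
    """Straight tube along +y inside a 20^3 x 2 mm grid.

    Valid where |x| <= 5 and |z| <= 5 mm; the natural target is a two-ended
    slab |y| >= 13 so that streamlines launched in either axial direction
    reach it.  Returns (field, target_mask, slab_name).
    """
    grid = centered_grid((20, 20, 20), 2.0)
    coords = grid.coordinate_volume()
    tube = (np.abs(coords[..., 0]) <= 5) & (np.abs(coords[..., 2]) <= 5)
    field = make_uniform_field(grid, (0, 1, 0), mask=tube, kappa=kappa)
    target = tube & (np.abs(coords[..., 1]) >= 13)
    return field, target


ARC_CENTER = np.array([-20.0, 0.0, 0.0])  # in the x-z plane
ARC_RADIUS = 26.0


def make_arc_field(kappa: float = np.inf):
    """Circular arc band in the x-z plane of a 30^3 x 2 mm grid.

    Orientations are tangents of circles concentric with ``ARC_CENTER``, so
    the analytic trajectory of a streamline started at p0 is the circle of
    radius |p0 - C| — an exact tracker oracle.  The band is mirror-symmetric
    in the arc angle theta (positive and negative branches), so both axial
    launch directions traverse the same ordered sequence of angle bands.

    Returns (field, masks) where masks contains the seed voxels near
    theta = 0, two way-point bands (wp1 at |theta| in [25, 35] deg, wp2 at
    [55, 65] deg) and the terminal band at |theta| >= 85 deg.
    """
    grid = centered_grid((30, 30, 30), 2.0)
    coords = grid.coordinate_volume()
    dx = coords[..., 0] - ARC_CENTER[0]
    dz = coords[..., 2] - ARC_CENTER[2]
    r = np.hypot(dx, dz)
    theta = np.degrees(np.arctan2(dz, dx))  # 0 at +x axis, +90 at +z axis
    band = (np.abs(r - ARC_RADIUS) <= 5.0) & (np.abs(coords[..., 1]) <= 5.0)
    band &= (theta >= -100.0) & (theta <= 100.0)

    shape = grid.shape
    directions = np.zeros(shape + (2, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        tx = -dz / np.where(r > 0, r, 1.0)
        tz = dx / np.where(r > 0, r, 1.0)
    directions[..., 0, 0] = tx
    directions[..., 0, 2] = tz
    fractions = np.zeros(shape + (2,))
    fractions[band, 0] = 1.0
    field = OrientationField(
        grid=grid,
        directions=directions,
        fractions=fractions,
        kappa=np.where(band, float(kappa), np.nan),
        mask=band,
    )
    abs_theta = np.abs(theta)
    masks = {
        "seed": band & (abs_theta <= 3.0) & (np.abs(coords[..., 1]) <= 1.5)
        & (np.abs(r - ARC_RADIUS) <= 1.5),
        "wp1": band & (abs_theta >= 25.0) & (abs_theta <= 35.0),
        "wp2": band & (abs_theta >= 55.0) & (abs_theta <= 65.0),
        "terminal": band & (abs_theta >= 85.0),
    }
    return field, masks


@pytest.fixture(scope="session")
def tube():
    return make_tube_field()


@pytest.fixture(scope="session")
def arc():
    return make_arc_field()
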