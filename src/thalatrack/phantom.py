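"""Synthetic multi-subject, multi-scanner phantoms.

The phantom emulates the anatomy the pipeline operates on: a thalamus
containing two nucleus labels (a VLpv-like motor relay and a VPLp-like
somatosensory relay), cortical target regions (precentral, postcentral,
supplementary motor), cerebellar structures (dentate nucleus, superior
cerebellar peduncle) and the red nucleus, plus orientation fields realising
thalamocortical bundles and a decussating cerebello-thalamic arc.

All structures are analytic primitives — axis-aligned ellipsoids, boxes and
tubes around cubic-spline centerlines — so that tracker tests have exact
oracle trajectories.  Geometry is defined in coordinates normalised by the
grid half-extent, which means the anatomy scales with the requested grid.

Inter-subject variability is a smooth random warp (sum of three
low-frequency sinusoidal displacement fields, scaled to a requested RMS
magnitude in mm) applied to the analytic primitives before voxelisation.
Inter-scanner variability is an additive reduction of the orientation
dispersion concentration plus a scanner-specific systematic perturbation of
the per-voxel directions.  Both effects are deterministic functions of the
master seed (hierarchical seeding: master -> subject -> scanner), so the
whole phantom set is a pure function of its configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .diffusion import GradientTable, OrientationField, make_gradient_scheme
from .grid import VolumeGrid, centered_grid

__all__ = [
    "PhantomConfig",
    "LabelVolume",
    "PhantomGeometry",
    "SubjectInstance",
    "PhantomSet",
    "PhantomSizingError",
    "generate_atlas",
    "generate_subject",
    "apply_scanner",
    "simulate_dwi",
    "generate_phantom_set",
    "atlas_geometry",
    "subject_geometry",
    "regions_along_path",
]

log = logging.getLogger(__name__)


class PhantomSizingError(ValueError):
    """Raised when the grid is too small to voxelise every phantom region."""


# ---------------------------------------------------------------------------
# configuration


def _as_tuple3(value) -> tuple:
    arr = np.broadcast_to(np.asarray(value), (3,))
    return tuple(arr.tolist())


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: four subjects scanned on
    three scanners with a 32-direction b=1000 s/mm^2 protocol on a 2 mm
    grid.  ``subject_displacement_mm`` is the RMS magnitude of the smooth
    inter-subject warp (residual anatomical variability after spatial
    normalisation); ``scanner_dispersion_delta`` is the per-scanner additive
    reduction of the Watson concentration and ``scanner_noise_sd`` the
    per-scanner multiplicative DWI intensity noise SD.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_subjects: int = 4
    n_scanners: int = 3
    subject_displacement_mm: float = 1.5
    scanner_dispersion_delta: tuple[float, ...] | None = None
    scanner_noise_sd: tuple[float, ...] | None = None
    master_seed: int = 0
    b_value: float = 1000.0
    n_directions: int = 32
    # orientation model
    kappa: float = 60.0
    bundle_radius_mm: float = 4.0
    ctt_radius_mm: float = 4.0
    direction_jitter_per_delta: float = 0.006
    # diffusivities (mm^2/s) for DWI synthesis
    lambda_parallel: float = 1.7e-3
    lambda_perp: float = 3.0e-4
    background_adc: float = 8.0e-4
    s0: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", _as_tuple3(self.grid_shape))
        object.__setattr__(self, "voxel_size_mm", _as_tuple3(self.voxel_size_mm))
        if any(int(n) < 32 for n in self.grid_shape):
            raise ValueError("grid_shape must be at least (32, 32, 32)")
        if self.n_subjects < 1 or self.n_scanners < 1:
            raise ValueError("n_subjects and n_scanners must be >= 1")
        if self.subject_displacement_mm < 0:
            raise ValueError("subject_displacement_mm must be >= 0")
        delta = self.scanner_dispersion_delta
        if delta is None:
            delta = tuple(20.0 * j for j in range(self.n_scanners))
        else:
            delta = tuple(np.broadcast_to(np.asarray(delta, float), (self.n_scanners,)).tolist()) \
                if np.ndim(delta) == 0 else tuple(float(d) for d in delta)
        if len(delta) != self.n_scanners:
            raise ValueError("scanner_dispersion_delta must have one entry per scanner")
        noise = self.scanner_noise_sd
        if noise is None:
            noise = tuple(0.01 * j for j in range(self.n_scanners))
        else:
            noise = tuple(np.broadcast_to(np.asarray(noise, float), (self.n_scanners,)).tolist()) \
                if np.ndim(noise) == 0 else tuple(float(s) for s in noise)
        if len(noise) != self.n_scanners:
            raise ValueError("scanner_noise_sd must have one entry per scanner")
        if any(d < 0 for d in delta) or any(s < 0 for s in noise):
            raise ValueError("noise scales must be >= 0")
        object.__setattr__(self, "scanner_dispersion_delta", delta)
        object.__setattr__(self, "scanner_noise_sd", noise)
        if self.n_directions < 6:
            raise ValueError("n_directions must be >= 6")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def make_grid(self) -> VolumeGrid:
        return centered_grid(self.grid_shape, self.voxel_size_mm)

    def stream(self, *key: int) -> np.random.Generator:
        """Deterministic RNG sub-stream derived from the master seed."""
        entropy = [int(self.master_seed) & 0x7FFFFFFF] + [int(k) for k in key]
        return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# label volume

LEGEND: dict[int, str] = {
    1: "thalamus_L", 2: "thalamus_R",
    3: "vlpv_L", 4: "vlpv_R",
    5: "vplp_L", 6: "vplp_R",
    7: "precentral_L", 8: "precentral_R",
    9: "postcentral_L", 10: "postcentral_R",
    11: "sma_L", 12: "sma_R",
    13: "cerebellum_L", 14: "cerebellum_R",
    15: "dentate_L", 16: "dentate_R",
    17: "scp_L", 18: "scp_R",
    19: "red_nucleus_L", 20: "red_nucleus_R",
}
_NAME_TO_ID = {v: k for k, v in LEGEND.items()}

# containment hierarchy: nucleus labels overwrite their parent in the array,
# so a parent's mask is the union over its member ids
_HIERARCHY: dict[str, tuple[str, ...]] = {
    "thalamus_L": ("thalamus_L", "vlpv_L", "vplp_L"),
    "thalamus_R": ("thalamus_R", "vlpv_R", "vplp_R"),
    "cerebellum_L": ("cerebellum_L", "dentate_L"),
    "cerebellum_R": ("cerebellum_R", "dentate_R"),
}


@dataclass
class LabelVolume:
    """Integer region labels on a grid, with a legend and the AC-PC plane."""

    grid: VolumeGrid
    labels: np.ndarray  # int16, grid.shape
    legend: dict[int, str]
    acpc_z_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    def ids_for(self, name: str) -> tuple[int, ...]:
        """Resolve a region name (hierarchy- and side-aware) to label ids."""
        if name in _NAME_TO_ID:
            members = _HIERARCHY.get(name, (name,))
            return tuple(_NAME_TO_ID[m] for m in members)
        # unsided name -> union of both hemispheres
        sided = (f"{name}_L", f"{name}_R")
        if all(s in _NAME_TO_ID for s in sided):
            return self.ids_for(sided[0]) + self.ids_for(sided[1])
        raise KeyError(f"unknown region name: {name!r}")

    def mask(self, name: str) -> np.ndarray:
        ids = self.ids_for(name)
        return np.isin(self.labels, ids)

    def validate(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        missing = [LEGEND[i] for i in self.legend if i not in present]
        if missing:
            raise PhantomSizingError(
                f"grid too small: regions missing after voxelisation: {missing}"
            )
        for side in "LR":
            both = self.mask(f"vlpv_{side}") & self.mask(f"vplp_{side}")
            if both.any():
                raise ValueError("vlpv and vplp overlap")


# ---------------------------------------------------------------------------
# analytic geometry (normalised coordinates: world_mm / half_extent_mm)

# ellipsoids: name -> (center, semi-axes); x entries are for the RIGHT (+x)
# side and are mirrored for the left
_ELLIPSOIDS = {
    "thalamus": ((0.23, 0.00, 0.04), (0.15, 0.19, 0.15)),
    "vlpv": ((0.27, 0.085, 0.04), (0.067, 0.075, 0.067)),
    "vplp": ((0.27, -0.105, 0.04), (0.067, 0.075, 0.067)),
    "cerebellum": ((0.29, -0.62, -0.50), (0.27, 0.27, 0.25)),
    "dentate": ((0.25, -0.62, -0.50), (0.073, 0.073, 0.073)),
    "scp": ((0.146, -0.458, -0.27), (0.0625, 0.083, 0.083)),
    "red_nucleus": ((0.104, -0.1875, -0.104), (0.0625, 0.0625, 0.0625)),
}

# boxes: name -> (lo, hi), right side
_BOXES = {
    "precentral": ((0.12, 0.08, 0.54), (0.70, 0.33, 0.79)),
    "postcentral": ((0.12, -0.33, 0.54), (0.70, -0.08, 0.79)),
    "sma": ((0.04, 0.38, 0.62), (0.25, 0.62, 0.83)),
}

# bundle centerline control points (right side); the CTT entry describes the
# tract terminating in the RIGHT thalamus, i.e. seeded from the LEFT dentate
_BUNDLE_CONTROLS = {
    "tc_precentral": (
        (0.271, 0.085, 0.042),
        (0.3125, 0.125, 0.208),
        (0.333, 0.167, 0.417),
        (0.3125, 0.23, 0.68),
    ),
    "tc_sma": (
        (0.271, 0.085, 0.042),
        (0.208, 0.167, 0.25),
        (0.167, 0.333, 0.5),
        (0.146, 0.458, 0.708),
    ),
    "tc_postcentral": (
        (0.271, -0.105, 0.042),
        (0.3125, -0.125, 0.208),
        (0.333, -0.167, 0.417),
        (0.3125, -0.23, 0.68),
    ),
    "ctt": (
        (-0.25, -0.62, -0.50),   # contralateral dentate
        (-0.146, -0.458, -0.27),  # contralateral SCP
        (0.0, -0.333, -0.167),    # decussation
        (0.104, -0.1875, -0.104),  # ipsilateral red nucleus
        (0.167, -0.063, 0.0),
        (0.271, 0.085, 0.042),    # terminates in vlpv
    ),
}

_SIDE_SIGN = {"L": -1.0, "R": 1.0}


@dataclass
class PhantomGeometry:
    """Analytic primitives in world mm, after any subject warp.

    ``centerlines`` maps bundle names (e.g. ``"ctt_L"`` for the tract that
    terminates in the left thalamus) to densely resampled (points, tangents)
    arrays — the oracle trajectories for tracker tests.
    """

    ellipsoids: dict[str, tuple[np.ndarray, np.ndarray]]
    boxes: dict[str, tuple[np.ndarray, np.ndarray]]
    centerlines: dict[str, tuple[np.ndarray, np.ndarray]]
    controls: dict[str, np.ndarray]


def _resample_spline(controls_mm: np.ndarray, step_mm: float = 0.6):
    """Cubic spline through control points, resampled at ~step_mm arclength."""
    controls_mm = np.asarray(controls_mm, dtype=float)
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(controls_mm, axis=0), axis=1))]
    spline = CubicSpline(chord, controls_mm, axis=0)
    # densify, then re-measure arclength for near-uniform sampling
    t_fine = np.linspace(0.0, chord[-1], max(int(chord[-1] / 0.2), 8))
    pts_fine = spline(t_fine)
    arc = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pts_fine, axis=0), axis=1))]
    n = max(int(arc[-1] / step_mm), 4)
    targets = np.linspace(0.0, arc[-1], n)
    t_samp = np.interp(targets, arc, t_fine)
    points = spline(t_samp)
    tangents = spline(t_samp, 1)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return points, tangents


def _build_geometry(config: PhantomConfig, warp=None) -> PhantomGeometry:
    grid = config.make_grid()
    half = grid.half_extent_mm  # per-axis scale from normalised units to mm

    def to_mm(p):
        return np.asarray(p, dtype=float) * half

    def displaced(p_mm):
        if warp is None:
            return p_mm
        return p_mm + warp(p_mm)

    ellipsoids: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, (c, a) in _ELLIPSOIDS.items():
        for side, sign in _SIDE_SIGN.items():
            center = to_mm((sign * c[0], c[1], c[2]))
            ellipsoids[f"{name}_{side}"] = (displaced(center), to_mm(a))
    boxes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, (lo, hi) in _BOXES.items():
        for side, sign in _SIDE_SIGN.items():
            lo_mm = to_mm((sign * lo[0], lo[1], lo[2]))
            hi_mm = to_mm((sign * hi[0], hi[1], hi[2]))
            lo_s, hi_s = np.minimum(lo_mm, hi_mm), np.maximum(lo_mm, hi_mm)
            shift = displaced((lo_s + hi_s) / 2.0) - (lo_s + hi_s) / 2.0
            boxes[f"{name}_{side}"] = (lo_s + shift, hi_s + shift)
    centerlines: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    controls: dict[str, np.ndarray] = {}
    for name, ctrl in _BUNDLE_CONTROLS.items():
        ctrl = np.asarray(ctrl, dtype=float)
        for side, sign in _SIDE_SIGN.items():
            pts = ctrl.copy()
            pts[:, 0] *= sign
            pts_mm = pts * half
            if warp is not None:
                pts_mm = pts_mm + warp(pts_mm)
            controls[f"{name}_{side}"] = pts_mm
            centerlines[f"{name}_{side}"] = _resample_spline(pts_mm)
    return PhantomGeometry(
        ellipsoids=ellipsoids, boxes=boxes, centerlines=centerlines, controls=controls
    )


# sub-voxel sampling offsets for majority-rule voxelisation: occupancy is
# estimated on a 3^3 lattice inside each voxel so small structures keep a
# stable voxel count when displaced by a warp
_SUBOFFSETS = (
    np.stack(
        np.meshgrid(*[np.array([-1.0, 0.0, 1.0]) / 3] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
)


def _occupancy_mask(grid: VolumeGrid, inside_fn, lo_mm, hi_mm) -> np.ndarray:
    """Voxels whose sub-sampled occupancy of an analytic region is >= 1/2."""
    lo_v = np.floor(grid.world_to_voxel(lo_mm)).astype(int) - 1
    hi_v = np.ceil(grid.world_to_voxel(hi_mm)).astype(int) + 1
    lo_v = np.clip(lo_v, 0, np.asarray(grid.shape) - 1)
    hi_v = np.clip(hi_v, 0, np.asarray(grid.shape) - 1)
    ii, jj, kk = np.meshgrid(
        *[np.arange(lo_v[a], hi_v[a] + 1) for a in range(3)], indexing="ij"
    )
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    occ = np.zeros(ijk.shape[0])
    for off in _SUBOFFSETS:
        pts = grid.voxel_to_world(ijk + off)
        occ += inside_fn(pts)
    occ /= len(_SUBOFFSETS)
    mask = np.zeros(grid.shape, dtype=bool)
    sel = occ >= 0.5
    sub = ijk[sel].astype(int)
    mask[sub[:, 0], sub[:, 1], sub[:, 2]] = True
    return mask


def _paint_labels(grid: VolumeGrid, geom: PhantomGeometry) -> np.ndarray:
    labels = np.zeros(grid.shape, dtype=np.int16)

    def ellipsoid_mask(name: str) -> np.ndarray:
        c, a = geom.ellipsoids[name]

        def inside(pts):
            d = (pts - c) / a
            return np.sum(d * d, axis=-1) <= 1.0

        return _occupancy_mask(grid, inside, c - a, c + a)

    def box_mask(name: str) -> np.ndarray:
        lo, hi = geom.boxes[name]

        def inside(pts):
            return np.all((pts >= lo) & (pts <= hi), axis=-1)

        return _occupancy_mask(grid, inside, lo, hi)

    def paint(name: str, mask: np.ndarray) -> None:
        labels[mask] = _NAME_TO_ID[name]

    # painting order encodes priority: later regions win voxel conflicts.
    # Deep, small structures (CTT way-points) are painted last so a warp
    # cannot erode them against their larger neighbours.
    for side in "LR":
        paint(f"cerebellum_{side}", ellipsoid_mask(f"cerebellum_{side}"))
    for side in "LR":
        thal = ellipsoid_mask(f"thalamus_{side}")
        paint(f"thalamus_{side}", thal)
        # nucleus labels live strictly inside the thalamus mask
        paint(f"vlpv_{side}", ellipsoid_mask(f"vlpv_{side}") & thal)
        paint(f"vplp_{side}", ellipsoid_mask(f"vplp_{side}") & thal)
    for side in "LR":
        for cortex in ("precentral", "postcentral", "sma"):
            paint(f"{cortex}_{side}", box_mask(f"{cortex}_{side}"))
    for side in "LR":
        paint(f"dentate_{side}", ellipsoid_mask(f"dentate_{side}"))
        paint(f"scp_{side}", ellipsoid_mask(f"scp_{side}"))
        paint(f"red_nucleus_{side}", ellipsoid_mask(f"red_nucleus_{side}"))
    return labels


def _build_orientation_field(
    grid: VolumeGrid, geom: PhantomGeometry, config: PhantomConfig
) -> OrientationField:
    coords = grid.coordinate_volume().reshape(-1, 3)
    n_vox = coords.shape[0]
    directions = np.zeros((n_vox, 2, 3), dtype=np.float64)
    npop = np.zeros(n_vox, dtype=np.int8)

    radii = {
        "tc_precentral": config.bundle_radius_mm,
        "tc_sma": config.bundle_radius_mm,
        "tc_postcentral": config.bundle_radius_mm,
        "ctt": config.ctt_radius_mm,
    }
    for name, (points, tangents) in geom.centerlines.items():
        radius = radii[name.rsplit("_", 1)[0]]
        lo = points.min(axis=0) - radius
        hi = points.max(axis=0) + radius
        box = np.flatnonzero(np.all((coords >= lo) & (coords <= hi), axis=-1))
        if box.size == 0:
            continue
        dist, nearest = cKDTree(points).query(coords[box])
        sel = box[dist <= radius]
        tang = tangents[nearest[dist <= radius]]
        empty = npop[sel] == 0
        idx0 = sel[empty]
        directions[idx0, 0, :] = tang[empty]
        npop[idx0] = 1
        occupied = sel[~empty]
        if occupied.size:
            t_new = tang[~empty]
            existing = directions[occupied, 0, :]
            # axial angle between populations; only genuinely crossing
            # orientations get a second population slot
            cosang = np.abs(np.sum(existing * t_new, axis=-1))
            crossing = (cosang < np.cos(np.deg2rad(25.0))) & (npop[occupied] == 1)
            idx1 = occupied[crossing]
            directions[idx1, 1, :] = t_new[crossing]
            npop[idx1] = 2

    fractions = np.zeros((n_vox, 2), dtype=np.float64)
    fractions[npop == 1, 0] = 1.0
    fractions[npop == 2, :] = 0.5
    mask = npop > 0
    kappa = np.where(mask, float(config.kappa), np.nan)
    shape = grid.shape
    return OrientationField(
        grid=grid,
        directions=directions.reshape(shape + (2, 3)),
        fractions=fractions.reshape(shape + (2,)),
        kappa=kappa.reshape(shape),
        mask=mask.reshape(shape),
    )


# ---------------------------------------------------------------------------
# subject warp


class SinusoidalWarp:
    """Smooth displacement field: sum of 3 low-frequency sinusoidal modes.

    d_c(x) = sum_m a[m, c] * sin(2 pi k_m . x_hat + phi[m, c]) where x_hat is
    the position in grid-normalised coordinates.  Amplitudes are rescaled so
    the RMS of |d| over the grid equals the requested magnitude in mm.
    """

    N_MODES = 3

    def __init__(self, wavevectors, amplitudes, phases, half_extent_mm):
        self.wavevectors = np.asarray(wavevectors, dtype=float)  # (M, 3)
        self.amplitudes = np.asarray(amplitudes, dtype=float)  # (M, 3)
        self.phases = np.asarray(phases, dtype=float)  # (M, 3)
        self.half_extent_mm = np.asarray(half_extent_mm, dtype=float)

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        x_hat = pts / self.half_extent_mm
        phase = 2.0 * np.pi * (x_hat @ self.wavevectors.T)  # (n, M)
        disp = np.zeros_like(pts)
        for c in range(3):
            disp[:, c] = np.sum(
                self.amplitudes[:, c] * np.sin(phase + self.phases[:, c]), axis=1
            )
        return disp.reshape(np.shape(points_mm))

    def scaled(self, factor: float) -> "SinusoidalWarp":
        return SinusoidalWarp(
            self.wavevectors, self.amplitudes * factor, self.phases, self.half_extent_mm
        )

    @classmethod
    def random(
        cls, rng: np.random.Generator, rms_mm: float, half_extent_mm
    ) -> "SinusoidalWarp":
        m = cls.N_MODES
        # random low-frequency wave vectors: 0.25-0.75 cycles per normalised
        # unit, i.e. 0.5-1.5 cycles across the full grid extent
        direction = rng.normal(size=(m, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        magnitude = rng.uniform(0.25, 0.75, size=(m, 1))
        wavevectors = direction * magnitude
        amplitudes = rng.normal(size=(m, 3))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(m, 3))
        warp = cls(wavevectors, amplitudes, phases, half_extent_mm)
        # empirical RMS over a coarse lattice of the normalised cube
        ax = np.linspace(-1.0, 1.0, 9) * np.asarray(half_extent_mm)[:, None]
        gx, gy, gz = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
        lattice = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        disp = warp(lattice)
        rms = float(np.sqrt(np.mean(np.sum(disp**2, axis=1))))
        factor = rms_mm / rms if rms > 0 else 0.0
        return warp.scaled(factor)

    def truth(self) -> dict:
        return {
            "wavevectors": self.wavevectors.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "phases": self.phases.tolist(),
        }


def _geometry_fits(config: PhantomConfig, geom: PhantomGeometry) -> bool:
    half = config.make_grid().half_extent_mm
    for center, semi in geom.ellipsoids.values():
        if np.any(np.abs(center) + semi > half):
            return False
    for lo, hi in geom.boxes.values():
        if np.any(np.abs(lo) > half) or np.any(np.abs(hi) > half):
            return False
    return True


# ---------------------------------------------------------------------------
# public operations


def atlas_geometry(config: PhantomConfig) -> PhantomGeometry:
    """Unwarped ground-truth geometry in the common space."""
    return _build_geometry(config, warp=None)


def subject_geometry(
    config: PhantomConfig, subject_index: int
) -> tuple[PhantomGeometry, SinusoidalWarp | None]:
    """Warped geometry for one subject plus the warp itself (truth record)."""
    if subject_index >= config.n_subjects:
        raise ValueError("subject_index out of range")
    if config.subject_displacement_mm == 0:
        return _build_geometry(config, warp=None), None
    rng = config.stream(1, subject_index)
    half = config.make_grid().half_extent_mm
    warp = SinusoidalWarp.random(rng, config.subject_displacement_mm, half)
    geom = _build_geometry(config, warp=warp)
    # a warp that pushes a region off-grid is clipped (halved) until it fits
    for _ in range(8):
        if _geometry_fits(config, geom):
            break
        log.warning(
            "subject %d: warp pushes a region off-grid; clipping amplitude",
            subject_index,
        )
        warp = warp.scaled(0.5)
        geom = _build_geometry(config, warp=warp)
    else:
        raise PhantomSizingError("could not fit warped geometry on the grid")
    return geom, warp


def generate_atlas(config: PhantomConfig) -> LabelVolume:
    """Ground-truth label volume in the common (unwarped) space."""
    grid = config.make_grid()
    geom = atlas_geometry(config)
    if not _geometry_fits(config, geom):
        raise PhantomSizingError("grid too small to place all phantom regions")
    labels = _paint_labels(grid, geom)
    vol = LabelVolume(grid=grid, labels=labels, legend=dict(LEGEND), acpc_z_mm=0.0)
    vol.validate()
    return vol


def generate_subject(
    atlas: LabelVolume, subject_index: int, config: PhantomConfig
) -> tuple[LabelVolume, OrientationField]:
    """One subject's label volume and orientation field (warped anatomy)."""
    geom, _ = subject_geometry(config, subject_index)
    labels = _paint_labels(atlas.grid, geom)
    vol = LabelVolume(
        grid=atlas.grid, labels=labels, legend=dict(LEGEND), acpc_z_mm=atlas.acpc_z_mm
    )
    vol.validate()
    field = _build_orientation_field(atlas.grid, geom, config)
    return vol, field


def apply_scanner(
    field: OrientationField, scanner_index: int, config: PhantomConfig
) -> OrientationField:
    """Scanner effect: reduce the Watson concentration by the scanner's
    dispersion delta and apply a scanner-specific systematic perturbation to
    the per-voxel mean directions.

    The perturbation field is drawn from a per-scanner RNG stream on the full
    grid, so it is identical across subjects scanned on the same scanner —
    a reproducible vendor bias rather than random noise.
    """
    if scanner_index >= config.n_scanners:
        raise ValueError("scanner_index out of range")
    delta = config.scanner_dispersion_delta[scanner_index]
    out = field.copy()
    if delta == 0:
        return out
    out.kappa = np.where(
        np.isfinite(out.kappa), np.maximum(out.kappa - delta, 1.0), out.kappa
    )
    jitter_sd = config.direction_jitter_per_delta * delta
    if jitter_sd > 0:
        rng = config.stream(2, scanner_index)
        noise = rng.normal(0.0, jitter_sd, size=field.directions.shape)
        new_dirs = out.directions + noise
        norms = np.linalg.norm(new_dirs, axis=-1, keepdims=True)
        np.divide(new_dirs, norms, out=new_dirs, where=norms > 0)
        active = out.fractions > 0
        out.directions[active] = new_dirs[active]
    return out


def simulate_dwi(
    field: OrientationField,
    config: PhantomConfig,
    gradients: GradientTable | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, GradientTable]:
    """Monoexponential DWI synthesis: S = S0 exp(-b g^T D g).

    Per-voxel tensors are assembled from the orientation field (prolate
    tensor per population, mixed by volume fraction); voxels outside the
    valid mask carry an isotropic background tensor.  Returns one b=0 volume
    plus ``n_directions`` weighted volumes.
    """
    if gradients is None:
        gradients = make_gradient_scheme(config.n_directions, config.b_value)
    if gradients.n_weighted < 6:
        raise ValueError("tensor-fit infeasible: fewer than 6 weighted directions")
    grid = field.grid
    shape = grid.shape
    n_vox = int(np.prod(shape))

    lam1, lam3 = config.lambda_parallel, config.lambda_perp
    dirs = field.directions.reshape(n_vox, 2, 3)
    frac = field.fractions.reshape(n_vox, 2)
    mask = field.mask.ravel()

    six = np.zeros((n_vox, 6))
    six[:, :3] = config.background_adc
    aniso = np.flatnonzero(mask)
    if aniso.size:
        d = np.full((aniso.size, 6), 0.0)
        d[:, :3] = lam3
        for p in range(2):
            f = frac[aniso, p]
            mu = dirs[aniso, p, :]
            scale = f * (lam1 - lam3)
            d[:, 0] += scale * mu[:, 0] ** 2
            d[:, 1] += scale * mu[:, 1] ** 2
            d[:, 2] += scale * mu[:, 2] ** 2
            d[:, 3] += scale * mu[:, 0] * mu[:, 1]
            d[:, 4] += scale * mu[:, 0] * mu[:, 2]
            d[:, 5] += scale * mu[:, 1] * mu[:, 2]
        six[aniso] = d

    b = gradients.bvals
    g = gradients.bvecs
    bmat = np.column_stack(
        [
            b * g[:, 0] ** 2,
            b * g[:, 1] ** 2,
            b * g[:, 2] ** 2,
            2 * b * g[:, 0] * g[:, 1],
            2 * b * g[:, 0] * g[:, 2],
            2 * b * g[:, 1] * g[:, 2],
        ]
    )  # (n_vol, 6)
    signal = config.s0 * np.exp(-(six @ bmat.T))  # (n_vox, n_vol)
    if noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(config.master_seed) & 0x7FFFFFFF, 3, int(seed or 0)]
            )
        )
        signal = signal * (1.0 + rng.normal(0.0, noise_sd, size=signal.shape))
        np.clip(signal, 1e-6 * config.s0, None, out=signal)
    return signal.reshape(shape + (len(b),)), gradients


# ---------------------------------------------------------------------------
# phantom sets


@dataclass
class SubjectInstance:
    """One (subject, scanner) acquisition: anatomy, field, oracle geometry."""

    subject: int
    scanner: int
    labels: LabelVolume
    field: OrientationField
    geometry: PhantomGeometry


@dataclass
class PhantomSet:
    """A full synthetic study: atlas plus per-(subject, scanner) instances."""

    config: PhantomConfig
    atlas: LabelVolume
    instances: dict[tuple[int, int], SubjectInstance]
    truth: dict

    def units(self) -> list[tuple[int, int]]:
        return sorted(self.instances)


def generate_phantom_set(config: PhantomConfig) -> PhantomSet:
    """Generate the whole study deterministically from the configuration."""
    atlas = generate_atlas(config)
    instances: dict[tuple[int, int], SubjectInstance] = {}
    truth: dict = {"master_seed": int(config.master_seed), "subjects": {}, "scanners": {}}
    for j in range(config.n_scanners):
        truth["scanners"][j] = {
            "dispersion_delta": config.scanner_dispersion_delta[j],
            "noise_sd": config.scanner_noise_sd[j],
        }
    for i in range(config.n_subjects):
        geom, warp = subject_geometry(config, i)
        labels = _paint_labels(atlas.grid, geom)
        vol = LabelVolume(
            grid=atlas.grid, labels=labels, legend=dict(LEGEND), acpc_z_mm=0.0
        )
        vol.validate()
        base_field = _build_orientation_field(atlas.grid, geom, config)
        truth["subjects"][i] = {
            "displacement_rms_mm": config.subject_displacement_mm,
            "warp": warp.truth() if warp is not None else None,
        }
        for j in range(config.n_scanners):
            field = apply_scanner(base_field, j, config)
            instances[(i, j)] = SubjectInstance(
                subject=i, scanner=j, labels=vol, field=field, geometry=geom
            )
    return PhantomSet(config=config, atlas=atlas, instances=instances, truth=truth)


def regions_along_path(labels: LabelVolume, points_mm: np.ndarray) -> list[str]:
    """Region names in order of first entry while walking a polyline.

    Used to verify that the analytic cerebello-thalamic arc traverses the
    superior cerebellar peduncle before the red nucleus.
    """
    ijk = labels.grid.world_to_index(points_mm)
    inside = labels.grid.inside(ijk)
    seen: list[str] = []
    for point, ok in zip(ijk, inside):
        if not ok:
            continue
        lab = int(labels.labels[tuple(point)])
        if lab == 0:
            continue
        name = labels.legend[lab]
        if name not in seen:
            seen.append(name)
    return seen
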