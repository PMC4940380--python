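"""Probabilistic streamline propagation and connectivity counting.

Streamlines are launched from every seed voxel, advance in fixed steps by
sampling the local orientation model, and terminate on leaving the valid
mask, exceeding the per-step curvature limit, revisiting an already-visited
voxel (loops and recursions are not allowed), hitting a target region, or
reaching the step cap.  Each seed voxel keeps one hit counter per target
region, credited to the FIRST target a sample enters; the waytotal is the
total number of samples across all seed voxels that reached any target, and
dividing the counters by it turns a count map into a probability map.

Way-point filtered tracking additionally requires a streamline to traverse
an ordered list of way-point masks (gaps allowed, order inversions not)
before reaching its terminal target; the voxel-wise visitation counts of the
kept streamlines form the tract probability map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
from scipy import ndimage

from .diffusion import OrientationField, sample_orientations_batch
from .grid import VolumeGrid

__all__ = [
    "TrackingParams",
    "Streamline",
    "ConnectivityMap",
    "WaypointSpec",
    "WaypointTractResult",
    "Termination",
    "propagate",
    "track_seed_mask",
    "track_waypoint_tract",
    "normalize_by_waytotal",
    "dilate_mask",
]

log = logging.getLogger(__name__)


class Termination(str, Enum):
    TARGET_HIT = "target-hit"
    MASK_EXIT = "mask-exit"
    LOOP = "loop"
    CURVATURE = "curvature"
    MAX_STEPS = "max-steps"
    REJECTED_SEED = "rejected-seed"


@dataclass(frozen=True)
class TrackingParams:
    """Propagation parameters.

    ``samples_per_seed_voxel`` defaults to the study protocol value of 5000;
    ``step_mm`` defaults to half the smallest voxel dimension when left
    unset.  The curvature limit is the maximum per-step turning angle.
    """

    samples_per_seed_voxel: int = 5000
    step_mm: float | None = None
    max_steps: int = 2000
    curvature_limit_deg: float = 80.0
    seed_jitter: bool = True
    batch_size: int = 4096

    def __post_init__(self) -> None:
        if self.samples_per_seed_voxel < 1:
            raise ValueError("samples_per_seed_voxel must be >= 1")
        if not (0 < self.curvature_limit_deg <= 90):
            raise ValueError("curvature_limit_deg must be in (0, 90]")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    def resolve_step(self, grid: VolumeGrid) -> float:
        step = self.step_mm
        if step is None:
            step = 0.5 * float(np.min(grid.spacing))
        if not (0 < step <= float(np.min(grid.spacing))):
            raise ValueError(
                f"step_mm must be in (0, min voxel size]; got {step} for "
                f"spacing {grid.spacing}"
            )
        return step


@dataclass
class Streamline:
    """Ordered world-mm points plus the reason propagation stopped."""

    points: np.ndarray  # (n, 3)
    termination: Termination
    target: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class WaypointSpec:
    """Ordered way-point masks plus a terminal target, all by region name."""

    waypoints: tuple[str, ...]
    terminal: str

    def __post_init__(self) -> None:
        if len(self.waypoints) == 0:
            raise ValueError("waypoint list must be non-empty")


@dataclass
class ConnectivityMap:
    """Per-seed-voxel hit counters, one per named target, plus the waytotal."""

    grid: VolumeGrid
    seed_voxels: np.ndarray  # (K, 3) int voxel indices
    counts: np.ndarray  # (K, T) float (int-valued until normalized)
    target_names: tuple[str, ...]
    samples_per_voxel: int
    waytotal: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counters must be >= 0")
        if not self.normalized and np.any(self.counts > self.samples_per_voxel):
            raise ValueError("a counter exceeds samples_per_seed_voxel")

    def total_map(self) -> np.ndarray:
        """3D volume: per seed voxel, samples that reached ANY target."""
        out = np.zeros(self.grid.shape, dtype=float)
        out[tuple(self.seed_voxels.T)] = self.counts.sum(axis=1)
        return out

    def target_map(self, name: str) -> np.ndarray:
        t = self.target_names.index(name)
        out = np.zeros(self.grid.shape, dtype=float)
        out[tuple(self.seed_voxels.T)] = self.counts[:, t]
        return out


@dataclass
class WaypointTractResult:
    """Output of way-point filtered tracking."""

    connectivity: ConnectivityMap  # seed counters of kept samples only
    tract_map: np.ndarray  # 3D visitation counts of kept streamlines
    streamlines: list[Streamline]
    n_kept: int
    n_launched: int


# ---------------------------------------------------------------------------
# batch propagation engine


class _BatchResult:
    __slots__ = (
        "termination",
        "hit_target",
        "way_complete",
        "history",
        "history_len",
        "points",
        "n_points",
    )


def _propagate_batch(
    field: OrientationField,
    starts: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
    target_lab: np.ndarray | None,
    way_lab: np.ndarray | None = None,
    n_way: int = 0,
    record_points: bool = False,
) -> _BatchResult:
    """Propagate ``len(starts)`` streamlines in lockstep."""
    grid = field.grid
    step = params.resolve_step(grid)
    cos_limit = np.cos(np.deg2rad(params.curvature_limit_deg))
    shape = grid.shape
    n = starts.shape[0]
    flat_labels_t = target_lab.ravel() if target_lab is not None else None
    flat_way = way_lab.ravel() if way_lab is not None else None
    flat_valid = field.mask.ravel()

    def to_index(pos):
        return grid.world_to_index(pos)

    def ravel(ijk):
        return (ijk[:, 0] * shape[1] + ijk[:, 1]) * shape[2] + ijk[:, 2]

    pos = np.array(starts, dtype=float)
    term = np.full(n, -1, dtype=np.int8)
    TERMS = list(Termination)
    code = {t: i for i, t in enumerate(TERMS)}

    vox = to_index(pos)
    inb = grid.inside(vox)
    lin = np.where(inb, ravel(np.clip(vox, 0, np.asarray(shape) - 1)), -1)
    ok0 = inb & np.where(lin >= 0, flat_valid[np.maximum(lin, 0)], False)
    term[~ok0] = code[Termination.REJECTED_SEED]
    alive = ok0.copy()

    history = np.full((n, params.max_steps + 1), -1, dtype=np.int32)
    history[:, 0] = lin
    hist_len = np.ones(n, dtype=np.int64)
    hit_target = np.full(n, -1, dtype=np.int32)
    way_ptr = np.zeros(n, dtype=np.int32)
    way_violated = np.zeros(n, dtype=bool)

    if record_points:
        points = np.full((n, params.max_steps + 1, 3), np.nan, dtype=np.float32)
        points[:, 0, :] = pos
    else:
        points = None
    n_points = np.ones(n, dtype=np.int64)

    # initial direction: a free orientation draw with random sign
    prev = np.zeros((n, 3))
    idx0 = np.flatnonzero(alive)
    if idx0.size:
        seed_dirs = sample_orientations_batch(
            field, vox[idx0], np.zeros((idx0.size, 3)), rng
        )
        signs = np.where(rng.random(idx0.size) < 0.5, -1.0, 1.0)
        prev[idx0] = seed_dirs * signs[:, None]

    cur_lin = lin.copy()
    cur_vox = vox.copy()

    for _ in range(params.max_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        d = sample_orientations_batch(field, cur_vox[idx], prev[idx], rng)
        # midpoint (RK2-style) refinement: re-evaluate the orientation at the
        # half-step position; curved fields are followed with O(step^3) local
        # error instead of Euler's O(step^2) outward drift
        mid_vox = to_index(pos[idx] + 0.5 * step * d)
        mid_ok = grid.inside(mid_vox)
        mid_lin = np.where(
            mid_ok, ravel(np.clip(mid_vox, 0, np.asarray(shape) - 1)), -1
        )
        mid_ok &= np.where(mid_lin >= 0, flat_valid[np.maximum(mid_lin, 0)], False)
        if mid_ok.any():
            d_mid = sample_orientations_batch(
                field, mid_vox[mid_ok], d[mid_ok], rng
            )
            d[mid_ok] = d_mid
        cosang = np.sum(d * prev[idx], axis=-1)
        curved = cosang < cos_limit
        if curved.any():
            stop = idx[curved]
            term[stop] = code[Termination.CURVATURE]
            alive[stop] = False
            idx = idx[~curved]
            d = d[~curved]
        if idx.size == 0:
            continue
        pos[idx] += step * d
        prev[idx] = d
        if record_points:
            points[idx, n_points[idx], :] = pos[idx]
        n_points[idx] += 1

        new_vox = to_index(pos[idx])
        inb = grid.inside(new_vox)
        new_lin = np.where(
            inb, ravel(np.clip(new_vox, 0, np.asarray(shape) - 1)), -1
        )
        valid = inb & np.where(new_lin >= 0, flat_valid[np.maximum(new_lin, 0)], False)
        # mask exit: stepping outside the grid or the valid orientation mask.
        # A target region adjacent to the mask still counts when the step
        # lands in it, so check targets before declaring an exit.
        t_here = (
            flat_labels_t[np.maximum(new_lin, 0)]
            if flat_labels_t is not None
            else np.zeros(idx.size, dtype=np.int32)
        )
        t_here = np.where(inb, t_here, 0)

        hit = t_here > 0
        if hit.any():
            stop = idx[hit]
            term[stop] = code[Termination.TARGET_HIT]
            hit_target[stop] = t_here[hit] - 1
            alive[stop] = False
        exited = ~valid & ~hit
        if exited.any():
            stop = idx[exited]
            term[stop] = code[Termination.MASK_EXIT]
            alive[stop] = False
        cont = ~hit & ~exited
        idx_c = idx[cont]
        if idx_c.size == 0:
            continue
        new_lin_c = new_lin[cont]
        new_vox_c = new_vox[cont]

        moved = new_lin_c != cur_lin[idx_c]
        if moved.any():
            idx_m = idx_c[moved]
            lin_m = new_lin_c[moved]
            if flat_way is not None:
                w = flat_way[lin_m]
                has_w = w > 0
                if has_w.any():
                    iw = idx_m[has_w]
                    wv = w[has_w]
                    advance = wv == way_ptr[iw] + 1
                    way_ptr[iw[advance]] += 1
                    ahead = wv > way_ptr[iw] + 1
                    way_violated[iw[ahead]] = True
            # loop rule: terminate on re-entering any voxel this streamline
            # already visited
            hmax = int(hist_len[idx_m].max())
            looped = np.any(history[idx_m, :hmax] == lin_m[:, None], axis=1)
            if looped.any():
                stop = idx_m[looped]
                term[stop] = code[Termination.LOOP]
                alive[stop] = False
                idx_m = idx_m[~looped]
                lin_m = lin_m[~looped]
            history[idx_m, hist_len[idx_m]] = lin_m
            hist_len[idx_m] += 1
        cur_lin[idx_c] = new_lin_c
        cur_vox[idx_c] = new_vox_c

    still = term == -1
    term[still] = code[Termination.MAX_STEPS]

    res = _BatchResult()
    res.termination = np.array([TERMS[c] for c in term], dtype=object)
    res.hit_target = hit_target
    res.way_complete = (way_ptr >= n_way) & ~way_violated
    res.history = history
    res.history_len = hist_len
    res.points = points
    res.n_points = n_points
    return res


# ---------------------------------------------------------------------------
# public operations


def _run_rng(master_seed, tag: int) -> np.random.Generator:
    """RNG stream for one tracking run; ``master_seed`` may be an int or a
    tuple of ints (hierarchical run keys)."""
    if np.ndim(master_seed) == 0:
        entropy = [int(master_seed) & 0x7FFFFFFF, tag]
    else:
        entropy = [int(k) & 0x7FFFFFFF for k in master_seed] + [tag]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def propagate(
    field: OrientationField,
    start_point: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
    target_lab: np.ndarray | None = None,
) -> Streamline:
    """Propagate a single streamline from a world-mm start point."""
    starts = np.asarray(start_point, dtype=float).reshape(1, 3)
    res = _propagate_batch(field, starts, params, rng, target_lab, record_points=True)
    n_pts = int(res.n_points[0])
    return Streamline(
        points=res.points[0, :n_pts, :].astype(float),
        termination=res.termination[0],
    )


def _seed_starts(
    grid: VolumeGrid,
    seed_voxels: np.ndarray,
    samples: int,
    jitter: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """World-mm start points, ``samples`` per seed voxel, with ownership."""
    k = seed_voxels.shape[0]
    owner = np.repeat(np.arange(k), samples)
    ijk = seed_voxels[owner].astype(float)
    if jitter:
        ijk = ijk + rng.uniform(-0.5, 0.5, size=ijk.shape)
    return grid.voxel_to_world(ijk), owner


def track_seed_mask(
    field: OrientationField,
    seed: np.ndarray,
    targets: Mapping[str, np.ndarray],
    params: TrackingParams,
    master_seed: int,
) -> ConnectivityMap:
    """Launch samples from every seed voxel and count first-target hits.

    ``targets`` maps region names to boolean masks on the field grid; a
    sample is credited to the first target region it enters and then
    terminated, so counts never double across targets.
    """
    grid = field.grid
    seed = np.asarray(seed, dtype=bool)
    if seed.shape != grid.shape:
        raise ValueError("seed mask shape does not match grid")
    if not seed.any():
        raise ValueError("empty seed mask")
    if len(targets) == 0:
        raise ValueError("empty target set")
    target_names = tuple(targets)
    target_lab = np.zeros(grid.shape, dtype=np.int32)
    for t, name in enumerate(target_names):
        m = np.asarray(targets[name], dtype=bool)
        if m.shape != grid.shape:
            raise ValueError(f"target {name!r} shape does not match grid")
        if np.any(m & seed):
            raise ValueError(f"target {name!r} overlaps the seed mask")
        target_lab[m] = t + 1

    seed_voxels = np.argwhere(seed)
    rng = _run_rng(master_seed, 11)
    starts, owner = _seed_starts(
        grid, seed_voxels, params.samples_per_seed_voxel, params.seed_jitter, rng
    )
    counts = np.zeros((seed_voxels.shape[0], len(target_names)), dtype=np.int64)
    for lo in range(0, starts.shape[0], params.batch_size):
        sl = slice(lo, lo + params.batch_size)
        res = _propagate_batch(field, starts[sl], params, rng, target_lab)
        hits = res.hit_target >= 0
        np.add.at(counts, (owner[sl][hits], res.hit_target[hits]), 1)
    waytotal = int(counts.sum())
    return ConnectivityMap(
        grid=grid,
        seed_voxels=seed_voxels,
        counts=counts.astype(float),
        target_names=target_names,
        samples_per_voxel=params.samples_per_seed_voxel,
        waytotal=waytotal,
    )


def track_waypoint_tract(
    field: OrientationField,
    seed: np.ndarray,
    spec: WaypointSpec,
    masks: Mapping[str, np.ndarray],
    params: TrackingParams,
    master_seed: int,
) -> WaypointTractResult:
    """Way-point filtered tracking (the cerebello-thalamic tract recipe).

    A streamline is kept iff it enters the way-point masks in the stated
    order (other voxels may intervene; entering a later way-point before an
    earlier one disqualifies it) and then reaches the terminal target.
    Returns the kept-sample connectivity counters, the voxel-wise visitation
    map of kept streamlines, and the kept streamlines themselves.
    """
    grid = field.grid
    seed = np.asarray(seed, dtype=bool)
    if not seed.any():
        raise ValueError("empty seed mask")
    for name in (*spec.waypoints, spec.terminal):
        if name not in masks:
            raise KeyError(f"mask {name!r} missing from mask set")
    way_lab = np.zeros(grid.shape, dtype=np.int32)
    for order, name in enumerate(spec.waypoints, start=1):
        way_lab[np.asarray(masks[name], dtype=bool)] = order
    target_lab = np.zeros(grid.shape, dtype=np.int32)
    target_lab[np.asarray(masks[spec.terminal], dtype=bool)] = 1
    if np.any((target_lab > 0) & seed):
        raise ValueError("terminal target overlaps the seed mask")

    seed_voxels = np.argwhere(seed)
    rng = _run_rng(master_seed, 12)
    starts, owner = _seed_starts(
        grid, seed_voxels, params.samples_per_seed_voxel, params.seed_jitter, rng
    )
    counts = np.zeros((seed_voxels.shape[0], 1), dtype=np.int64)
    tract_map = np.zeros(grid.shape, dtype=np.int64)
    kept_streamlines: list[Streamline] = []
    batch = min(params.batch_size, 1024)  # point recording is memory-heavy
    n_launched = starts.shape[0]
    for lo in range(0, n_launched, batch):
        sl = slice(lo, lo + batch)
        res = _propagate_batch(
            field,
            starts[sl],
            params,
            rng,
            target_lab,
            way_lab=way_lab,
            n_way=len(spec.waypoints),
            record_points=True,
        )
        kept = (res.hit_target >= 0) & res.way_complete
        for i in np.flatnonzero(kept):
            h = res.history[i, : res.history_len[i]]
            np.add.at(tract_map.ravel(), h, 1)
            n_pts = int(res.n_points[i])
            kept_streamlines.append(
                Streamline(
                    points=res.points[i, :n_pts, :].astype(float),
                    termination=Termination.TARGET_HIT,
                    target=spec.terminal,
                )
            )
        np.add.at(counts[:, 0], owner[sl][kept], 1)
    n_kept = int(counts.sum())
    conn = ConnectivityMap(
        grid=grid,
        seed_voxels=seed_voxels,
        counts=counts.astype(float),
        target_names=(spec.terminal,),
        samples_per_voxel=params.samples_per_seed_voxel,
        waytotal=n_kept,
    )
    return WaypointTractResult(
        connectivity=conn,
        tract_map=tract_map,
        streamlines=kept_streamlines,
        n_kept=n_kept,
        n_launched=n_launched,
    )


def normalize_by_waytotal(cmap: ConnectivityMap) -> ConnectivityMap:
    """Divide every counter by the waytotal, turning counts into
    probabilities.  A zero waytotal yields an all-zero map with a warning;
    normalizing twice is an error."""
    if cmap.normalized:
        raise ValueError("connectivity map is already normalized")
    if cmap.waytotal == 0:
        warnings.warn("waytotal is zero; returning an all-zero map", stacklevel=2)
        counts = np.zeros_like(cmap.counts, dtype=float)
    else:
        counts = cmap.counts / float(cmap.waytotal)
    return ConnectivityMap(
        grid=cmap.grid,
        seed_voxels=cmap.seed_voxels,
        counts=counts,
        target_names=cmap.target_names,
        samples_per_voxel=cmap.samples_per_voxel,
        waytotal=cmap.waytotal,
        normalized=True,
    )


_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


def dilate_mask(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Binary dilation with a 6-connected structuring element."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=_STRUCT_6, iterations=iterations)
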