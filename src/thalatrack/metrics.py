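"""Connectivity-based targets and their evaluation against atlas targets.

A connectivity-based target (CBT) is the set of voxels whose connectivity
value reaches a percentile cutoff computed over the map's strictly positive
voxel intensities (linear-interpolation / "type 7" quantile, retention rule
value >= cutoff).  CBTs are compared to atlas targets by the Dice overlap
D = 2|X ∩ Y| / (|X| + |Y|) and by the Euclidean distance in mm between
centres of gravity, swept over integer percentiles 50..100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid

__all__ = [
    "ThresholdSpec",
    "CBT",
    "OverlapRecord",
    "SweepCurve",
    "percentile_threshold",
    "dice",
    "cog",
    "cog_distance",
    "sweep",
    "build_cbt_stack",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES: tuple[int, ...] = tuple(range(50, 101))

# relative slack on the >= cutoff comparison so that positive rescaling of a
# map (e.g. waytotal normalization) cannot flip voxels exactly at the cutoff
_CUTOFF_RTOL = 1e-12


@dataclass(frozen=True)
class ThresholdSpec:
    """Percentile threshold over the non-zero voxel intensities."""

    percentile: float
    basis: str = "non-zero voxel intensities"

    def __post_init__(self) -> None:
        if not (50.0 <= self.percentile <= 100.0):
            raise ValueError("percentile must lie in [50, 100]")


@dataclass
class CBT:
    """Binary target volume obtained at a stated percentile threshold."""

    mask: np.ndarray  # bool, grid.shape
    grid: VolumeGrid
    threshold: ThresholdSpec
    cutoff: float
    intent: str | None = None

    @property
    def degenerate(self) -> bool:
        return not bool(self.mask.any())

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class OverlapRecord:
    dice: float
    cog_distance_mm: float
    vol_x: int
    vol_y: int
    percentile: float


@dataclass
class SweepCurve:
    """Metric values over an increasing percentile grid (NaN = missing)."""

    percentiles: np.ndarray
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.percentiles.shape != self.values.shape:
            raise ValueError("percentiles and values must align")
        if np.any(np.diff(self.percentiles) <= 0):
            raise ValueError("percentiles must be strictly increasing")


def _as_array(volume) -> tuple[np.ndarray, VolumeGrid | None]:
    if isinstance(volume, CBT):
        return volume.mask.astype(float), volume.grid
    return np.asarray(volume, dtype=float), None


def percentile_threshold(
    map_values: np.ndarray,
    grid: VolumeGrid,
    spec: ThresholdSpec | float,
    intent: str | None = None,
) -> CBT:
    """Threshold a probability/count map at a percentile of its non-zero
    values; returns the voxels with value >= cutoff."""
    if not isinstance(spec, ThresholdSpec):
        spec = ThresholdSpec(percentile=float(spec))
    values = np.asarray(map_values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("map shape does not match grid")
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("cannot threshold an all-zero map")
    cutoff = float(np.percentile(positive, spec.percentile, method="linear"))
    mask = values >= cutoff * (1.0 - np.sign(cutoff) * _CUTOFF_RTOL)
    return CBT(mask=mask, grid=grid, threshold=spec, cutoff=cutoff, intent=intent)


def dice(x, y) -> float:
    """Dice overlap D = 2|X ∩ Y| / (|X| + |Y|) between two voxel sets."""
    xm, gx = _as_array(x)
    ym, gy = _as_array(y)
    if gx is not None and gy is not None and not gx.same_as(gy):
        raise ValueError("volumes live on different grids")
    if xm.shape != ym.shape:
        raise ValueError("volume shapes differ")
    xb = xm > 0
    yb = ym > 0
    nx = int(np.count_nonzero(xb))
    ny = int(np.count_nonzero(yb))
    if nx + ny == 0:
        raise ValueError("Dice is undefined for two empty volumes")
    inter = int(np.count_nonzero(xb & yb))
    return 2.0 * inter / (nx + ny)


def cog(volume, grid: VolumeGrid, weighted: bool = True) -> np.ndarray:
    """Centre of gravity in world mm.

    ``weighted=True`` uses the voxel intensities as weights (connectivity
    maps); ``weighted=False`` treats the volume as a binary mask (atlas
    targets).
    """
    arr, g = _as_array(volume)
    grid = g or grid
    if weighted:
        w = np.where(arr > 0, arr, 0.0)
    else:
        w = (arr > 0).astype(float)
    total = w.sum()
    if total == 0:
        raise ValueError("cannot compute the centre of gravity of an empty volume")
    ijk = np.argwhere(w > 0).astype(float)
    weights = w[w > 0]
    centroid_vox = (ijk * weights[:, None]).sum(axis=0) / total
    return grid.voxel_to_world(centroid_vox)


def cog_distance(x, y, grid: VolumeGrid | None = None, weighted_x: bool = True) -> float:
    """Euclidean distance (mm) between the centre of gravity of a
    connectivity-derived volume (intensity-weighted) and an atlas mask
    (binary centroid)."""
    xa, gx = _as_array(x)
    ya, gy = _as_array(y)
    g = gx or gy or grid
    if g is None:
        raise ValueError("a grid is required")
    cx = cog(xa, gx or g, weighted=weighted_x)
    cy = cog(ya, gy or g, weighted=False)
    return float(np.linalg.norm(cx - cy))


def sweep(
    map_values: np.ndarray,
    atlas_target: np.ndarray,
    grid: VolumeGrid,
    percentiles=DEFAULT_PERCENTILES,
) -> tuple[SweepCurve, SweepCurve, list[OverlapRecord]]:
    """Dice and CoG-distance curves across a percentile grid.

    Degenerate thresholds are recorded as NaN rather than dropped.
    """
    ps = np.asarray(list(percentiles), dtype=float)
    if np.any(ps < 50) or np.any(ps > 100):
        raise ValueError("percentile grid must lie within [50, 100]")
    atlas = np.asarray(atlas_target, dtype=bool)
    dices = np.full(ps.shape, np.nan)
    cogs = np.full(ps.shape, np.nan)
    records: list[OverlapRecord] = []
    for i, p in enumerate(ps):
        cbt = percentile_threshold(map_values, grid, p)
        if cbt.degenerate:
            records.append(
                OverlapRecord(np.nan, np.nan, 0, int(atlas.sum()), float(p))
            )
            continue
        d = dice(cbt.mask, atlas)
        weighted = np.where(cbt.mask, map_values, 0.0)
        c = cog_distance(weighted, atlas, grid)
        dices[i] = d
        cogs[i] = c
        records.append(
            OverlapRecord(d, c, cbt.n_voxels, int(atlas.sum()), float(p))
        )
    return (
        SweepCurve(ps, dices, "dice"),
        SweepCurve(ps, cogs, "cog_distance_mm"),
        records,
    )


def build_cbt_stack(
    map_values: np.ndarray,
    grid: VolumeGrid,
    percentiles=DEFAULT_PERCENTILES,
    intent: str | None = None,
) -> dict[float, CBT]:
    """CBTs of one map at every percentile of a grid."""
    return {
        float(p): percentile_threshold(map_values, grid, float(p), intent=intent)
        for p in percentiles
    }
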