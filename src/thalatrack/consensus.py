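"""Population-level optimal connectivity threshold.

The optimum balances two competing objectives: lower thresholds give higher
inter-subject overlap (more reproducible, less specific targets), higher
thresholds give better agreement with the atlas target.  The consensus rule
multiplies the median inter-subject Dice curve by the median atlas Dice
curve and takes the percentile at the product's maximum; ties break toward
the lowest percentile (the more inclusive volume).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .metrics import CBT, DEFAULT_PERCENTILES, SweepCurve, build_cbt_stack, dice, sweep

__all__ = [
    "ConsensusCurve",
    "intersubject_overlap_curve",
    "consensus_optimum",
    "optimize_all",
]

log = logging.getLogger(__name__)


@dataclass
class ConsensusCurve:
    percentiles: np.ndarray
    intersubject_median: np.ndarray
    atlas_median: np.ndarray
    product: np.ndarray
    optimum: float

    @property
    def product_max(self) -> float:
        return float(np.nanmax(self.product))


def _unit_pairs(units: list) -> list[tuple]:
    """Unordered unit pairs eligible for the inter-subject overlap.

    Units may be plain subject ids or (subject, scanner) tuples; for the
    latter only different-subject, same-scanner pairs are compared, pooled
    across scanners.
    """
    pairs = []
    for a, b in itertools.combinations(units, 2):
        if isinstance(a, tuple) and isinstance(b, tuple) and len(a) == 2:
            if a[0] != b[0] and a[1] == b[1]:
                pairs.append((a, b))
        else:
            pairs.append((a, b))
    return pairs


def intersubject_overlap_curve(
    cbts: Mapping[object, Mapping[float, CBT]],
    percentiles=DEFAULT_PERCENTILES,
) -> SweepCurve:
    """Median pairwise Dice between subjects' CBTs, per percentile.

    ``cbts`` maps unit ids (subject, or (subject, scanner)) to a
    percentile -> CBT mapping of the same intent and side.  Pairs with a
    degenerate member are excluded (and logged) at that percentile.
    """
    units = list(cbts)
    if len({u[0] if isinstance(u, tuple) else u for u in units}) < 2:
        raise ValueError("inter-subject overlap needs >= 2 subjects")
    pairs = _unit_pairs(units)
    ps = np.asarray(list(percentiles), dtype=float)
    medians = np.full(ps.shape, np.nan)
    for i, p in enumerate(ps):
        values = []
        for a, b in pairs:
            ca, cb = cbts[a][float(p)], cbts[b][float(p)]
            if ca.degenerate or cb.degenerate:
                log.info("excluding pair %s-%s at p=%g: degenerate CBT", a, b, p)
                continue
            values.append(dice(ca.mask, cb.mask))
        if values:
            medians[i] = float(np.median(values))
    return SweepCurve(ps, medians, "intersubject_dice_median")


def consensus_optimum(
    intersubject: SweepCurve, atlas: SweepCurve
) -> ConsensusCurve:
    """Product of the two median curves and its argmax percentile."""
    if not np.array_equal(intersubject.percentiles, atlas.percentiles):
        raise ValueError("percentile grids differ")
    product = intersubject.values * atlas.values
    finite = np.isfinite(product)
    if not finite.any():
        raise ValueError("product curve is entirely missing")
    best = np.nanmax(product)
    # ties break toward the lowest percentile
    optimum = float(intersubject.percentiles[finite][product[finite] >= best][0])
    return ConsensusCurve(
        percentiles=intersubject.percentiles,
        intersubject_median=intersubject.values,
        atlas_median=atlas.values,
        product=product,
        optimum=optimum,
    )


def optimize_all(
    maps: Mapping[tuple[str, str, int, int], np.ndarray],
    atlas_masks: Mapping[tuple[str, str], np.ndarray],
    grid: VolumeGrid,
    percentiles=DEFAULT_PERCENTILES,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ConsensusCurve]]:
    """Optimal percentile per (intent, side).

    ``maps`` is keyed by (intent, side, subject, scanner); ``atlas_masks``
    by (intent, side).  Returns a table of optima and the full consensus
    curves.  Intents with fewer than two subjects are skipped with a
    warning.
    """
    rows = []
    curves: dict[tuple[str, str], ConsensusCurve] = {}
    keys = sorted({(intent, side) for intent, side, _, _ in maps})
    for intent, side in keys:
        unit_maps = {
            (subj, scan): m
            for (it, sd, subj, scan), m in maps.items()
            if it == intent and sd == side
        }
        subjects = {u[0] for u in unit_maps}
        if len(subjects) < 2:
            log.warning("skipping %s/%s: fewer than 2 subjects", intent, side)
            continue
        cbts = {
            unit: build_cbt_stack(m, grid, percentiles, intent=intent)
            for unit, m in unit_maps.items()
        }
        inter = intersubject_overlap_curve(cbts, percentiles)
        ps = np.asarray(list(percentiles), dtype=float)
        atlas = np.asarray(atlas_masks[(intent, side)], dtype=bool)
        dice_stack = np.full((len(unit_maps), ps.size), np.nan)
        for row_i, m in enumerate(unit_maps.values()):
            dice_curve, _, _ = sweep(m, atlas, grid, percentiles)
            dice_stack[row_i] = dice_curve.values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            atlas_median = np.nanmedian(dice_stack, axis=0)
        curve = consensus_optimum(
            inter, SweepCurve(ps, atlas_median, "atlas_dice_median")
        )
        curves[(intent, side)] = curve
        rows.append(
            {
                "intent": intent,
                "side": side,
                "optimal_percentile": curve.optimum,
                "product_max": curve.product_max,
            }
        )
    return pd.DataFrame(rows, columns=["intent", "side", "optimal_percentile", "product_max"]), curves
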