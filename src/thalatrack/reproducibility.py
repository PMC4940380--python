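"""Decomposition of target variability into scanner and subject components.

All unordered pairs of (subject, scanner) units are tagged: *inter_scanner*
(same subject, different scanner), *inter_subject* (different subject, same
scanner) or *crossed* (both differ).  The two tagged groups are compared by
a two-sided Welch two-sample t-test on their pairwise Dice values (a
label-permutation alternative is available; pairwise Dice values sharing a
unit are not independent, which the permutation test respects by permuting
unit identities).  The overall overlap pools all three groups.

The cerebello-thalamic tract gets a dedicated recipe: restrict each tract
map to a slab around the AC-PC plane (the neurosurgical working volume),
threshold at a fixed top-90th percentile — no consensus optimisation exists
for the tract because there is no atlas target — then decompose as above.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .grid import VolumeGrid
from .metrics import CBT, dice, percentile_threshold

__all__ = [
    "PairwiseDiceSet",
    "ReproRow",
    "pairwise_dice",
    "decompose_variability",
    "restrict_slab",
    "ctt_reproducibility",
]

log = logging.getLogger(__name__)

INTER_SCANNER = "inter_scanner"
INTER_SUBJECT = "inter_subject"
CROSSED = "crossed"


@dataclass
class PairwiseDiceSet:
    """All unordered unit pairs with their Dice values and group tags."""

    table: pd.DataFrame  # columns: unit_a, unit_b, dice, tag
    excluded_units: tuple

    def group(self, tag: str) -> np.ndarray:
        return self.table.loc[self.table["tag"] == tag, "dice"].to_numpy()

    @property
    def n_pairs(self) -> int:
        return len(self.table)


@dataclass
class ReproRow:
    """One row of the reproducibility report (one intent and side)."""

    intent: str
    side: str
    inter_scanner_mean: float
    inter_scanner_sd: float
    inter_subject_mean: float
    inter_subject_sd: float
    p_value: float
    overall_mean: float
    overall_sd: float
    n_inter_scanner: int
    n_inter_subject: int
    n_pairs: int
    complete: bool = True


def _tag(unit_a: tuple[int, int], unit_b: tuple[int, int]) -> str:
    same_subject = unit_a[0] == unit_b[0]
    same_scanner = unit_a[1] == unit_b[1]
    if same_subject and not same_scanner:
        return INTER_SCANNER
    if not same_subject and same_scanner:
        return INTER_SUBJECT
    return CROSSED


def pairwise_dice(
    cbts: Mapping[tuple[int, int], CBT | np.ndarray],
    intent: str = "",
    side: str = "",
) -> PairwiseDiceSet:
    """Dice for every unordered pair of units, tagged by what differs.

    Units with a degenerate (empty) CBT are excluded and logged.
    """
    units = sorted(cbts)
    if len(units) < 2:
        raise ValueError("need at least 2 units")

    def is_degenerate(v) -> bool:
        if isinstance(v, CBT):
            return v.degenerate
        return not bool(np.asarray(v).any())

    excluded = tuple(u for u in units if is_degenerate(cbts[u]))
    for u in excluded:
        log.warning("excluding unit %s (%s/%s): degenerate CBT", u, intent, side)
    kept = [u for u in units if u not in excluded]
    rows = []
    for a, b in itertools.combinations(kept, 2):
        rows.append(
            {
                "unit_a": a,
                "unit_b": b,
                "dice": dice(cbts[a], cbts[b]),
                "tag": _tag(a, b),
            }
        )
    table = pd.DataFrame(rows, columns=["unit_a", "unit_b", "dice", "tag"])
    return PairwiseDiceSet(table=table, excluded_units=excluded)


def _permutation_p(
    pairs: PairwiseDiceSet, n_permutations: int, seed: int
) -> float:
    """Two-sided p for the inter_scanner minus inter_subject mean difference
    under permutation of unit identities (subject, scanner) labels."""
    units = sorted(
        set(pairs.table["unit_a"]).union(pairs.table["unit_b"])
    )
    index = {u: i for i, u in enumerate(units)}
    ia = pairs.table["unit_a"].map(index).to_numpy()
    ib = pairs.table["unit_b"].map(index).to_numpy()
    d = pairs.table["dice"].to_numpy()
    labels = np.array(units, dtype=object)

    def stat(perm_labels) -> float:
        tags = np.array(
            [_tag(perm_labels[a], perm_labels[b]) for a, b in zip(ia, ib)]
        )
        g1 = d[tags == INTER_SCANNER]
        g2 = d[tags == INTER_SUBJECT]
        if g1.size == 0 or g2.size == 0:
            return np.nan
        return float(g1.mean() - g2.mean())

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    valid = 0
    for _ in range(n_permutations):
        perm = labels[rng.permutation(len(labels))]
        s = stat(perm)
        if np.isnan(s):
            continue
        valid += 1
        if abs(s) >= abs(observed) - 1e-15:
            hits += 1
    return (hits + 1) / (valid + 1)


def decompose_variability(
    pairs: PairwiseDiceSet,
    intent: str = "",
    side: str = "",
    test: str = "welch",
    n_permutations: int = 10000,
    seed: int = 0,
) -> ReproRow:
    """Group means/SDs, the significance of their difference, and the
    overall overlap across all pairs."""
    g_scan = pairs.group(INTER_SCANNER)
    g_subj = pairs.group(INTER_SUBJECT)
    all_d = pairs.table["dice"].to_numpy()
    complete = g_scan.size >= 2 and g_subj.size >= 2
    if not complete:
        log.warning("incomplete report row %s/%s: a pair group is too small", intent, side)
        p = np.nan
    elif np.allclose(g_scan, g_scan[0]) and np.allclose(g_subj, g_scan[0]):
        p = 1.0  # both groups constant and equal: no evidence of a difference
    elif test == "welch":
        p = float(stats.ttest_ind(g_scan, g_subj, equal_var=False).pvalue)
    elif test == "permutation":
        p = _permutation_p(pairs, n_permutations, seed)
    else:
        raise ValueError(f"unknown test {test!r}")

    def mean_sd(x: np.ndarray) -> tuple[float, float]:
        if x.size == 0:
            return np.nan, np.nan
        return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    ms, ss = mean_sd(g_scan)
    mu, su = mean_sd(g_subj)
    mo, so = mean_sd(all_d)
    return ReproRow(
        intent=intent,
        side=side,
        inter_scanner_mean=ms,
        inter_scanner_sd=ss,
        inter_subject_mean=mu,
        inter_subject_sd=su,
        p_value=p,
        overall_mean=mo,
        overall_sd=so,
        n_inter_scanner=int(g_scan.size),
        n_inter_subject=int(g_subj.size),
        n_pairs=pairs.n_pairs,
        complete=complete,
    )


def restrict_slab(
    volume: np.ndarray,
    grid: VolumeGrid,
    acpc_z_mm: float,
    half_extent_mm: float = 20.0,
) -> np.ndarray:
    """Keep voxels whose world z lies within ``half_extent_mm`` of the AC-PC
    plane; zero the rest.  Works on probability maps and binary targets."""
    z = grid.world_z_volume()
    inside = np.abs(z - acpc_z_mm) <= half_extent_mm
    if not inside.any():
        raise ValueError("slab does not intersect the grid")
    out = np.asarray(volume).copy()
    out[~inside] = 0
    return out


def ctt_reproducibility(
    tract_maps: Mapping[tuple[int, int], np.ndarray],
    grid: VolumeGrid,
    acpc_z_mm: float,
    half_extent_mm: float = 20.0,
    percentile: float = 90.0,
    intent: str = "ctt",
    side: str = "",
    test: str = "welch",
    n_permutations: int = 10000,
    seed: int = 0,
) -> tuple[ReproRow, PairwiseDiceSet]:
    """Tract reproducibility: slab-restrict each map around the AC-PC plane,
    threshold at the fixed top-``percentile`` of the restricted non-zero
    values, then run the pairwise decomposition.  Units whose restricted map
    is empty are excluded (logged)."""
    cbts: dict[tuple[int, int], CBT] = {}
    for unit, m in sorted(tract_maps.items()):
        restricted = restrict_slab(m, grid, acpc_z_mm, half_extent_mm)
        if not (restricted > 0).any():
            log.warning("excluding unit %s: empty slab-restricted tract map", unit)
            continue
        cbts[unit] = percentile_threshold(restricted, grid, percentile, intent=intent)
    if len(cbts) < 2:
        raise ValueError("fewer than 2 usable units after slab restriction")
    pairs = pairwise_dice(cbts, intent=intent, side=side)
    row = decompose_variability(
        pairs, intent=intent, side=side, test=test,
        n_permutations=n_permutations, seed=seed,
    )
    return row, pairs
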