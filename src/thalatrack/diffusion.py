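"""Diffusion tensor fitting, fractional anisotropy, and the per-voxel
orientation-sampling model used by the probabilistic tracker.

The orientation model is a parametric Watson (axial, antipodally symmetric)
distribution per fibre population: each voxel stores up to two mean unit
directions with volume fractions and a single dispersion concentration
``kappa``.  ``kappa = inf`` is the zero-dispersion limit in which sampling
returns the mean direction exactly — the deterministic regime used by the
tracker oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid

__all__ = [
    "GradientTable",
    "OrientationField",
    "TensorField",
    "make_gradient_scheme",
    "fit_tensor",
    "compute_fa",
    "sample_orientation",
    "sample_watson",
    "watson_mean_angle",
    "OutOfMaskError",
]

log = logging.getLogger(__name__)

# lower-triangular component order used for the 6-vector tensor layout
_TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


class OutOfMaskError(ValueError):
    """Raised when an orientation sample is requested outside the valid mask."""


# ---------------------------------------------------------------------------
# gradient schemes


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions, one row per volume."""

    bvals: np.ndarray  # (n,)
    bvecs: np.ndarray  # (n, 3), unit rows for b > 0

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError("bvals and bvecs row counts differ")
        weighted = bvals > 0
        norms = np.linalg.norm(bvecs[weighted], axis=1)
        if weighted.any() and not np.allclose(norms, 1.0, atol=1e-6):
            bvecs = bvecs.copy()
            bvecs[weighted] /= norms[:, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_weighted(self) -> int:
        return int(np.count_nonzero(self.bvals > 0))


def make_gradient_scheme(n_directions: int = 32, b_value: float = 1000.0) -> GradientTable:
    """One b=0 volume plus ``n_directions`` directions on a spherical
    Fibonacci hemisphere (near-uniform, deterministic)."""
    if n_directions < 6:
        raise ValueError("at least 6 non-collinear directions are required")
    i = np.arange(n_directions)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * i / golden
    # upper hemisphere only: diffusion signal is antipodally symmetric
    z = (i + 0.5) / n_directions
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# fields


@dataclass
class OrientationField:
    """Per-voxel fibre orientation model (up to two Watson populations)."""

    grid: VolumeGrid
    directions: np.ndarray  # (X, Y, Z, 2, 3) unit mean directions
    fractions: np.ndarray  # (X, Y, Z, 2) volume fractions, sum <= 1
    kappa: np.ndarray  # (X, Y, Z) Watson concentration, inf allowed
    mask: np.ndarray  # (X, Y, Z) bool, valid voxels

    def __post_init__(self) -> None:
        shape = self.grid.shape
        if self.directions.shape != shape + (2, 3):
            raise ValueError("directions must have shape grid.shape + (2, 3)")
        if self.fractions.shape != shape + (2,):
            raise ValueError("fractions must have shape grid.shape + (2,)")
        if self.kappa.shape != shape or self.mask.shape != shape:
            raise ValueError("kappa and mask must have grid shape")

    def validate(self) -> None:
        """Check the unit-norm / fraction / kappa invariants on valid voxels."""
        m = self.mask
        frac = self.fractions[m]
        if np.any(frac < 0) or np.any(frac.sum(axis=-1) > 1 + 1e-6):
            raise ValueError("fractions must lie in [0,1] and sum to <= 1")
        if np.any(~(self.kappa[m] > 0)):
            raise ValueError("kappa must be positive on valid voxels")
        for p in range(2):
            active = m & (self.fractions[..., p] > 0)
            norms = np.linalg.norm(self.directions[active, p, :], axis=-1)
            if active.any() and not np.allclose(norms, 1.0, atol=1e-5):
                raise ValueError("mean directions must be unit-norm")

    def copy(self) -> "OrientationField":
        return OrientationField(
            grid=self.grid,
            directions=self.directions.copy(),
            fractions=self.fractions.copy(),
            kappa=self.kappa.copy(),
            mask=self.mask.copy(),
        )


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors with sorted eigensystem."""

    grid: VolumeGrid
    components: np.ndarray  # (X, Y, Z, 6) in _TENSOR_COMPONENTS order, mm^2/s
    evals: np.ndarray  # (X, Y, Z, 3) sorted descending
    evecs: np.ndarray  # (X, Y, Z, 3, 3), evecs[..., :, i] pairs with evals[..., i]
    mask: np.ndarray  # (X, Y, Z) bool

    @property
    def principal_direction(self) -> np.ndarray:
        return self.evecs[..., :, 0]

    def as_matrices(self) -> np.ndarray:
        return _six_to_matrix(self.components)


def _six_to_matrix(six: np.ndarray) -> np.ndarray:
    xx, yy, zz, xy, xz, yz = np.moveaxis(six, -1, 0)
    out = np.empty(six.shape[:-1] + (3, 3), dtype=six.dtype)
    out[..., 0, 0] = xx
    out[..., 1, 1] = yy
    out[..., 2, 2] = zz
    out[..., 0, 1] = out[..., 1, 0] = xy
    out[..., 0, 2] = out[..., 2, 0] = xz
    out[..., 1, 2] = out[..., 2, 1] = yz
    return out


# ---------------------------------------------------------------------------
# tensor fit and FA


def fit_tensor(
    dwi: np.ndarray,
    gradients: GradientTable,
    grid: VolumeGrid,
    mask: np.ndarray | None = None,
) -> TensorField:
    """Log-linear least-squares tensor fit.

    ``dwi`` has shape ``grid.shape + (n_volumes,)`` matching the gradient
    table row order; at least one unweighted volume and six non-collinear
    weighted directions are required.  Voxels with non-positive signal in any
    volume are masked out (the count is logged).
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[:3] != grid.shape or dwi.shape[3] != gradients.bvals.shape[0]:
        raise ValueError("dwi shape does not match grid / gradient table")
    if gradients.n_weighted < 6:
        raise ValueError("tensor fit needs >= 6 weighted directions")
    if not np.any(gradients.bvals == 0):
        raise ValueError("tensor fit needs >= 1 unweighted (b=0) volume")

    b = gradients.bvals
    g = gradients.bvecs
    # design: ln S = ln S0 - b (gx^2 Dxx + gy^2 Dyy + gz^2 Dzz
    #                           + 2 gx gy Dxy + 2 gx gz Dxz + 2 gy gz Dyz)
    design = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < 7:
        raise ValueError("gradient directions are collinear; tensor fit infeasible")

    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    positive = np.all(dwi > 0, axis=-1)
    n_bad = int(np.count_nonzero(mask & ~positive))
    if n_bad:
        log.warning("fit_tensor: masked out %d voxels with non-positive signal", n_bad)
    fit_mask = mask & positive

    comps = np.zeros(grid.shape + (6,), dtype=float)
    if fit_mask.any():
        logs = np.log(dwi[fit_mask])  # (n_vox, n_vol)
        beta, *_ = np.linalg.lstsq(design, logs.T, rcond=None)  # (7, n_vox)
        comps[fit_mask] = beta[1:].T

    mats = _six_to_matrix(comps)
    evals = np.zeros(grid.shape + (3,))
    evecs = np.zeros(grid.shape + (3, 3))
    evecs[..., :, :] = np.eye(3)
    if fit_mask.any():
        w, v = np.linalg.eigh(mats[fit_mask])  # ascending
        order = np.argsort(w, axis=-1)[..., ::-1]
        w = np.take_along_axis(w, order, axis=-1)
        v = np.take_along_axis(v, order[..., None, :], axis=-1)
        evals[fit_mask] = w
        evecs[fit_mask] = v
    return TensorField(grid=grid, components=comps, evals=evals, evecs=evecs, mask=fit_mask)


def compute_fa(tensors: TensorField) -> np.ndarray:
    """Fractional anisotropy from sorted eigenvalues, clipped to [0, 1].

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||; voxels with zero
    trace get FA = 0 (count logged).
    """
    ev = tensors.evals
    norm_sq = np.sum(ev**2, axis=-1)
    mean = ev.mean(axis=-1, keepdims=True)
    dev_sq = np.sum((ev - mean) ** 2, axis=-1)
    fa = np.zeros(ev.shape[:-1])
    ok = norm_sq > 0
    n_zero = int(np.count_nonzero(tensors.mask & ~ok))
    if n_zero:
        log.warning("compute_fa: %d masked voxels with zero trace set to FA=0", n_zero)
    # single square root so the degenerate closed forms land exactly on 0/1
    fa[ok] = np.sqrt(1.5 * dev_sq[ok] / norm_sq[ok])
    return np.clip(fa, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Watson sampling


def _sample_watson_cosines(kappa: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample u = |cos(theta)| in [0, 1] with density proportional to
    exp(kappa * u^2), by rejection from a truncated exponential envelope
    exp(kappa * u) (acceptance ratio exp(kappa*u*(u-1)) <= 1)."""
    n = kappa.shape[0]
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        k = kappa[todo]
        u1 = rng.random(todo.shape[0])
        # inverse CDF of the truncated exponential, numerically stable for
        # large kappa:  u = 1 + log(u1 + (1-u1) e^{-k}) / k
        with np.errstate(divide="ignore", invalid="ignore"):
            u = 1.0 + np.log(u1 + (1.0 - u1) * np.exp(-k)) / k
        small = k < 1e-12
        if small.any():
            u[small] = u1[small]
        accept = rng.random(todo.shape[0]) < np.exp(k * u * (u - 1.0))
        out[todo[accept]] = u[accept]
        todo = todo[~accept]
        if todo.size == 0:
            break
    else:  # pragma: no cover - rejection with ratio >= ~0.5 cannot starve
        out[todo] = 1.0
    return out


def _orthonormal_frame(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``mu`` (rows, unit) to an orthonormal frame."""
    helper = np.zeros_like(mu)
    smallest = np.argmin(np.abs(mu), axis=-1)
    helper[np.arange(mu.shape[0]), smallest] = 1.0
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = np.cross(mu, e1)
    return e1, e2


def sample_watson(
    mu: np.ndarray, kappa: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one axis per row from a Watson distribution about ``mu``.

    Returns unit vectors; the sign is random (axial distribution), callers
    align it against a previous direction.  ``kappa = inf`` rows return the
    mean direction exactly.
    """
    mu = np.asarray(mu, dtype=float).reshape(-1, 3)
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float).ravel(), (mu.shape[0],))
    out = mu.copy()
    finite = np.isfinite(kappa)
    if finite.any():
        m = mu[finite]
        c = _sample_watson_cosines(kappa[finite], rng)
        sign = np.where(rng.random(c.shape[0]) < 0.5, -1.0, 1.0)
        c = c * sign
        phi = rng.uniform(0.0, 2.0 * np.pi, c.shape[0])
        s = np.sqrt(np.clip(1.0 - c**2, 0.0, 1.0))
        e1, e2 = _orthonormal_frame(m)
        vec = (
            c[:, None] * m
            + (s * np.cos(phi))[:, None] * e1
            + (s * np.sin(phi))[:, None] * e2
        )
        vec /= np.linalg.norm(vec, axis=-1, keepdims=True)
        out[finite] = vec
    return out


def watson_mean_angle(kappa: float) -> float:
    """Expected angular deviation (radians) of a Watson sample from its mean
    axis, after antipodal alignment: E[arccos |cos theta|].

    Computed by numerical quadrature of the normalised density — the
    independent check used against the Monte-Carlo sampler.
    """
    from scipy.integrate import quad

    num, _ = quad(lambda u: np.arccos(u) * np.exp(kappa * u**2), 0.0, 1.0)
    den, _ = quad(lambda u: np.exp(kappa * u**2), 0.0, 1.0)
    return num / den


def _choose_population(
    field: OrientationField, idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Pick a population index per voxel row, proportional to volume fractions."""
    f0 = field.fractions[idx[:, 0], idx[:, 1], idx[:, 2], 0]
    f1 = field.fractions[idx[:, 0], idx[:, 1], idx[:, 2], 1]
    total = f0 + f1
    p0 = np.where(total > 0, f0 / np.where(total > 0, total, 1.0), 1.0)
    return (rng.random(idx.shape[0]) >= p0).astype(np.int64)


def sample_orientations_batch(
    field: OrientationField,
    idx: np.ndarray,
    previous: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised orientation draw for the tracker.

    ``idx``: (n, 3) integer voxel indices (assumed valid); ``previous``:
    (n, 3) previous step directions used for sign alignment.  In voxels with
    two fibre populations, a streamline with a previous direction follows
    the population whose mean axis best aligns with it (so crossings do not
    scatter propagating streamlines); free draws (zero previous direction,
    i.e. at seeding) choose a population proportional to volume fraction.
    """
    pop = _choose_population(field, idx, rng)
    free = np.all(previous == 0, axis=-1)
    if not free.all():
        mu_all = field.directions[idx[:, 0], idx[:, 1], idx[:, 2], :, :]  # (n, 2, 3)
        frac_all = field.fractions[idx[:, 0], idx[:, 1], idx[:, 2], :]
        align = np.abs(np.einsum("npc,nc->np", mu_all, previous))
        align[frac_all <= 0] = -1.0
        best = np.argmax(align, axis=-1)
        pop = np.where(free, pop, best)
    mu = field.directions[idx[:, 0], idx[:, 1], idx[:, 2], pop, :]
    kap = field.kappa[idx[:, 0], idx[:, 1], idx[:, 2]]
    d = sample_watson(mu, kap, rng)
    dots = np.sum(d * previous, axis=-1)
    flip = np.where(dots < 0, -1.0, 1.0)
    return d * flip[:, None]


def sample_orientation(
    field: OrientationField,
    voxel: tuple[int, int, int],
    previous_direction: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a single unit direction at ``voxel``, sign-aligned so that
    dot(previous_direction, sample) >= 0.

    Raises :class:`OutOfMaskError` if the voxel is outside the valid mask.
    """
    ijk = np.asarray(voxel, dtype=np.int64).reshape(1, 3)
    if not field.grid.inside(ijk)[0] or not field.mask[tuple(ijk[0])]:
        raise OutOfMaskError(f"voxel {tuple(voxel)} is outside the valid mask")
    prev = np.asarray(previous_direction, dtype=float).reshape(1, 3)
    return sample_orientations_batch(field, ijk, prev, rng)[0]
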