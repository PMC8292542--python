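"""Empirical nulls: spherical spin permutations and label shuffling.

Spin permutations destroy the alignment between two brain maps while
preserving each map's spatial autocorrelation: ROI centroids on the unit
sphere are rotated by a random 3-D rotation (mirrored across hemispheres)
and a one-to-one nearest-centroid assignment between original and rotated
positions yields a spatial permutation of ROI indices.  The assignment is
bijective (solved as a linear sum assignment problem per hemisphere), so
a spun map keeps its exact value multiset and mask cardinalities - a
requirement for Dice denominators at ROI resolution.  ROIs without a
spherical embedding (midline/subcortical) are held fixed across spins.

Label shuffling permutes case/control labels (optionally within strata)
and recomputes the full downstream statistic, giving an empirical null
for pipeline-level quantities such as the size of a convergence set.

Empirical p values use the add-one rule p = (1 + b) / (1 + n), the
standard bias-free estimator with a floor of 1/(n+1); p can never be 0.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from cnvmorph.data_model import CohortTable, RoiAtlas, ValidationError
from cnvmorph.convergence import TailMask, dice


def _empirical_p(observed: float, null: np.ndarray, alternative: str) -> float:
    if alternative == "greater":
        b = int(np.sum(null >= observed))
    elif alternative == "less":
        b = int(np.sum(null <= observed))
    elif alternative == "two_sided":
        b = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + b) / (1 + len(null))


@dataclass
class NullDistribution:
    """An observed statistic with its permutation null and empirical p."""

    statistic: str
    observed: float
    null_values: np.ndarray
    p: float
    n_perm: int
    seed: int
    alternative: str
    n_dropped: int = 0  # permutations where the statistic was undefined


@dataclass
class SpinEnsemble:
    """Precomputed ROI index reassignments from random sphere rotations.

    ``assignment[b, i]`` gives the source ROI whose value lands on ROI
    ``i`` in spin ``b``; every row is a bijection of ``0..R-1`` that maps
    each hemisphere onto itself and fixes midline ROIs.
    """

    n_rotations: int
    assignment: np.ndarray  # (n_rotations, R) int
    seed: int
    atlas_hash: str
    include_identity: bool = False

    def __post_init__(self) -> None:
        ref = np.arange(self.assignment.shape[1])
        for b, row in enumerate(self.assignment):
            if not np.array_equal(np.sort(row), ref):
                raise ValidationError(f"spin row {b} is not a permutation")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform 3-D rotation via sign-fixed QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(Rm))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def build_spin_ensemble(
    atlas: RoiAtlas,
    n_rotations: int,
    seed: int = 0,
    mirror_hemispheres: bool = True,
    include_identity: bool = False,
) -> SpinEnsemble:
    """Build a spin ensemble over an atlas with unit-sphere centroids.

    Each spin draws one uniform rotation, applies it to the left
    hemisphere (and its mirror image across the sagittal plane to the
    right hemisphere when ``mirror_hemispheres``), then solves a
    one-to-one nearest-centroid assignment between original and rotated
    positions within each hemisphere.  Deterministic under ``seed``.
    """
    if n_rotations < 1:
        raise ValueError("need at least one rotation")
    rng = np.random.default_rng(seed)
    hemi = np.asarray(atlas.hemisphere)
    R = atlas.n_roi
    mirror = np.diag([-1.0, 1.0, 1.0])

    rows = []
    if include_identity:
        rows.append(np.arange(R))
    n_random = n_rotations - len(rows)
    for _ in range(n_random):
        rot_L = _random_rotation(rng)
        perm = np.arange(R)
        for h in ("L", "R"):
            idx = np.flatnonzero(hemi == h)
            if len(idx) == 0:
                continue
            if h == "R" and mirror_hemispheres:
                rot = mirror @ rot_L @ mirror
            elif h == "R":
                rot = _random_rotation(rng)
            else:
                rot = rot_L
            orig = atlas.centroids[idx]
            rotated = orig @ rot.T
            cost = np.arccos(np.clip(orig @ rotated.T, -1.0, 1.0))
            rows_i, cols_j = linear_sum_assignment(cost)
            perm[idx[rows_i]] = idx[cols_j]
        rows.append(perm)
    assignment = np.array(rows, dtype=int)
    atlas_hash = hashlib.sha256(atlas.hashable_repr().encode()).hexdigest()[:16]
    return SpinEnsemble(
        n_rotations=n_rotations,
        assignment=assignment,
        seed=seed,
        atlas_hash=atlas_hash,
        include_identity=include_identity,
    )


def _as_vector(m) -> np.ndarray:
    if isinstance(m, TailMask):
        return m.members
    return np.asarray(m)


def spin_pvalue(
    stat: str,
    map_a,
    map_b,
    ensemble: SpinEnsemble,
    alternative: str = "greater",
) -> NullDistribution:
    """Empirical spin p value for the similarity of two aligned maps.

    ``map_a`` is spun, ``map_b`` held fixed; the statistic (``pearson_r``
    on d-value vectors or ``dice`` on boolean masks) is recomputed per
    rotation.  Spins on which the statistic is undefined (e.g. a constant
    spun vector) are dropped and counted in ``n_dropped``.
    """
    a = _as_vector(map_a)
    b = _as_vector(map_b)
    if a.shape != b.shape or a.shape[0] != ensemble.assignment.shape[1]:
        raise ValueError("maps must be aligned with each other and the ensemble")

    def compute(x, y) -> float | None:
        if stat == "pearson_r":
            if np.std(x) == 0 or np.std(y) == 0:
                return None
            return float(stats.pearsonr(x, y).statistic)
        if stat == "dice":
            if int(np.sum(x)) + int(np.sum(y)) == 0:
                return None
            return dice(x.astype(bool), y.astype(bool))
        raise ValueError(f"unknown statistic {stat!r}")

    observed = compute(a, b)
    if observed is None:
        raise ValidationError(f"statistic {stat!r} undefined on the observed maps")
    null = []
    dropped = 0
    for row in ensemble.assignment:
        v = compute(a[row], b)
        if v is None:
            dropped += 1
        else:
            null.append(v)
    null = np.asarray(null)
    if len(null) == 0:
        raise ValidationError("all spins produced undefined statistics")
    return NullDistribution(
        statistic=f"spin_{stat}",
        observed=observed,
        null_values=null,
        p=_empirical_p(observed, null, alternative),
        n_perm=len(null),
        seed=ensemble.seed,
        alternative=alternative,
        n_dropped=dropped,
    )


def shuffle_pvalue(
    cohort: CohortTable,
    pipeline_stat: Callable[[CohortTable], float],
    n_perm: int,
    seed: int = 0,
    stratify_by: str = "site",
    alternative: str = "greater",
) -> NullDistribution:
    """Case/control label-shuffling null for a pipeline-level statistic.

    ``pipeline_stat`` must recompute the full downstream chain (contrasts
    -> tail masks -> convergence/overlap statistic) from a cohort table.
    Genotype labels are permuted within strata (``site`` keeps each
    scanning site's label composition fixed; ``none`` permutes freely),
    the statistic is recomputed per permutation, and the empirical p uses
    the add-one rule.
    """
    if n_perm < 19:
        raise ValueError("n_perm < 19 gives a p-value floor coarser than 0.05")
    if stratify_by not in ("site", "none"):
        raise ValueError(f"stratify_by must be 'site' or 'none', got {stratify_by!r}")
    rng = np.random.default_rng(seed)
    observed = float(pipeline_stat(cohort))
    labels = cohort.data["group"].to_numpy().copy()
    if stratify_by == "site":
        strata = [
            np.flatnonzero((cohort.data["site"] == s).to_numpy())
            for s in cohort.data["site"].unique()
        ]
    else:
        strata = [np.arange(cohort.n_subjects)]
    null = np.empty(n_perm)
    df = cohort.data
    for b in range(n_perm):
        perm_labels = labels.copy()
        for idx in strata:
            perm_labels[idx] = labels[idx][rng.permutation(len(idx))]
        shuffled = CohortTable(df.assign(group=perm_labels), cohort.metric)
        null[b] = float(pipeline_stat(shuffled))
    return NullDistribution(
        statistic="shuffle",
        observed=observed,
        null_values=null,
        p=_empirical_p(observed, null, alternative),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )


def morans_i(values: np.ndarray, atlas: RoiAtlas, kernel_deg: float = 20.0) -> float:
    """Moran's I spatial autocorrelation of a map over the atlas.

    Weights are a Gaussian kernel of geodesic angle within each
    hemisphere (zero across hemispheres and on the diagonal).  Used to
    check that spins preserve spatial structure on average.
    """
    x = np.asarray(values, dtype=float)
    n = atlas.n_roi
    hemi = np.asarray(atlas.hemisphere)
    W = np.zeros((n, n))
    ell = np.deg2rad(kernel_deg)
    for h in ("L", "R"):
        idx = np.flatnonzero(hemi == h)
        if len(idx) < 2:
            continue
        C = atlas.centroids[idx]
        ang = np.arccos(np.clip(C @ C.T, -1.0, 1.0))
        K = np.exp(-(ang**2) / (2 * ell**2))
        np.fill_diagonal(K, 0.0)
        W[np.ix_(idx, idx)] = K
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValidationError("Moran's I undefined for a constant map")
    return float(n / W.sum() * (z @ W @ z) / denom)
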