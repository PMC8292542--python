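"""Latent dimensions across CNVs: PCA of Cohen's d profiles and
gene-dosage-coded CCA on subject-level data.

PCA treats ROIs as observations and CNV contrasts as variables, so
"variance explained" is the share of cross-CNV d-profile variance.  The
decomposition is computed as an SVD of the column-standardized d matrix;
component signs are fixed by forcing the largest-magnitude CNV loading of
each component positive, making results reproducible bit-for-bit.

CCA relates a gene-dosage design (deletion = -1, duplication = +1 at each
locus; controls excluded from fitting) to residualized regional volumes.
It is computed by SVD of the whitened cross-covariance (QR whitening of
both blocks).  ROI-side loadings are reported as structure correlations
(correlation of each ROI with the canonical variate).  Significance is
assessed by permuting rows of the dosage matrix with the add-one
empirical p.  Controls are projected post hoc onto the fitted canonical
axes and are never used in the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from cnvmorph.data_model import (
    LOCI,
    CohortTable,
    EffectMap,
    ValidationError,
    parse_group,
)


@dataclass
class DMatrix:
    """R x G matrix of Cohen's d values: rows ROIs, columns CNV contrasts."""

    matrix: np.ndarray
    contrast_ids: list[str]
    roi_ids: list[str]
    zscored: bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def build_dmatrix(maps: list[EffectMap], zscore: bool = True) -> DMatrix:
    """Assemble effect maps into a d matrix, columns ordered by contrast id.

    With ``zscore=True`` each column is standardized to mean 0, SD 1; a
    constant column is then an error.
    """
    if len(maps) < 2:
        raise ValueError("need at least two effect maps")
    ids = [m.contrast_id for m in maps]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate contrast ids: {sorted(ids)}")
    ref = maps[0].roi_ids
    for m in maps[1:]:
        if m.roi_ids != ref:
            raise ValidationError(
                f"effect map {m.contrast_id!r} has a different ROI order"
            )
    order = np.argsort(ids)
    X = np.column_stack([maps[i].d for i in order])
    if zscore:
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [ids[order[i]] for i in np.flatnonzero(sd == 0)]
            raise ValidationError(f"constant d column(s) cannot be z-scored: {bad}")
        X = (X - X.mean(axis=0)) / sd
    return DMatrix(
        matrix=X,
        contrast_ids=[ids[i] for i in order],
        roi_ids=list(ref),
        zscored=zscore,
    )


@dataclass
class LatentDecomposition:
    """PCA of a d matrix: CNV loadings, ROI scores, variance shares."""

    cnv_loadings: np.ndarray  # (G, K) unit eigenvectors, sign-fixed
    roi_scores: np.ndarray  # (R, K) principal component scores
    variance_explained: np.ndarray  # (K,) percent of total
    variance_explained_all: np.ndarray  # all min(R-1, G) components, sums to 100
    contrast_ids: list[str]
    roi_ids: list[str]


def pca_latent(dm: DMatrix, K: int = 2) -> LatentDecomposition:
    """Principal components of the cross-CNV d-profile matrix."""
    R, G = dm.shape
    k_max = min(R - 1, G)
    if not (1 <= K <= k_max):
        raise ValueError(f"K must be in [1, {k_max}], got {K}")
    Xc = dm.matrix - dm.matrix.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    ve_all = 100.0 * var[:k_max] / var.sum()
    loadings = Vt[:K].T.copy()  # (G, K)
    scores = U[:, :K] * S[:K]
    for k in range(K):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]
    return LatentDecomposition(
        cnv_loadings=loadings,
        roi_scores=scores,
        variance_explained=ve_all[:K].copy(),
        variance_explained_all=ve_all,
        contrast_ids=list(dm.contrast_ids),
        roi_ids=list(dm.roi_ids),
    )


def r2_per_cnv(decomp: LatentDecomposition, dm: DMatrix) -> np.ndarray:
    """Percent of each CNV's d profile explained by an OLS on PC1 + PC2."""
    if dm.contrast_ids != decomp.contrast_ids or dm.roi_ids != decomp.roi_ids:
        raise ValidationError("decomposition was not computed from this d matrix")
    k = min(2, decomp.roi_scores.shape[1])
    Z = np.column_stack([np.ones(dm.shape[0]), decomp.roi_scores[:, :k]])
    out = np.empty(dm.shape[1])
    for g in range(dm.shape[1]):
        y = dm.matrix[:, g]
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        sse = float(np.sum((y - Z @ beta) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        out[g] = 100.0 * (1.0 - sse / sst)
    return out


# ---------------------------------------------------------------------------
# Gene-dosage CCA


def gene_dosage_design(
    cohort: CohortTable, loci: tuple[str, ...] = LOCI
) -> tuple[np.ndarray, list[str]]:
    """N x L dosage matrix over carriers: -1 deletion, +1 duplication.

    Controls must be excluded before calling; a control row is an error
    because controls are projected post hoc, never fitted.
    """
    X = np.zeros((cohort.n_subjects, len(loci)))
    for i, label in enumerate(cohort.data["group"]):
        locus, copy = parse_group(label)
        if copy == "none":
            raise ValidationError(
                f"subject {cohort.data['subject_id'].iloc[i]!r} is a control; "
                "exclude controls before building the dosage design"
            )
        if locus not in loci:
            raise ValidationError(f"locus {locus!r} not in {loci}")
        X[i, loci.index(locus)] = -1.0 if copy == "del" else 1.0
    return X, list(loci)


@dataclass
class ResidualizeModel:
    """Stored OLS coefficients for ROI residualization, reusable on
    held-out controls with the training-set design conventions."""

    covariates: tuple[str, ...]
    coef: np.ndarray  # (p, R)
    age_center: float
    site_levels: list[str]
    roi_ids: list[str]

    def design(self, cohort: CohortTable) -> np.ndarray:
        cols = [np.ones(cohort.n_subjects)]
        da = cohort.data["age"].to_numpy(dtype=float) - self.age_center
        for cov in self.covariates:
            if cov == "age":
                cols.append(da)
            elif cov == "age2":
                cols.append(da**2)
            elif cov in ("sex", "TIV", "total_GM"):
                cols.append(cohort.data[cov].to_numpy(dtype=float))
            elif cov == "site":
                site = cohort.data["site"].astype(str)
                for s in self.site_levels[1:]:  # unseen sites fall to reference
                    cols.append((site == s).to_numpy(dtype=float))
            else:
                raise KeyError(f"unknown covariate {cov!r}")
        return np.column_stack(cols)

    def apply(self, cohort: CohortTable) -> np.ndarray:
        """Residualize a cohort's ROI values with the stored coefficients."""
        if cohort.roi_ids != self.roi_ids:
            raise ValidationError("cohort ROI order differs from the fitted model")
        if cohort.n_subjects == 0:
            return np.empty((0, len(self.roi_ids)))
        return cohort.roi_values - self.design(cohort) @ self.coef


def residualize_rois(
    cohort: CohortTable,
    covariates: tuple[str, ...] = ("total_GM", "age", "age2", "sex", "site"),
) -> tuple[np.ndarray, ResidualizeModel]:
    """Per-ROI OLS residuals of the ROI values on nuisance covariates.

    Returns the residual matrix for this cohort and the fitted model so
    that held-out controls can be residualized with identical
    coefficients and design conventions.
    """
    model = ResidualizeModel(
        covariates=tuple(covariates),
        coef=np.empty(0),
        age_center=float(cohort.data["age"].mean()),
        site_levels=sorted(cohort.data["site"].astype(str).unique()),
        roi_ids=cohort.roi_ids,
    )
    X = model.design(cohort)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular residualization design")
    coef, *_ = np.linalg.lstsq(X, cohort.roi_values, rcond=None)
    model.coef = coef
    return cohort.roi_values - X @ coef, model


@dataclass
class GeneMorphCCA:
    """Canonical correlation between gene dosage and brain residuals."""

    loci: list[str]
    canonical_correlations: np.ndarray  # (K,), non-increasing, in [0, 1]
    x_weights: np.ndarray  # (L, K): unit-variance canonical variates
    y_weights: np.ndarray  # (R, K)
    x_loadings: np.ndarray  # (L, K) structure correlations
    y_loadings: np.ndarray  # (R, K) structure correlations
    x_scores: np.ndarray  # (N, K) dosage-side subject scores
    subject_scores: np.ndarray  # (N, K) brain-side subject scores
    perm_p: np.ndarray  # (K,) add-one permutation p per dimension
    x_mean: np.ndarray
    y_mean: np.ndarray
    n_perm: int
    seed: int
    y_reduction: str | None = None


def _cca_core(
    Xc: np.ndarray, Yc: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlations and weights of two column-centered blocks
    via QR whitening and SVD of the whitened cross-covariance."""
    Qx, Rx = np.linalg.qr(Xc)
    Qy, Ry = np.linalg.qr(Yc)
    U, S, Vt = np.linalg.svd(Qx.T @ Qy)
    S = np.clip(S[:K], 0.0, 1.0)
    n = Xc.shape[0]
    # weights normalized so canonical variates have unit sample variance
    wx = linalg.solve_triangular(Rx, U[:, :K]) * np.sqrt(n - 1)
    wy = linalg.solve_triangular(Ry, Vt[:K].T) * np.sqrt(n - 1)
    return S, wx, wy


def cca_gene_morph(
    X: np.ndarray,
    Y: np.ndarray,
    K: int = 2,
    n_perm: int = 999,
    seed: int = 0,
    loci: list[str] | tuple[str, ...] = LOCI,
    y_reduce: str | None = None,
) -> GeneMorphCCA:
    """Fit gene-dosage CCA and assess dimensions by row permutation of X.

    ``Y`` must have full column rank with more rows than columns; when it
    does not, pass ``y_reduce='pca90'`` to fit in a PCA basis retaining
    at least 90% of Y's variance (weights and loadings are mapped back to
    ROI space).  ``perm_p[k]`` compares the k-th canonical correlation
    with its distribution under ``n_perm`` joint row permutations of X.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    N, L = X.shape
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    basis = None
    if y_reduce is None:
        if N <= Y.shape[1] or np.linalg.matrix_rank(Yc) < Y.shape[1]:
            raise ValueError(
                "Y is rank deficient (or has no more rows than columns); "
                "pass y_reduce='pca90' to fit in a reduced PCA basis"
            )
        Yf = Yc
    elif y_reduce == "pca90":
        U, S, Vt = np.linalg.svd(Yc, full_matrices=False)
        var = S**2
        keep = int(np.searchsorted(np.cumsum(var) / var.sum(), 0.90) + 1)
        keep = max(keep, K)
        basis = Vt[:keep].T  # (R, keep)
        Yf = Yc @ basis
    else:
        raise ValueError(f"unknown y_reduce {y_reduce!r}")
    if not (1 <= K <= min(L, Yf.shape[1])):
        raise ValueError(f"K must be in [1, {min(L, Yf.shape[1])}], got {K}")

    rho, wx, wy_f = _cca_core(Xc, Yf, K)
    wy = basis @ wy_f if basis is not None else wy_f
    x_scores = Xc @ wx
    y_scores = Yc @ wy
    # deterministic sign: largest-magnitude y-weight positive per dimension
    for k in range(K):
        j = int(np.argmax(np.abs(wy[:, k])))
        if wy[j, k] < 0:
            wy[:, k] = -wy[:, k]
            wx[:, k] = -wx[:, k]
            y_scores[:, k] = -y_scores[:, k]
            x_scores[:, k] = -x_scores[:, k]

    def structure_corr(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
        bs = block.std(axis=0, ddof=0)
        ss = scores.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (block - block.mean(axis=0)).T @ (
                scores - scores.mean(axis=0)
            ) / block.shape[0]
            c = c / np.outer(bs, ss)
        return np.nan_to_num(c)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, K))
    for b in range(n_perm):
        Xp = Xc[rng.permutation(N)]
        null[b], _, _ = _cca_core(Xp, Yf, K)
    perm_p = (1 + np.sum(null >= rho[None, :], axis=0)) / (1 + n_perm)

    return GeneMorphCCA(
        loci=list(loci),
        canonical_correlations=rho,
        x_weights=wx,
        y_weights=wy,
        x_loadings=structure_corr(Xc, x_scores),
        y_loadings=structure_corr(Yc, y_scores),
        x_scores=x_scores,
        subject_scores=y_scores,
        perm_p=perm_p,
        x_mean=x_mean,
        y_mean=y_mean,
        n_perm=n_perm,
        seed=seed,
        y_reduction=y_reduce,
    )


def project_controls(cca: GeneMorphCCA, controls_Y: np.ndarray) -> np.ndarray:
    """Project held-out (residualized) control subjects onto the fitted
    brain-side canonical axes.  Projecting the training Y reproduces
    ``subject_scores`` exactly; an empty control set yields an empty
    score matrix."""
    controls_Y = np.asarray(controls_Y, dtype=float)
    if controls_Y.ndim != 2 or (
        controls_Y.shape[0] > 0 and controls_Y.shape[1] != cca.y_weights.shape[0]
    ):
        raise ValueError(
            f"controls_Y must be (n, {cca.y_weights.shape[0]}), "
            f"got {controls_Y.shape}"
        )
    if controls_Y.shape[0] == 0:
        return np.empty((0, cca.y_weights.shape[1]))
    return (controls_Y - cca.y_mean) @ cca.y_weights


def compare_loadings(cca: GeneMorphCCA, decomp: LatentDecomposition) -> np.ndarray:
    """K x K Pearson correlations between CCA ROI loadings (rows of the
    result index CCA dimensions) and PCA ROI score columns."""
    A = cca.y_loadings
    B = decomp.roi_scores
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"ROI count mismatch: CCA has {A.shape[0]}, PCA has {B.shape[0]}"
        )
    Ac = (A - A.mean(axis=0)) / A.std(axis=0, ddof=0)
    Bc = (B - B.mean(axis=0)) / B.std(axis=0, ddof=0)
    return Ac.T @ Bc / A.shape[0]
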