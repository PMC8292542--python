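"""Null-calibration experiments for the pipeline's inferential machinery.

Each function simulates data with no planted effects and measures the
behavior of a p value under its own null: per-ROI GLM p values should be
uniform, spin p values for the correlation of two independent smooth maps
should be uniform across replicate experiments, the label-shuffle test of
the convergence-set size should reject at its nominal rate, and CCA
permutation p values should be uniform when dosage and brain data are
independent.  These are the checks a user should rerun after modifying
any of the null machinery.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from cnvmorph.contrasts import pvalues, roi_contrast
from cnvmorph.convergence import convergence_map, tail_mask
from cnvmorph.data_model import CohortTable
from cnvmorph.latent import cca_gene_morph
from cnvmorph.nulls import build_spin_ensemble, shuffle_pvalue, spin_pvalue
from cnvmorph.pipeline import _subseeds
from cnvmorph.synthetic import (
    CovariateModel,
    make_effect_atlas,
    make_roi_sphere,
    simulate_cohort,
)

NULL_GROUPS = ("1q21.1_del", "16p11.2_del", "22q11.2_del", "15q11.2_del")


def _randomized_pit(pvals: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Randomized probability-integral transform for add-one p values.

    An exactly valid permutation p is discrete uniform on k/(n_perm+1),
    k = 1..n_perm+1 (mean 0.5 + 0.5/(n_perm+1), never 0); subtracting an
    independent U(0, 1/(n_perm+1)) jitter maps it to continuous U(0, 1),
    so a KS test against the continuous uniform is exact rather than
    penalizing the p-value grid.
    """
    return pvals - rng.uniform(0.0, 1.0 / (n_perm + 1), size=len(pvals))


def _null_cohort(n_roi: int, n_per_group: int, n_controls: int, seed: int):
    atlas = make_effect_atlas(
        n_roi,
        groups=list(NULL_GROUPS),
        K=1,
        loading_spec=np.zeros((len(NULL_GROUPS), 1)),
        mirror=False,
        seed=seed,
    )
    cohort, _ = simulate_cohort(
        atlas,
        CovariateModel(),
        {g: n_per_group for g in NULL_GROUPS},
        n_controls=n_controls,
        seed=seed,
    )
    return cohort


def contrast_pvalue_uniformity(seed: int, n_roi: int = 2000, n: int = 100) -> dict:
    """KS test of per-ROI contrast p values under the global null."""
    cohort = _null_cohort(n_roi, n, n, seed)
    emap = roi_contrast(cohort, NULL_GROUPS[0], covariates=("age", "age2", "sex"))
    ks = stats.kstest(pvalues(emap), "uniform")
    return {"ks_p": float(ks.pvalue), "n_roi": n_roi}


def spin_pvalue_calibration(
    seed: int, n_rep: int = 200, n_roi: int = 60, n_spins: int = 499
) -> dict:
    """Spin p for the correlation of two independent exchangeable null
    maps, with a fresh atlas and ensemble per replicate experiment;
    returns the KS uniformity p.

    Exchangeable maps are the spin test's exact-validity regime; for
    strongly autocorrelated maps, parcel-level bijective spins are known
    to be mildly anticonservative (see the methods note), so calibration
    of the machinery is assessed where the null is exact.
    """
    rep_seeds = _subseeds(seed, 3 * n_rep + 1)
    pvals = np.empty(n_rep)
    for i in range(n_rep):
        sphere = make_roi_sphere(n_roi, hemispheres=True, seed=rep_seeds[3 * i])
        ens = build_spin_ensemble(sphere, n_spins, seed=rep_seeds[3 * i + 1])
        rng = np.random.default_rng(rep_seeds[3 * i + 2])
        a = rng.standard_normal(n_roi)
        b = rng.standard_normal(n_roi)
        pvals[i] = spin_pvalue("pearson_r", a, b, ens, alternative="greater").p
    u = _randomized_pit(pvals, n_spins, np.random.default_rng(rep_seeds[-1]))
    ks = stats.kstest(u, "uniform")
    return {"ks_p": float(ks.pvalue), "pvals": pvals, "n_rep": n_rep}


def shuffle_type_i_error(
    seed: int,
    n_rep: int = 100,
    n_perm: int = 99,
    n_roi: int = 250,
    n_per_group: int = 30,
    n_controls: int = 100,
    alpha: float = 0.05,
    groups: tuple[str, ...] = NULL_GROUPS[:2],
) -> dict:
    """Rejection rate of the label-shuffle convergence test on null data.

    The statistic is the all-K convergence-set size over the given
    groups' tail masks.  Two groups keep the null distribution of the
    size non-degenerate (with four independent null maps the all-4 set
    is almost surely empty, which makes the discrete test unmeasurably
    conservative rather than calibrated).
    """

    def stat(cohort: CohortTable) -> float:
        maps = [
            roi_contrast(cohort, g, covariates=("age", "sex")) for g in groups
        ]
        lows, highs = zip(*(tail_mask(m) for m in maps))
        return float(
            convergence_map(list(lows)).all_k.sum()
            + convergence_map(list(highs)).all_k.sum()
        )

    rep_seeds = _subseeds(seed, 2 * n_rep)
    rejections = 0
    for i in range(n_rep):
        cohort = _null_cohort(n_roi, n_per_group, n_controls, rep_seeds[2 * i])
        nd = shuffle_pvalue(cohort, stat, n_perm=n_perm, seed=rep_seeds[2 * i + 1])
        rejections += nd.p <= alpha
    return {"rejection_rate": rejections / n_rep, "n_rep": n_rep, "alpha": alpha}


def cca_permutation_calibration(
    seed: int, n_rep: int = 100, n: int = 150, n_roi: int = 12, n_perm: int = 99
) -> dict:
    """CCA permutation p for independent dosage and brain blocks."""
    rep_seeds = _subseeds(seed, n_rep + 1)
    pvals = np.empty(n_rep)
    for i, s in enumerate(rep_seeds[:n_rep]):
        rng = np.random.default_rng(s)
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, 4))
        Y = rng.standard_normal((n, n_roi))
        fit = cca_gene_morph(X, Y, K=1, n_perm=n_perm, seed=s)
        pvals[i] = fit.perm_p[0]
    u = _randomized_pit(pvals, n_perm, np.random.default_rng(rep_seeds[-1]))
    ks = stats.kstest(u, "uniform")
    return {"ks_p": float(ks.pvalue), "pvals": pvals, "n_rep": n_rep}
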