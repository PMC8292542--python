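"""Covariate-adjusted global z-scores and per-ROI Cohen's d effect maps.

Global aggregate measures (TIV, total grey matter, ...) are adjusted for
age, age^2 and sex as fixed effects with scanning site as a random
intercept, the model being fitted on controls only and applied to all
subjects; z-scores are then standardized by the control residual
distribution.

Regional contrasts fit, per ROI, the fixed-effects GLM
``value ~ group + covariates (+ site dummies)``; Cohen's d is the
adjusted standardized mean difference ``beta_group / residual SD``,
which equals the common conversion ``t * sqrt(1/n_case + 1/n_control)``
whenever the covariates are orthogonal to the group factor and reduces
to pooled-SD Cohen's d with no covariates at all.  Site enters the
regional model as fixed dummies, mirroring mass-univariate practice,
while the global model uses a random site intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from cnvmorph.data_model import CohortTable, EffectMap, parse_group

KNOWN_COVARIATES = ("age", "age2", "sex", "TIV", "total_GM")


def _fixed_design(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + age + age^2 + sex columns (age centered for conditioning)."""
    age = covariates["age"].to_numpy(dtype=float)
    da = age - age.mean()
    sex = covariates["sex"].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(age)), da, da**2, sex])


def adjust_metric(
    values: np.ndarray,
    covariates: pd.DataFrame,
    control_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Residualize a global metric on age, age^2, sex (fixed) and site
    (random intercept), fitting on controls only.

    ``covariates`` must carry ``age``, ``sex`` and ``site`` columns
    aligned with ``values``.  Subjects outside ``control_mask`` are
    residualized with the control-fitted coefficients; sites unseen in
    the control fit get a zero site offset.  With a single site the model
    degenerates to fixed-effects OLS (a warning is raised).
    """
    values = np.asarray(values, dtype=float)
    if control_mask is None:
        control_mask = np.ones(len(values), dtype=bool)
    control_mask = np.asarray(control_mask, dtype=bool)
    X = _fixed_design(covariates)
    if np.linalg.matrix_rank(X[control_mask]) < X.shape[1]:
        raise ValueError("singular fixed-effects design on the control subset")
    if control_mask.sum() <= X.shape[1] + 2:
        raise ValueError("too few controls to fit the adjustment model")
    sites = covariates["site"].astype(str).to_numpy()
    n_sites = len(np.unique(sites[control_mask]))
    site_effect = {}
    if n_sites < 2:
        warnings.warn(
            "single scanning site: falling back to fixed-effects-only adjustment",
            UserWarning,
        )
        beta, *_ = np.linalg.lstsq(X[control_mask], values[control_mask], rcond=None)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary fits (zero site variance)
            model = MixedLM(
                values[control_mask], X[control_mask], groups=sites[control_mask]
            )
            fit = model.fit(reml=True)
        re_var = float(np.asarray(fit.cov_re).ravel()[0])
        boundary = re_var <= 1e-8 * float(fit.scale)
        if getattr(fit, "converged", True) and not boundary:
            beta = fit.fe_params
            try:
                site_effect = {
                    g: float(re.iloc[0]) for g, re in fit.random_effects.items()
                }
            except ValueError:
                # site variance at the boundary (zero): no offsets
                site_effect = {}
        else:
            # degenerate likelihood (e.g. no real site variance):
            # the model reduces to fixed-effects OLS
            beta, *_ = np.linalg.lstsq(
                X[control_mask], values[control_mask], rcond=None
            )
    offsets = np.array([site_effect.get(s, 0.0) for s in sites])
    return values - X @ beta - offsets


@dataclass
class GlobalZscores:
    """Covariate-adjusted z-scores of a global metric, standardized so the
    control group has mean 0 and SD 1."""

    metric: str
    table: pd.DataFrame  # subject_id, group, ascertainment, z
    group_stats: pd.DataFrame  # group, n, mean_z, t, p (H0: mean z = 0)
    locus_tests: pd.DataFrame  # locus, t, p (deletion vs duplication)

    def z_for(self, group: str) -> np.ndarray:
        return self.table.loc[self.table["group"] == group, "z"].to_numpy()


def global_zscores(
    cases: CohortTable, controls: CohortTable, metric: str
) -> GlobalZscores:
    """z-scores of one global metric for every case group versus controls.

    Emits a two-sided one-sample test of mean z per group and a
    deletion-versus-duplication test within each locus with both copy
    states present.  Controls should be ascertainment-matched to the
    cases; a mismatch raises a warning, not an error.
    """
    if metric not in cases.data.columns:
        raise KeyError(f"metric {metric!r} not in cohort table")
    if controls.n_subjects < 2:
        raise ValueError("need at least 2 controls")
    case_asc = set(cases.data["ascertainment"])
    ctrl_asc = set(controls.data["ascertainment"])
    if not case_asc <= ctrl_asc:
        warnings.warn(
            f"controls are not ascertainment-matched (cases {sorted(case_asc)}, "
            f"controls {sorted(ctrl_asc)})",
            UserWarning,
        )
    combined = pd.concat([controls.data, cases.data], ignore_index=True)
    is_control = np.zeros(len(combined), dtype=bool)
    is_control[: controls.n_subjects] = True
    resid = adjust_metric(
        combined[metric].to_numpy(dtype=float), combined, control_mask=is_control
    )
    mu = resid[is_control].mean()
    sd = resid[is_control].std(ddof=0)
    if sd == 0:
        raise ValueError(f"control residuals of {metric!r} are constant")
    z = (resid - mu) / sd

    table = combined[["subject_id", "group", "ascertainment"]].copy()
    table["z"] = z
    stats_rows = []
    for group in sorted(set(cases.data["group"])):
        zg = z[~is_control][(cases.data["group"] == group).to_numpy()]
        t, p = stats.ttest_1samp(zg, 0.0)
        stats_rows.append(
            {"group": group, "n": len(zg), "mean_z": zg.mean(), "t": t, "p": p}
        )
    group_stats = pd.DataFrame(stats_rows)

    locus_rows = []
    by_locus: dict[str, dict[str, np.ndarray]] = {}
    for group in sorted(set(cases.data["group"])):
        locus, copy = parse_group(group)
        if copy in ("del", "dup"):
            zg = z[~is_control][(cases.data["group"] == group).to_numpy()]
            by_locus.setdefault(locus, {})[copy] = zg
    for locus, arms in sorted(by_locus.items()):
        if {"del", "dup"} <= set(arms):
            t, p = stats.ttest_ind(arms["del"], arms["dup"])
            locus_rows.append({"locus": locus, "t": t, "p": p})
    locus_tests = pd.DataFrame(locus_rows, columns=["locus", "t", "p"])
    return GlobalZscores(metric, table, group_stats, locus_tests)


# ---------------------------------------------------------------------------
# Regional contrasts


def _contrast_design(
    sub: pd.DataFrame, case_group: str, covariates: tuple[str, ...], site_mode: str
) -> tuple[np.ndarray, int]:
    """Design matrix (intercept, group indicator, covariates, site dummies)
    and the column index of the group indicator."""
    n = len(sub)
    cols = [np.ones(n)]
    group_col = (sub["group"] == case_group).to_numpy(dtype=float)
    cols.append(group_col)
    age = sub["age"].to_numpy(dtype=float)
    da = age - age.mean()
    for cov in covariates:
        if cov == "age":
            cols.append(da)
        elif cov == "age2":
            cols.append(da**2)
        elif cov in ("sex", "TIV", "total_GM"):
            cols.append(sub[cov].to_numpy(dtype=float))
        else:
            raise KeyError(f"unknown covariate {cov!r}; known: {KNOWN_COVARIATES}")
    if site_mode == "fixed":
        sites = sorted(sub["site"].astype(str).unique())
        for s in sites[1:]:  # first site is the reference level
            cols.append((sub["site"].astype(str) == s).to_numpy(dtype=float))
    elif site_mode != "none":
        raise ValueError(f"site_mode must be 'fixed' or 'none', got {site_mode!r}")
    return np.column_stack(cols), 1


def _glm_group_stats(
    X: np.ndarray, Y: np.ndarray, j: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Coefficient j, its t-statistic, the residual SD, and residual df of
    the per-column GLM Y = X b + e."""
    n, p = X.shape
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < p:
        raise ValueError("singular contrast design matrix")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.sum(resid**2, axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[j, j], 1e-300))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[j] / se
    t = np.where(sigma2 == 0, 0.0, t)
    return beta[j], t, np.sqrt(sigma2), df


def roi_contrast(
    cohort: CohortTable,
    case_group: str,
    control_group: str = "control",
    covariates: tuple[str, ...] | list[str] = ("age", "age2", "sex", "total_GM"),
    site_mode: str = "fixed",
) -> EffectMap:
    """Per-ROI case-control Cohen's d effect map from a fixed-effects GLM.

    ``t`` is the group-coefficient t-statistic and ``df`` the residual
    degrees of freedom of the fitted GLM.  Cohen's d is the adjusted
    standardized mean difference ``d = beta_group / residual SD``.  When
    the covariates are orthogonal to the group factor this equals the
    common two-sample conversion ``t * sqrt(1/n_case + 1/n_control)`` (and
    with no covariates at all it is exactly pooled-SD Cohen's d); when a
    covariate such as total grey matter differs between the groups, the
    direct form avoids the attenuation that the ``t``-based conversion
    inherits from the inflated coefficient standard error.  Site dummies
    are included when ``site_mode='fixed'`` and more than one site is
    present.
    """
    covariates = tuple(covariates)
    mask = cohort.data["group"].isin([case_group, control_group]).to_numpy()
    sub = cohort.data.loc[mask].reset_index(drop=True)
    n_case = int((sub["group"] == case_group).sum())
    n_control = int((sub["group"] == control_group).sum())
    if n_case < 3:
        raise ValueError(f"case group {case_group!r} has n={n_case} < 3")
    if n_control < 3:
        raise ValueError(f"control group {control_group!r} has n={n_control} < 3")
    effective_site_mode = site_mode
    if site_mode == "fixed" and sub["site"].nunique() < 2:
        effective_site_mode = "none"
    X, j = _contrast_design(sub, case_group, covariates, effective_site_mode)
    Y = sub[cohort.roi_columns].to_numpy(dtype=float)
    beta, t, sigma, df = _glm_group_stats(X, Y, j)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(sigma > 0, beta / np.maximum(sigma, 1e-300), 0.0)
    var_jj = float(np.linalg.inv(X.T @ X)[j, j])
    d_var_scale = var_jj * (df / (df - 2) if df > 2 else 1.0)
    return EffectMap(
        contrast_id=case_group,
        roi_ids=cohort.roi_ids,
        d=d,
        t=t,
        df=df,
        n_case=n_case,
        n_control=n_control,
        covariate_set=list(covariates),
        d_var_scale=d_var_scale,
    )


def pvalues(emap: EffectMap) -> np.ndarray:
    """Two-sided p-values of the per-ROI group t-statistics."""
    return 2.0 * stats.t.sf(np.abs(emap.t), emap.df)


def multiplicity(
    emap: EffectMap,
    method: str = "fdr_bh",
    alpha: float = 0.05,
    cohort: CohortTable | None = None,
    case_group: str | None = None,
    control_group: str = "control",
    covariates: tuple[str, ...] | list[str] = (),
    site_mode: str = "fixed",
    n_perm: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """Boolean significance mask per ROI under a multiplicity correction.

    Methods: ``none`` (uncorrected two-sided p < alpha), ``bonferroni``,
    ``fdr_bh``, and ``maxT_permutation`` - a permutation family-wise
    correction that permutes the case/control labels, refits the GLM, and
    compares each observed \\|t\\| with the permutation distribution of the
    maximum \\|t\\| over ROIs (the ROI-scale analogue of image-based FWE
    thresholding; ``cohort`` and ``case_group`` are required).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if method == "none":
        return pvalues(emap) < alpha
    if method in ("bonferroni", "fdr_bh"):
        reject, *_ = multipletests(pvalues(emap), alpha=alpha, method=method)
        return reject
    if method == "maxT_permutation":
        if cohort is None or case_group is None:
            raise ValueError("maxT_permutation requires cohort and case_group")
        mask = cohort.data["group"].isin([case_group, control_group]).to_numpy()
        sub = cohort.data.loc[mask].reset_index(drop=True)
        effective_site_mode = site_mode
        if site_mode == "fixed" and sub["site"].nunique() < 2:
            effective_site_mode = "none"
        X, j = _contrast_design(sub, case_group, tuple(covariates), effective_site_mode)
        Y = sub[cohort.roi_columns].to_numpy(dtype=float)
        _, t_obs, _, _ = _glm_group_stats(X, Y, j)
        rng = np.random.default_rng(seed)
        group_col = X[:, j].copy()
        max_t = np.empty(n_perm)
        Xp = X.copy()
        for b in range(n_perm):
            Xp[:, j] = rng.permutation(group_col)
            _, t_b, _, _ = _glm_group_stats(Xp, Y, j)
            max_t[b] = np.max(np.abs(t_b))
        # add-one empirical FWE-adjusted p per ROI
        p_adj = (1 + np.sum(max_t[None, :] >= np.abs(t_obs)[:, None], axis=1)) / (
            1 + n_perm
        )
        return p_adj <= alpha
    raise ValueError(f"unknown multiplicity method {method!r}")
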