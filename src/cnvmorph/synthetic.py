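"""Synthetic cohorts with planted cross-CNV effect structure.

The generator emulates the statistical design of a multi-site
deletion/duplication morphometry study: carriers at four genomic loci plus
controls, clinical and non-clinical (biobank) ascertainment with a large
age offset, site offsets, age/age^2/sex covariate effects, global
(TIV-like) scaling, and regional effect maps composed of a small number of
shared latent spatial components - with opposing deletion/duplication
loadings per locus - plus CNV-private components.

Effects are planted on the residual-SD scale, so planted values are
directly Cohen's d units and parameter-recovery assertions are exact.
Every planted quantity is returned in a truth record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from cnvmorph.data_model import (
    CONTROL_GROUP,
    LOCI,
    CohortTable,
    RoiAtlas,
    parse_group,
)

PAPER8_GROUPS = (
    "1q21.1_del",
    "1q21.1_dup",
    "16p11.2_del",
    "16p11.2_dup",
    "22q11.2_del",
    "22q11.2_dup",
    "15q11.2_del",
    "15q11.2_dup",
)

# Per-group latent direction (degrees within the 2-D latent plane) and
# loading magnitude.  Deletion directions cluster tightly around the first
# latent axis, so all four deletions share a convergent extreme set;
# duplications load with opposite sign on that axis (locus-wise mirror
# sign opposition) while carrying most of the second-axis mass, keeping
# the two latent dimensions comparably important.  16p11.2 duplications
# are the exact negative of half the deletion loading: the locus with a
# twofold deletion/duplication effect-size ratio.
_PAPER8_DESIGN: dict[str, dict[str, tuple[float, float]]] = {
    # locus: {copy: (angle_deg, loading magnitude)}
    "1q21.1": {"del": (12.0, 7.20), "dup": (225.0, 8.20)},
    "16p11.2": {"del": (-8.0, 8.20), "dup": (172.0, 4.10)},
    "22q11.2": {"del": (20.0, 7.20), "dup": (248.0, 7.80)},
    "15q11.2": {"del": (0.0, 4.60), "dup": (215.0, 4.70)},
}
PAPER8_VARIANCE_SPLIT = (0.60, 0.40)  # latent dimension 1 : dimension 2
PAPER8_DISTINCT_SD = 0.2
PAPER8_RATIO_LOCUS = "16p11.2"

# Group sizes mimic the demographics table of a pooled clinical + biobank
# design: clinically ascertained carriers at 1q21.1/16p11.2/22q11.2 with
# 331 clinical controls, biobank-ascertained 15q11.2 carriers with 965
# controls.
PAPER8_GROUP_SIZES: dict[str, int] = {
    "1q21.1_del": 29,
    "1q21.1_dup": 19,
    "16p11.2_del": 83,
    "16p11.2_dup": 73,
    "22q11.2_del": 74,
    "22q11.2_dup": 22,
    "15q11.2_del": 72,
    "15q11.2_dup": 76,
}
PAPER8_ASCERTAINMENT: dict[str, str] = {
    "1q21.1_del": "clinical",
    "1q21.1_dup": "clinical",
    "16p11.2_del": "clinical",
    "16p11.2_dup": "clinical",
    "22q11.2_del": "clinical",
    "22q11.2_dup": "clinical",
    "15q11.2_del": "nonclinical",
    "15q11.2_dup": "nonclinical",
}
PAPER8_N_CONTROLS: dict[str, int] = {"clinical": 331, "nonclinical": 965}

# Multiplicative TIV factors per group relative to the matched control
# mean, read off the demographics table (e.g. 1q21.1 deletions have
# markedly smaller, duplications larger head size).
PAPER8_GLOBAL_SCALE: dict[str, float] = {
    "1q21.1_del": 1.22 / 1.46,
    "1q21.1_dup": 1.57 / 1.46,
    "16p11.2_del": 1.54 / 1.46,
    "16p11.2_dup": 1.33 / 1.46,
    "22q11.2_del": 1.30 / 1.46,
    "22q11.2_dup": 1.47 / 1.46,
    "15q11.2_del": 1.54 / 1.51,
    "15q11.2_dup": 1.49 / 1.51,
}


def paper8_group_sizes() -> dict[str, int]:
    """Carrier group sizes of the eight-CNV study preset."""
    return dict(PAPER8_GROUP_SIZES)


@dataclass
class EffectAtlas:
    """Ground-truth regional effect structure for a set of CNV groups.

    ``group_map(g)`` = ``latent_patterns @ cnv_loadings[g] +
    distinct_patterns[:, g]`` in Cohen's d units at the generating noise
    scale.  Latent pattern columns are orthonormal.
    """

    groups: list[str]
    latent_patterns: np.ndarray  # (R, K), orthonormal columns
    cnv_loadings: np.ndarray  # (G, K)
    distinct_patterns: np.ndarray  # (R, G)
    global_scale: np.ndarray  # (G,), multiplicative TIV-like factor
    mirror: bool = True

    def __post_init__(self) -> None:
        R, K = self.latent_patterns.shape
        G = len(self.groups)
        if self.cnv_loadings.shape != (G, K):
            raise ValueError("cnv_loadings must be (G, K)")
        if self.distinct_patterns.shape != (R, G):
            raise ValueError("distinct_patterns must be (R, G)")
        gram = self.latent_patterns.T @ self.latent_patterns
        if not np.allclose(gram, np.eye(K), atol=1e-9):
            raise ValueError("latent_patterns columns must be orthonormal (1e-9)")
        if self.mirror:
            self._check_mirror()

    def _check_mirror(self) -> None:
        by_locus: dict[str, dict[str, int]] = {}
        for i, g in enumerate(self.groups):
            locus, copy = parse_group(g)
            by_locus.setdefault(locus, {})[copy] = i
        for locus, idx in by_locus.items():
            if {"del", "dup"} <= set(idx):
                ld = self.cnv_loadings[idx["del"]]
                lu = self.cnv_loadings[idx["dup"]]
                k = int(np.argmax(np.abs(ld)))
                if ld[k] * lu[k] >= 0:
                    raise ValueError(
                        f"mirror=True but {locus} deletion/duplication loadings do "
                        f"not oppose on dimension {k}"
                    )

    @property
    def n_roi(self) -> int:
        return self.latent_patterns.shape[0]

    @property
    def n_latent(self) -> int:
        return self.latent_patterns.shape[1]

    def group_map(self, group: str) -> np.ndarray:
        """Planted per-ROI Cohen's d map for one group."""
        try:
            g = self.groups.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} not in atlas ({self.groups})") from None
        return self.latent_patterns @ self.cnv_loadings[g] + self.distinct_patterns[:, g]

    def group_maps(self) -> np.ndarray:
        """(R, G) matrix of planted maps, columns in group order."""
        return self.latent_patterns @ self.cnv_loadings.T + self.distinct_patterns

    def sd_ratio(self, locus: str) -> float:
        """SD(deletion map) / SD(duplication map) of the planted maps."""
        return float(
            np.std(self.group_map(f"{locus}_del"), ddof=1)
            / np.std(self.group_map(f"{locus}_dup"), ddof=1)
        )


def _paper8_loadings() -> np.ndarray:
    """8x2 loading matrix with locus-wise sign opposition and an exact
    60/40 split between the two principal axes of the loading Gram.

    Normalizing the Gram eigenvalues (rather than raw per-axis loading
    mass) makes the planted split exactly what a PCA of the noiseless
    group-map matrix recovers as its first two variance shares.
    """
    rows = []
    for g in PAPER8_GROUPS:
        locus, copy = parse_group(g)
        angle, mag = _PAPER8_DESIGN[locus][copy]
        theta = np.deg2rad(angle)
        rows.append(mag * np.array([np.cos(theta), np.sin(theta)]))
    L = np.array(rows)
    gram = L.T @ L
    eigval, eigvec = np.linalg.eigh(gram)  # ascending
    eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
    target = np.array(PAPER8_VARIANCE_SPLIT) * eigval.sum()
    T = eigvec @ np.diag(np.sqrt(target / eigval)) @ eigvec.T
    return L @ T


def make_effect_atlas(
    R: int,
    groups: Sequence[str] | None = None,
    K: int = 2,
    loading_spec: np.ndarray | str = "paper8",
    distinct_sd: float = 0.0,
    mirror: bool = True,
    seed: int = 0,
) -> EffectAtlas:
    """Construct a ground-truth effect atlas.

    ``loading_spec`` is either a (G, K) matrix of signed loadings or the
    preset name ``"paper8"`` (eight groups at four loci, K=2, locus-wise
    opposing deletion/duplication loadings, 60/40 latent variance split).
    With ``distinct_sd=0`` every group map lies exactly in the span of the
    latent patterns.
    """
    global_scale = None
    if isinstance(loading_spec, str):
        if loading_spec != "paper8":
            raise ValueError(f"unknown loading preset {loading_spec!r}")
        groups = list(PAPER8_GROUPS)
        loadings = _paper8_loadings()
        K = 2
        global_scale = np.array([PAPER8_GLOBAL_SCALE[g] for g in groups])
    else:
        loadings = np.asarray(loading_spec, dtype=float)
        if groups is None:
            raise ValueError("groups must be given with an explicit loading matrix")
        groups = list(groups)
        if loadings.shape != (len(groups), K):
            raise ValueError(
                f"loading_spec shape {loadings.shape} != (G={len(groups)}, K={K})"
            )
    if not np.all(np.isfinite(loadings)):
        raise ValueError("loading_spec contains non-finite values")
    if not (1 <= K <= R):
        raise ValueError(f"need R >= K >= 1, got R={R}, K={K}")
    if global_scale is None:
        global_scale = np.ones(len(groups))

    rng = np.random.default_rng(seed)
    # Orthonormal spatial patterns: QR of a Gaussian matrix, signs fixed by
    # the largest-magnitude element so the atlas is reproducible.
    Q, _ = np.linalg.qr(rng.standard_normal((R, K)))
    for k in range(K):
        j = int(np.argmax(np.abs(Q[:, k])))
        if Q[j, k] < 0:
            Q[:, k] = -Q[:, k]
    distinct = rng.standard_normal((R, len(groups))) * float(distinct_sd)
    if isinstance(loading_spec, str) and loading_spec == "paper8":
        # the twofold-ratio locus is generated as an exact -1/2 scaled copy
        # of its deletion (private component included), so its planted
        # deletion/duplication d-map SD ratio is exactly 2 per realization
        i_del = groups.index(f"{PAPER8_RATIO_LOCUS}_del")
        i_dup = groups.index(f"{PAPER8_RATIO_LOCUS}_dup")
        distinct[:, i_dup] = -0.5 * distinct[:, i_del]
    return EffectAtlas(
        groups=groups,
        latent_patterns=Q,
        cnv_loadings=loadings,
        distinct_patterns=distinct,
        global_scale=global_scale,
        mirror=mirror,
    )


@dataclass
class CovariateModel:
    """Nuisance structure of the simulated cohorts.

    Ages are drawn per ascertainment arm; the biobank arm is offset by
    roughly 30 years, reproducing the confound handled in real data with
    ascertainment-matched controls.  Site acts as an additive per-ROI
    offset drawn once per site.  Per-ROI age/age^2/sex coefficients are
    drawn from zero-mean normals with the SDs below (units: residual SD
    per year, per year^2, and per sex level).
    """

    age_mean: Mapping[str, float] = field(
        default_factory=lambda: {"clinical": 26.0, "nonclinical": 62.0}
    )
    age_sd: Mapping[str, float] = field(
        default_factory=lambda: {"clinical": 14.0, "nonclinical": 7.4}
    )
    sex_ratio: float = 0.5
    site_sd: float = 0.3
    age_coef_sd: float = 0.01
    age2_coef_sd: float = 2e-4
    sex_coef_sd: float = 0.2
    residual_sd: float = 1.0
    tiv_mean: float = 1.46  # litres
    tiv_sd: float = 0.15
    gm_ratio: float = 0.6  # total grey matter as a fraction of TIV
    gm_coupling_sd: float = 2.0  # per-ROI global coupling, residual SD per litre GM
    latent_subject_sd: float = 0.0  # per-subject latent expression SD

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")


def paper8_covariates(latent_subject_sd: float = 0.0) -> CovariateModel:
    return CovariateModel(latent_subject_sd=latent_subject_sd)


def _dosage_row(group: str, loci: Sequence[str]) -> np.ndarray:
    locus, copy = parse_group(group)
    x = np.zeros(len(loci))
    if copy != "none":
        x[list(loci).index(locus)] = -1.0 if copy == "del" else 1.0
    return x


def population_canonical_correlations(
    atlas: EffectAtlas,
    group_sizes: Mapping[str, int],
    latent_subject_sd: float,
    noise_sd: float = 1.0,
    loci: Sequence[str] = LOCI,
) -> np.ndarray:
    """Exact canonical correlations between the gene-dosage design and the
    residualized ROI values implied by the generative model.

    Treats covariates, site and global scaling as perfectly removed, so Y
    reduces to the planted group map plus per-subject latent expression
    noise plus iid regional noise.  Used to calibrate
    ``latent_subject_sd`` for a target dosage-brain coupling.
    """
    groups = [g for g in atlas.groups if group_sizes.get(g, 0) > 0]
    n = np.array([group_sizes[g] for g in groups], dtype=float)
    pi = n / n.sum()
    X = np.stack([_dosage_row(g, loci) for g in groups])  # (G, L)
    M = np.stack([atlas.group_map(g) for g in groups])  # (G, R)
    xbar = pi @ X
    mbar = pi @ M
    Sxx = (X * pi[:, None]).T @ X - np.outer(xbar, xbar)
    Sxy = (X * pi[:, None]).T @ M - np.outer(xbar, mbar)
    P = atlas.latent_patterns
    Syy = (
        (M * pi[:, None]).T @ M
        - np.outer(mbar, mbar)
        + latent_subject_sd**2 * P @ P.T
        + noise_sd**2 * np.eye(atlas.n_roi)
    )
    keep = np.abs(np.diag(Sxx)) > 1e-12
    Sxx = Sxx[np.ix_(keep, keep)]
    Sxy = Sxy[keep]
    A = linalg.solve(Sxx, Sxy, assume_a="pos")
    B = linalg.solve(Syy, Sxy.T, assume_a="pos")
    eigvals = np.sort(np.linalg.eigvals(A @ B).real)[::-1]
    return np.sqrt(np.clip(eigvals, 0.0, 1.0))


def calibrate_latent_subject_sd(
    atlas: EffectAtlas,
    group_sizes: Mapping[str, int],
    target_rho: float = 0.8,
    noise_sd: float = 1.0,
) -> float:
    """Solve for the per-subject latent SD that sets the population first
    canonical correlation between gene dosage and brain residuals."""
    def f(tau: float) -> float:
        return (
            population_canonical_correlations(atlas, group_sizes, tau, noise_sd)[0]
            - target_rho
        )

    lo, hi = 0.0, 1.0
    if f(lo) < 0:
        raise ValueError(
            f"target coupling {target_rho} exceeds the noiseless maximum "
            f"{f(lo) + target_rho:.3f} for this atlas"
        )
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("latent SD calibration did not bracket the target")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def simulate_cohort(
    atlas: EffectAtlas,
    cov: CovariateModel,
    group_sizes: Mapping[str, int],
    n_controls: int | Mapping[str, int],
    n_sites: int = 5,
    seed: int = 0,
    ascertainment: Mapping[str, str] | None = None,
) -> tuple[CohortTable, dict]:
    """Simulate a per-subject ROI cohort with planted effects.

    The ROI value of subject *i* at region *r* is::

        baseline_r + b_age,r*(age-c) + b_age2,r*(age-c)^2 + b_sex,r*sex
        + site_offset(site_i, r) + g_r*(GM_i - GM_ref)
        + residual_sd * (effect_r(group_i) + latent_subject_term + noise)

    where ``effect_r`` is the atlas group map (Cohen's d units) and noise
    is standard normal.  ``n_controls`` may be a single count or a mapping
    ascertainment arm -> count; carriers default to the clinical arm
    unless ``ascertainment`` assigns them elsewhere.  Identical seed and
    arguments reproduce the table bit-for-bit.

    Returns the cohort plus a truth record of every planted quantity.
    """
    for g, n in group_sizes.items():
        if g not in atlas.groups:
            raise KeyError(f"group {g!r} absent from the effect atlas")
        if n < 0:
            raise ValueError(f"group size for {g!r} must be >= 0")
        if n == 0:
            warnings.warn(f"group {g!r} requested with size 0", UserWarning)
    if ascertainment is None:
        ascertainment = {g: "clinical" for g in group_sizes}
    if isinstance(n_controls, int):
        n_controls = {"clinical": n_controls}
    arms = sorted(set(ascertainment.values()) | set(n_controls.keys()))
    if cov.site_sd > 0 and n_sites < 2 and "clinical" in arms:
        raise ValueError("need at least 2 sites when site_sd > 0")

    rng = np.random.default_rng(seed)
    R = atlas.n_roi
    roi_ids = [f"{i:03d}" for i in range(R)]
    baseline = rng.normal(10.0, 2.0, size=R)
    b_age = rng.normal(0.0, cov.age_coef_sd, size=R)
    b_age2 = rng.normal(0.0, cov.age2_coef_sd, size=R)
    b_sex = rng.normal(0.0, cov.sex_coef_sd, size=R)
    g_gm = rng.normal(0.0, cov.gm_coupling_sd, size=R)
    gm_ref = cov.gm_ratio * cov.tiv_mean
    sites = {"clinical": [f"S{i + 1}" for i in range(n_sites)], "nonclinical": ["UKBB"]}
    all_sites = sorted({s for arm in arms for s in sites.get(arm, ["S1"])})
    site_offsets = {s: rng.normal(0.0, cov.site_sd, size=R) for s in all_sites}
    age_center = float(np.mean([cov.age_mean[a] for a in arms]))
    resid = np.atleast_1d(np.asarray(cov.residual_sd, dtype=float))
    resid = np.broadcast_to(resid, (R,))

    rows: list[dict] = []
    roi_rows: list[np.ndarray] = []
    sid = 0

    def emit(group: str, arm: str, n: int) -> None:
        nonlocal sid
        effect = (
            atlas.group_map(group) if group != CONTROL_GROUP else np.zeros(R)
        )
        scale = (
            atlas.global_scale[atlas.groups.index(group)]
            if group != CONTROL_GROUP
            else 1.0
        )
        arm_sites = sites.get(arm, ["S1"])
        for _ in range(n):
            age = float(np.clip(rng.normal(cov.age_mean[arm], cov.age_sd[arm]), 5, 95))
            sex = int(rng.random() < cov.sex_ratio)
            site = arm_sites[int(rng.integers(len(arm_sites)))]
            tiv = float(rng.normal(cov.tiv_mean * scale, cov.tiv_sd))
            gm = float(cov.gm_ratio * tiv + rng.normal(0.0, 0.03))
            eta = rng.normal(0.0, cov.latent_subject_sd, size=atlas.n_latent)
            da = age - age_center
            values = (
                baseline
                + b_age * da
                + b_age2 * da**2
                + b_sex * sex
                + site_offsets[site]
                + g_gm * (gm - gm_ref)
                + resid
                * (effect + atlas.latent_patterns @ eta + rng.standard_normal(R))
            )
            rows.append(
                {
                    "subject_id": f"sub{sid:05d}",
                    "group": group,
                    "ascertainment": arm,
                    "site": site,
                    "age": age,
                    "sex": sex,
                    "TIV": tiv,
                    "total_GM": gm,
                }
            )
            roi_rows.append(values)
            sid += 1

    for group in atlas.groups:
        n = group_sizes.get(group, 0)
        if n > 0:
            emit(group, ascertainment.get(group, "clinical"), n)
    for arm in arms:
        n = n_controls.get(arm, 0)
        if n > 0:
            emit(CONTROL_GROUP, arm, n)

    df = pd.DataFrame(rows)
    roi_df = pd.DataFrame(
        np.array(roi_rows), columns=[f"roi_{rid}" for rid in roi_ids]
    )
    table = CohortTable(pd.concat([df, roi_df], axis=1))

    loci_present = sorted(
        {parse_group(g)[0] for g in atlas.groups if g != CONTROL_GROUP},
        key=lambda x: list(LOCI).index(x) if x in LOCI else 99,
    )
    # True population Cohen's d: the planted mean shift divided by the
    # within-group SD, which per-subject latent expression variability
    # inflates ROI-dependently above the unit base noise.
    inflation = np.sqrt(
        1.0 + cov.latent_subject_sd**2 * np.sum(atlas.latent_patterns**2, axis=1)
    )
    d_maps = {g: atlas.group_map(g) / inflation for g in atlas.groups}

    def _d_ratio(locus: str) -> float:
        return float(
            np.std(d_maps[f"{locus}_del"], ddof=1)
            / np.std(d_maps[f"{locus}_dup"], ddof=1)
        )

    truth = {
        "seed": int(seed),
        "roi_ids": roi_ids,
        "groups": list(atlas.groups),
        "group_sizes": {g: int(group_sizes.get(g, 0)) for g in atlas.groups},
        "n_controls": {a: int(n_controls.get(a, 0)) for a in arms},
        "group_maps": {g: atlas.group_map(g).tolist() for g in atlas.groups},
        "group_d_maps": {g: m.tolist() for g, m in d_maps.items()},
        "variance_inflation": inflation.tolist(),
        "cnv_loadings": atlas.cnv_loadings.tolist(),
        "latent_patterns": atlas.latent_patterns.tolist(),
        "global_scale": atlas.global_scale.tolist(),
        "latent_subject_sd": float(cov.latent_subject_sd),
        "residual_sd": resid.tolist(),
        "baseline": baseline.tolist(),
        "coef_age": b_age.tolist(),
        "coef_age2": b_age2.tolist(),
        "coef_sex": b_sex.tolist(),
        "gm_coupling": g_gm.tolist(),
        "site_offsets": {s: o.tolist() for s, o in site_offsets.items()},
        "age_center": age_center,
        "sd_ratio_by_locus": {
            locus: _d_ratio(locus)
            for locus in loci_present
            if f"{locus}_del" in atlas.groups and f"{locus}_dup" in atlas.groups
        },
    }
    return table, truth


# ---------------------------------------------------------------------------
# Spherical ROI geometry


def make_roi_sphere(
    R: int, hemispheres: bool = True, seed: int = 0, min_angle_deg: float = 1.0
) -> RoiAtlas:
    """ROI centroids approximately uniform on the unit sphere.

    With ``hemispheres=True`` the regions are split evenly between left
    and right, each hemisphere on its own unit sphere (as in surface-based
    spherical registration); an odd leftover region is labelled midline
    with an arbitrary unit centroid.  Points closer than ``min_angle_deg``
    to an already placed point of the same hemisphere are redrawn, so
    nearest-neighbour separation is bounded away from zero.  Deterministic
    under ``seed``.
    """
    if R < 2:
        raise ValueError("need at least 2 ROIs")
    rng = np.random.default_rng(seed)
    cos_min = np.cos(np.deg2rad(min_angle_deg))

    def draw(n: int) -> np.ndarray:
        pts: list[np.ndarray] = []
        while len(pts) < n:
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            if all(float(v @ p) < cos_min for p in pts):
                pts.append(v)
        return np.array(pts)

    if hemispheres:
        n_left = R // 2
        n_right = R // 2
        n_mid = R - n_left - n_right
        centroids = np.vstack(
            [draw(n_left), draw(n_right)]
            + ([np.array([[0.0, 0.0, 1.0]])] * n_mid)
        )
        hemis = ["L"] * n_left + ["R"] * n_right + ["midline"] * n_mid
    else:
        centroids = draw(R)
        hemis = ["L"] * R
    roi_ids = [f"{i:03d}" for i in range(R)]
    return RoiAtlas(roi_ids=roi_ids, hemisphere=hemis, centroids=centroids)


def smooth_sphere_map(
    atlas: RoiAtlas, length_scale_deg: float = 30.0, seed: int = 0
) -> np.ndarray:
    """Sample a spatially smooth map over the atlas (Gaussian-process
    draw with a squared-exponential kernel in geodesic angle, independent
    per hemisphere).  Useful for exercising spin-permutation nulls with
    realistic spatial autocorrelation."""
    rng = np.random.default_rng(seed)
    values = np.zeros(atlas.n_roi)
    hemi = np.asarray(atlas.hemisphere)
    ell = np.deg2rad(length_scale_deg)
    for h in ("L", "R", "midline"):
        idx = np.flatnonzero(hemi == h)
        if len(idx) == 0:
            continue
        C = atlas.centroids[idx]
        ang = np.arccos(np.clip(C @ C.T, -1.0, 1.0))
        K = np.exp(-(ang**2) / (2 * ell**2))
        # eigenvalue clipping: the kernel loses numerical positive
        # definiteness for long length scales
        w, V = np.linalg.eigh(K)
        Lc = V * np.sqrt(np.clip(w, 1e-10, None))
        values[idx] = Lc @ rng.standard_normal(len(idx))
    return values
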