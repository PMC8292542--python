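"""Ranked-map tail overlap across CNVs and deletion-duplication mirror tests.

Effect maps from different CNV contrasts have very unequal statistical
power, so raw Cohen's d values are not compared directly: each map is
converted to fractional midranks, the rank distribution is thresholded at
its 15th and 85th quantiles, and spatial convergence is summarized as the
per-ROI count of maps whose extreme tail contains that ROI.  Overlap
between two binary masks is scored with the Dice index.

Mirror statistics for a locus compare the deletion and duplication maps:
their Pearson correlation over ROIs (anticorrelation = mirror effect, with
a spin-permutation p value) and the ratio of their d-value SDs (an F
statistic on ROI units, reported with an explicit caveat: ROIs are
spatially correlated, so the nominal degrees of freedom are
anticonservative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from cnvmorph.data_model import EffectMap, ValidationError


def rank_map(emap: EffectMap | np.ndarray) -> np.ndarray:
    """Fractional midranks of the per-ROI d values, in (0, 1).

    ``(rank - 0.5) / R`` with average ranks for ties: a strictly
    increasing map of length 5 ranks as (0.1, 0.3, 0.5, 0.7, 0.9); a
    constant map ranks 0.5 everywhere.  Invariant under strictly monotone
    transforms of d.
    """
    d = emap.d if isinstance(emap, EffectMap) else np.asarray(emap, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValidationError("rank_map requires finite d values")
    return (stats.rankdata(d, method="average") - 0.5) / len(d)


@dataclass
class TailMask:
    """Membership of ROIs in one extreme tail of a ranked effect map."""

    contrast_id: str
    tail: str  # {"low", "high"}
    quantile: float
    members: np.ndarray  # boolean, length R

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=bool)
        if self.tail not in ("low", "high"):
            raise ValueError(f"tail must be 'low' or 'high', got {self.tail!r}")

    @property
    def size(self) -> int:
        return int(self.members.sum())


def tail_mask(
    emap: EffectMap | np.ndarray,
    q_low: float = 0.15,
    q_high: float = 0.85,
    contrast_id: str | None = None,
) -> tuple[TailMask, TailMask]:
    """Low/high tail masks of a map's fractional-rank distribution.

    Membership is closed at the quantile (rank <= q_low, rank >= q_high),
    which makes counts deterministic under ties.  A constant map yields
    two empty masks and a warning.  Accepts an effect map or a plain
    vector of d values.
    """
    if not (0.0 <= q_low < q_high <= 1.0):
        raise ValueError(f"need 0 <= q_low < q_high <= 1, got ({q_low}, {q_high})")
    if isinstance(emap, EffectMap):
        d = emap.d
        cid = contrast_id if contrast_id is not None else emap.contrast_id
    else:
        d = np.asarray(emap, dtype=float)
        cid = contrast_id or ""
    ranks = rank_map(d)
    low = ranks <= q_low
    high = ranks >= q_high
    if np.ptp(d) == 0:
        warnings.warn(
            f"constant effect map {cid!r}: tail masks are empty", UserWarning
        )
    return (
        TailMask(cid, "low", q_low, low),
        TailMask(cid, "high", q_high, high),
    )


@dataclass
class ConvergenceMap:
    """Per-ROI concordance counts across K tail masks of the same tail."""

    tail: str
    counts: np.ndarray  # int, in [0, K]
    n_maps: int
    contrast_ids: list[str] = field(default_factory=list)

    @property
    def all_k(self) -> np.ndarray:
        """ROIs in the tail of every map."""
        return self.counts == self.n_maps

    @property
    def any_k_minus_1(self) -> np.ndarray:
        """ROIs in the tail of at least K-1 maps."""
        return self.counts >= self.n_maps - 1


def convergence_map(masks: list[TailMask]) -> ConvergenceMap:
    """Count, per ROI, how many of the given tail masks contain it."""
    if not masks:
        raise ValueError("need at least one tail mask")
    tails = {m.tail for m in masks}
    if len(tails) > 1:
        raise ValueError(f"mixed tails {sorted(tails)}: convergence needs one tail")
    lengths = {len(m.members) for m in masks}
    if len(lengths) > 1:
        raise ValueError(f"tail masks differ in length: {sorted(lengths)}")
    counts = np.sum([m.members for m in masks], axis=0).astype(int)
    return ConvergenceMap(
        tail=masks[0].tail,
        counts=counts,
        n_maps=len(masks),
        contrast_ids=[m.contrast_id for m in masks],
    )


def dice(a: TailMask | np.ndarray, b: TailMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary masks.

    Defined as 0.0 (with a warning) when both masks are empty.
    """
    av = a.members if isinstance(a, TailMask) else np.asarray(a, dtype=bool)
    bv = b.members if isinstance(b, TailMask) else np.asarray(b, dtype=bool)
    if av.shape != bv.shape:
        raise ValueError(f"mask length mismatch: {av.shape} vs {bv.shape}")
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks defined as 0", UserWarning)
        return 0.0
    return 2.0 * int(np.sum(av & bv)) / denom


def adjusted_map_sd(emap: EffectMap) -> float:
    """SD of a map's d values with its estimation variance subtracted.

    The observed variance of estimated d over ROIs is the true d-profile
    variance plus sampling variance; subtracting the design-implied
    sampling variance (``d_var_scale`` when recorded, else the two-sample
    approximation) gives a nearly unbiased profile SD.  Floored at
    ``sqrt(0.05 * observed variance)`` so a pure-noise map stays positive.
    """
    var = float(np.var(emap.d, ddof=1))
    if emap.d_var_scale is not None:
        noise = float(emap.d_var_scale)
    else:
        noise = (1.0 / emap.n_case + 1.0 / emap.n_control) * (
            emap.df / (emap.df - 2) if emap.df > 2 else 1.0
        )
    return float(np.sqrt(max(var - noise, 0.05 * var)))


@dataclass
class MirrorStats:
    """Deletion-versus-duplication mirror summary for one locus."""

    locus: str
    pearson_r: float
    spin_p: float | None
    sd_ratio: float  # SD(deletion d) / SD(duplication d) over ROIs
    sd_ratio_adjusted: float  # same, after subtracting estimation variance
    f_stat: float
    f_p: float
    n_roi: int
    note: str = (
        "F-test degrees of freedom treat ROIs as independent units; spatial "
        "correlation makes the parametric p anticonservative. Prefer spin_p "
        "for the anticorrelation test."
    )


def mirror_stats(
    del_map: EffectMap,
    dup_map: EffectMap,
    spin: "object | None" = None,
    n_spin_drop_warn: bool = True,
) -> MirrorStats:
    """Mirror-effect statistics between a deletion and a duplication map.

    Pearson r of the two d maps over ROIs; a one-sided spin p value for
    anticorrelation when a spin ensemble is supplied; the ratio of d-map
    SDs with a two-sided F test on (R-1, R-1) df.  ``sd_ratio_adjusted``
    subtracts each map's approximate estimation variance
    ``(1/n1 + 1/n2) * df/(df-2)`` from the observed d variance before
    taking the ratio, removing the upward noise inflation of the raw SDs
    (the raw ratio mirrors the published procedure and feeds the F test).
    """

    if del_map.roi_ids != dup_map.roi_ids:
        raise ValidationError("deletion and duplication maps must share ROI order")
    x, y = del_map.d, dup_map.d
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("mirror_stats undefined for a zero-variance map")
    r = float(stats.pearsonr(x, y).statistic)
    spin_p = None
    if spin is not None:
        from cnvmorph.nulls import spin_pvalue  # deferred: nulls imports dice

        spin_p = float(
            spin_pvalue("pearson_r", x, y, spin, alternative="less").p
        )
    sd_del = float(np.std(x, ddof=1))
    sd_dup = float(np.std(y, ddof=1))
    ratio = sd_del / sd_dup
    F = ratio**2
    R = len(x)
    f_p = float(2.0 * min(stats.f.sf(F, R - 1, R - 1), stats.f.cdf(F, R - 1, R - 1)))
    locus = del_map.contrast_id.rpartition("_")[0] or del_map.contrast_id
    return MirrorStats(
        locus=locus,
        pearson_r=r,
        spin_p=spin_p,
        sd_ratio=ratio,
        sd_ratio_adjusted=adjusted_map_sd(del_map) / adjusted_map_sd(dup_map),
        f_stat=F,
        f_p=min(f_p, 1.0),
        n_roi=R,
    )
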