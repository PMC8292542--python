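# Methods

This note documents the statistical models implemented in `cnvmorph`, the
design of the synthetic-cohort generator, the numerical conventions, and
the limitations a user should know before applying the package to real
data.

## Data model

A cohort is a flat table: subject id, genotype group (locus × copy state,
or control), ascertainment arm (clinical / non-clinical), scanning site,
age (years), sex (0/1, reference level 0), total intracranial volume and
total grey matter (litres), then one column per ROI. ROI column order is
fixed and shared with the ROI atlas (name, hemisphere, unit-sphere
centroid) and with every derived effect map. Missing covariate values are
a hard error: quality control happens upstream by exclusion, never by
imputation. One table carries one morphometry metric; volume and
surface-based metrics are parallel analyses, not mixed columns.

## Contrast models

**Global metrics.** TIV or total grey matter is adjusted for age, age²
and sex as fixed effects with scanning site as a random intercept
(statsmodels `MixedLM`, REML), fitted on controls only and applied to all
subjects; z-scores standardize by the control residual mean/SD, so the
control distribution is exactly N(0, 1)-normalized by construction. With
a single site, or when the site-variance estimate hits the zero boundary
(where `MixedLM` becomes unreliable), the model falls back to
fixed-effects OLS with a warning.

**Regional effect maps.** Per ROI, the fixed-effects GLM
`value ~ group + sex + age + age² + total GM (+ site dummies)` is fitted
by least squares, vectorized over ROIs. Age is centered before expansion
for conditioning. Site enters as fixed dummies here (the mass-univariate
convention) while the global model uses a random intercept. The map
stores the group-coefficient t statistic, the residual degrees of
freedom, and Cohen's d computed as the **adjusted standardized mean
difference** d = β̂_group / σ̂ (residual SD). When covariates are orthogonal
to the group factor this equals the familiar conversion
t·√(1/n₁ + 1/n₂), and with no covariates it is exactly pooled-SD Cohen's
d; when a covariate is group-shifted (total grey matter typically is),
the t-based conversion is attenuated by √(1−R²_group~covariates) while
the direct form stays unbiased, which is why the direct form is used.
Each map also records the design-implied sampling variance of d,
(XᵀX)⁻¹[g,g]·df/(df−2), used downstream for noise-corrected profile SDs.

**Multiplicity.** Uncorrected, Bonferroni, and Benjamini–Hochberg FDR
masks via statsmodels; family-wise control at ROI scale is offered as a
maxT permutation test (case/control labels permuted, GLM refitted, each
observed |t| compared with the permutation distribution of the maximum
|t| over ROIs). Random-field-theory FWE is out of scope at parcel
resolution and maxT is the labeled substitute.

## Convergence and mirror statistics

CNV contrasts differ strongly in power, so maps are compared on
**fractional midranks** (rank − ½)/R (average ranks at ties), not raw d.
Tail masks take ranks ≤ 0.15 ("low") and ≥ 0.85 ("high"); membership is
closed at the quantile so counts are deterministic under ties; a constant
map yields empty masks and a warning. Convergence across K maps is the
per-ROI count of tails containing it, with the all-K and any-(K−1)
subsets derived. Mask overlap uses the Dice index 2|A∩B|/(|A|+|B|),
defined as 0 with a warning when both masks are empty.

Mirror statistics per locus: Pearson r between deletion and duplication d
maps over ROIs (one-sided spin p for anticorrelation), and the ratio of
d-profile SDs. Two SD ratios are reported: the raw ratio (which feeds the
F statistic with (R−1, R−1) degrees of freedom, reproducing the
published-style procedure) and a noise-adjusted ratio in which each map's
design-implied sampling variance is subtracted from its observed d
variance first — raw profile SDs are inflated by estimation noise, and
the inflation is proportionally larger for the weaker map, biasing the
raw ratio toward 1. The F test treats ROIs as independent units; spatial
correlation makes its nominal df anticonservative, so the spin p is the
test to trust for anticorrelation.

## Empirical nulls

**Spin permutations.** ROI centroids live on a unit sphere per
hemisphere. Each spin draws one Haar-uniform rotation (sign-fixed QR of a
Gaussian matrix), applies it to the left hemisphere and its mirror image
(diag(−1,1,1) conjugation) to the right, then solves a one-to-one
nearest-centroid linear-sum assignment between original and rotated
positions within each hemisphere. The assignment is bijective, so a spun
map keeps its exact value multiset and any mask keeps its cardinality —
a requirement for Dice denominators at ROI resolution. Midline ROIs
without a spherical embedding are held fixed. The spin p spins map A,
holds map B fixed, recomputes the statistic per rotation, and drops (and
counts) rotations on which the statistic is undefined.

**Label shuffling.** Genotype labels are permuted within strata (site by
default, which also preserves ascertainment-arm composition because arms
do not share sites), and the *entire* downstream chain — contrasts, tail
masks, convergence statistic — is recomputed per permutation.

**Empirical p convention.** p = (1 + #{null at least as extreme}) /
(1 + n_perm) throughout: the standard bias-free estimator with a floor of
1/(n_perm+1); p can never be 0. Two-sided alternatives compare absolute
values.

## Latent dimensions

**PCA.** The d matrix is R×G with ROIs as observations and CNV contrasts
as variables (columns sorted by contrast id; z-scoring per column
optional and on by default, matching the convention of standardizing
contrasts of unequal power). The decomposition is the SVD of the
column-centered matrix; "variance explained" is the share of cross-CNV
d-profile variance, and the shares over all min(R−1, G) components sum to
100%. Component signs are fixed by forcing the largest-magnitude CNV
loading positive, making results bit-reproducible. Per-CNV R² is the OLS
of each column on the first two ROI-score columns, in percent.

**Gene-dosage CCA.** Carriers only; X codes deletion = −1, duplication =
+1 at the subject's locus (dosage magnitude ±1 — any locus-wise rescaling
leaves CCA invariant); Y is the ROI matrix residualized on total GM, age,
age², sex and site, with coefficients stored so held-out controls are
residualized identically (unseen sites fall to the reference level). The
fit whitens both centered blocks by QR and takes the SVD of the whitened
cross-covariance; canonical variates are scaled to unit sample variance
and successive variates are uncorrelated by construction. ROI-side
loadings are reported as structure correlations. When Y is rank-deficient
or nearly square in subjects, an optional PCA basis of Y retaining ≥ 90%
variance is available (`y_reduce="pca90"`); the eight-CNV pipeline uses
it by default because at 448 subjects × 130 ROIs the full-rank in-sample
first canonical correlation overshoots its population value by ≈ +0.05
(verified by simulation at 10× the sample size, where the estimate
converges to the population value), while the reduced fit recovers it
within ±0.03. Dimension significance is the add-one permutation p from
jointly permuting the rows of X. Controls are projected post hoc:
control_scores = (Y_controls − training mean) · y-weights.

## Synthetic cohorts

The generator plants effects on the residual-SD scale, so planted values
are directly Cohen's d units.

For subject *i* and region *r*:

    value = baseline_r + b_age,r·(age−c) + b_age2,r·(age−c)² + b_sex,r·sex
            + site_offset(site_i, r) + g_r·(GM_i − GM_ref)
            + σ_r·( effect_r(group_i) + Σ_k P_rk·η_ik + ε_ir )

with ε iid N(0,1), per-ROI covariate coefficients drawn once from
zero-mean normals, additive per-site per-ROI offsets (SD 0.3), a per-ROI
global coupling g to total grey matter, and group TIV factors that shift
TIV (and hence GM) multiplicatively. Ages are drawn per ascertainment arm
(clinical mean 26 y, biobank mean 62 y — the ~30-year offset that real
matched-control designs address). The clinical arm spans five sites, the
biobank arm one.

**Effect atlas.** Group maps are `P·ℓ_g + distinct_g`: K orthonormal
spatial patterns P (QR of a Gaussian matrix, signs fixed), signed
loadings ℓ per group, and per-group private patterns (iid, SD
`distinct_sd`). With `distinct_sd = 0` the group-map matrix has rank
exactly K. The mirror invariant requires deletion and duplication
loadings of a locus to oppose in sign on the locus's dominant dimension.

**The eight-CNV preset** ("paper8") has 8 groups at 4 loci, K = 2,
group sizes 29/19 (1q21.1), 83/73 (16p11.2), 74/22 (22q11.2) in the
clinical arm with 331 controls and 72/76 (15q11.2) in the biobank arm
with 965 controls, and group TIV factors read off the corresponding
demographics (e.g. 1q21.1 deletions ~0.84× control TIV, duplications
~1.08×). Deletion loading directions cluster around the first latent
axis (so all four deletions share a convergent extreme set, echoing the
finding that deletions converge on a common set of regions), duplications
load oppositely on that axis while carrying most of the second axis'
mass, and the loading matrix is linearly renormalized so the eigenvalues
of its Gram are exactly 60%/40% of the total — the quantity a PCA of the
noiseless maps recovers as its first two variance shares. 16p11.2
duplications are generated as the exact −½ copy of the deletion map
(shared and private parts), so the planted deletion/duplication d-SD
ratio is exactly 2 in every realization; the other loci sit near ratio 1,
a deliberate simplification — only the twofold locus is pinned.
`distinct_sd = 0.2` adds CNV-private structure (~10% of map variance).

**Dosage–brain coupling.** The per-subject latent expression term
Σ_k P_rk η_ik (η iid N(0, τ²)) is what makes the population canonical
correlation between gene dosage and brain residuals a tunable quantity:
without it the preset's coupling would be ≈ 0.94. τ is calibrated by
root-finding on the closed-form population CCA of the generative model
(group-mean structure + τ²PPᵀ + unit noise, covariates treated as
removed) so that the first canonical correlation equals the requested
coupling (0.8 by default); the preset's calibrated τ is ≈ 4–5. Because
this term inflates the within-group SD ROI-dependently by
√(1 + τ²Σ_k P²_rk), the truth record stores both the raw mean-shift maps
and the **true population Cohen's d maps** (shift divided by that
factor); all recovery comparisons use the latter.

**Spherical ROI atlases** place centroids approximately uniformly on a
unit sphere per hemisphere (rejection sampling keeps every pair ≥ 1°
apart); an odd leftover region becomes midline. A Gaussian-process
sampler (squared-exponential kernel in geodesic angle, eigenvalue-clipped
for long length scales) provides spatially smooth maps for exercising the
spin machinery.

## The replicated recovery study

Single-cohort recovery statistics carry irreducible sampling jitter. The
dominant term is the sampled group mean of the latent expression η, which
rescales each estimated map by roughly ±τ/(√n_g·‖ℓ_g‖) — about ±12% for
the smaller groups — so, for example, a single-cohort estimate of the
16p11.2 SD ratio has ~±14% noise. Recovery is therefore assessed on
replicate averages: 48 independent cohort replicates supply map-level
metrics (d-map recovery correlations, the noise-adjusted SD ratio
aggregated as the ratio of replicate-mean SDs, which avoids the ≈ +4%
convexity bias of averaging per-replicate ratios; mirror r; convergence
recovery; PCA split and locus-wise loading opposition), and the
permutation-based p values (shuffle convergence p at 199 permutations,
CCA dimension p at 199 permutations) are computed on the first 4
replicates. Monte Carlo standard errors of the averages are ≲ a third of
the tolerances of interest (e.g. ~3% on the SD ratio, ~0.4 points on the
variance split).

Two measurement conventions deserve note. *Planted shared-extreme ROIs*
(the recovery target of the deletion-convergence analysis) are defined as
the all-4 intersection of the planted deletion d maps at a deeper
quantile (0.10/0.90) than the estimated masks (0.15/0.85):
threshold-marginal planted ROIs flip tails under estimation noise and are
not a meaningful recovery target. *Loading opposition* is assessed
rotation-invariantly — the deletion and duplication loading vectors on
the PC1–PC2 plane must have negative inner product — because the fitted
principal axes are arbitrarily rotated relative to the generating axes
when the eigengap is moderate (60:40), making per-axis sign comparison
ill-posed; ~95% of replicates show exact opposition at all four loci.

## Null-calibration experiments

Four experiments, rerun by the acceptance script and test suite:
per-ROI GLM p values under a global null (2000 ROIs, KS uniformity); spin
p for the correlation of two independent exchangeable maps over 200
replicate experiments, each with a fresh 60-ROI atlas and 499-spin
ensemble (KS uniformity); type-I error of the label-shuffle
convergence-size test at nominal α = 0.05 over 100 null cohorts × 99
permutations (measured 0.02–0.06); and CCA permutation p under
independent blocks over 100 replicates (KS uniformity). Two conventions
make the KS checks exact: add-one permutation p values are discrete
uniform on k/(n_perm+1) under validity (mean 0.5 + 0.5/(n_perm+1)), so a
randomized probability-integral transform maps them to continuous
uniform before testing; and the shuffle experiment uses a two-map
convergence statistic on a 250-ROI atlas, because with four independent
null maps the all-4 set is almost surely empty, making the discrete test
unmeasurably conservative rather than informatively calibrated.

## Numerical conventions

- PCA/CCA signs fixed by forcing the largest-magnitude loading (CNV-side
  for PCA, ROI-side weight for CCA) positive.
- Ties in ranking get average ranks; tail membership is closed at the
  quantile.
- Effect-map round trips are exact to ≤ 1e-12 (`%.17g` TSV columns plus a
  JSON sidecar for metadata).
- Seeds: every stochastic routine takes an explicit seed; derived seeds
  come from `numpy.random.SeedSequence` spawning, reduced mod 2³¹.
- Degenerate inputs fail loudly: constant maps (empty tails + warning),
  empty mask pairs (Dice 0 + warning), single-site cohorts (OLS fallback
  + warning), case groups with n < 3 (error), K > R (error), empty filter
  results (warning).

## What the synthetic data does and does not show

The generator reproduces the *statistical design* of a pooled multi-site
CNV study — group sizes, ascertainment age structure, site offsets,
global scaling, shared-plus-private regional effect structure — so
passing recovery tests shows the pipeline estimates what was planted
under that design. It does not emulate spatial autocorrelation of real
effect maps (latent patterns are spatially white over the synthetic
sphere), scanner/protocol batch structure beyond additive site offsets,
family relatedness among intra-familial controls, non-Gaussian residuals,
or QC-driven selection. Conclusions about real-data effect sizes cannot
be read off these simulations.

## Known limitations

- **Parcel-level spins are anticonservative for strongly smooth maps.**
  With Gaussian-process maps whose correlation length is comparable to
  parcel spacing, the bijective reassignment attenuates the spun maps'
  autocorrelation and the spin test rejects ~7–8% at nominal 5% (measured
  at 60–150 parcels). On exchangeable maps the test is exact. This is a
  property of parcel-resolution spin tests generally; treat borderline
  spin p values near threshold with caution.
- **The mirror F test** treats ROIs as independent; its parametric p is
  anticonservative under spatial dependence and is reported with that
  caveat.
- **In-sample CCA correlations** are optimistically biased when the
  subjects-to-variables ratio is small; the pipeline's default PCA
  reduction mitigates but does not remove this, and no cross-validated
  out-of-sample estimate is provided.
- **Discrete convergence statistics** make the shuffle test conservative
  (rejection below nominal), increasingly so as the all-K set's null
  distribution degenerates toward zero.
- Family structure is recorded (optional `family_id`) but no kinship
  correction is implemented.
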