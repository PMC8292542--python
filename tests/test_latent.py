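import numpy as np
import pytest
from scipy import linalg

from cnvmorph.data_model import CohortTable, ValidationError, filter_cohort
from cnvmorph.latent import (
    build_dmatrix,
    cca_gene_morph,
    compare_loadings,
    gene_dosage_design,
    pca_latent,
    project_controls,
    r2_per_cnv,
    residualize_rois,
)
from cnvmorph.synthetic import (
    CovariateModel,
    make_effect_atlas,
    simulate_cohort,
)
from conftest import make_cohort_frame
from test_convergence import _emap


def _maps_from_matrix(M, ids=None):
    ids = ids or [f"1q21.1_del{i}".replace("del0", "del").replace("del1", "dup")
                  for i in range(M.shape[1])]
    # build valid contrast ids
    loci = ["1q21.1", "16p11.2", "22q11.2", "15q11.2"]
    ids = []
    for i in range(M.shape[1]):
        ids.append(f"{loci[i // 2 % 4]}_{'del' if i % 2 == 0 else 'dup'}")
    return [_emap(M[:, j], cid=ids[j]) for j in range(M.shape[1])]


class TestDMatrix:
    def test_shape_and_ordering(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((130, 8))
        dm = build_dmatrix(_maps_from_matrix(M), zscore=True)
        assert dm.shape == (130, 8)
        assert dm.contrast_ids == sorted(dm.contrast_ids)

    def test_zscore_columns(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((50, 4)) * 3 + 1
        dm = build_dmatrix(_maps_from_matrix(M), zscore=True)
        assert np.all(np.abs(dm.matrix.mean(axis=0)) < 1e-12)
        np.testing.assert_allclose(dm.matrix.std(axis=0), 1.0, atol=1e-12)

    def test_duplicate_contrast_id_rejected(self):
        m = _emap(np.arange(5.0), cid="1q21.1_del")
        with pytest.raises(ValidationError, match="duplicate"):
            build_dmatrix([m, m])

    def test_constant_column_rejected_when_zscoring(self):
        a = _emap(np.arange(5.0), cid="1q21.1_del")
        b = _emap(np.zeros(5), cid="1q21.1_dup")
        with pytest.raises(ValidationError, match="constant"):
            build_dmatrix([a, b], zscore=True)

    def test_roi_order_mismatch_rejected(self):
        a = _emap(np.arange(5.0), cid="1q21.1_del")
        b = _emap(np.arange(5.0), cid="1q21.1_dup")
        b.roi_ids = list(reversed(b.roi_ids))
        with pytest.raises(ValidationError, match="ROI order"):
            build_dmatrix([a, b])


class TestPcaLatent:
    def test_rank_one_matrix_explains_everything_on_pc1(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(40)
        M = np.column_stack([c * base for c in (1.0, -2.0, 0.5, 3.0)])
        dm = build_dmatrix(_maps_from_matrix(M), zscore=False)
        decomp = pca_latent(dm, K=2)
        assert decomp.variance_explained[0] == pytest.approx(100.0, abs=1e-9)
        assert decomp.variance_explained[1] == pytest.approx(0.0, abs=1e-9)

    def test_variance_explained_sums_to_100(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((30, 6))
        dm = build_dmatrix(_maps_from_matrix(M), zscore=True)
        decomp = pca_latent(dm, K=3)
        assert decomp.variance_explained_all.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(decomp.variance_explained_all) <= 1e-12)

    def test_roi_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        M = rng.standard_normal((30, 6))
        decomp = pca_latent(build_dmatrix(_maps_from_matrix(M)), K=3)
        gram = decomp.roi_scores.T @ decomp.roi_scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_matches_sklearn_pca(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(5)
        M = rng.standard_normal((40, 6))
        dm = build_dmatrix(_maps_from_matrix(M), zscore=True)
        decomp = pca_latent(dm, K=3)
        sk = PCA(n_components=3).fit(dm.matrix)
        np.testing.assert_allclose(
            decomp.variance_explained,
            100 * sk.explained_variance_ratio_,
            atol=1e-9,
        )
        for k in range(3):
            dot = abs(decomp.cnv_loadings[:, k] @ sk.components_[k])
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_planted_split_and_loadings_recovered_exactly_without_noise(self):
        # two orthogonal latent patterns, 60/40 split, no private effects:
        # SVD must recover the split within ±3 points and the loading
        # directions with |Tucker congruence| > 0.95
        loadings = np.array(
            [[3.0, 0.0], [-3.0, 0.0], [1.5, 2.0], [-1.5, -2.0],
             [2.0, -1.0], [-2.0, 1.0], [0.5, 2.5], [-0.5, -2.5]]
        )
        gram = loadings.T @ loadings
        ev, V = np.linalg.eigh(gram)
        target = np.array([0.4, 0.6]) * ev.sum()  # ascending order
        T = V @ np.diag(np.sqrt(target / ev)) @ V.T
        loadings = loadings @ T
        groups = [f"{l}_{c}" for l in ("1q21.1", "16p11.2", "22q11.2", "15q11.2")
                  for c in ("del", "dup")]
        atlas = make_effect_atlas(
            R=200, groups=groups, K=2, loading_spec=loadings,
            distinct_sd=0.0, mirror=False, seed=6,
        )
        maps = [_emap(atlas.group_map(g), cid=g) for g in groups]
        decomp = pca_latent(build_dmatrix(maps, zscore=False), K=2)
        ve = decomp.variance_explained
        split = 100 * ve[0] / (ve[0] + ve[1])
        assert split == pytest.approx(60.0, abs=3.0)
        # congruence of recovered loading directions with planted ones
        planted_axes = np.linalg.svd(loadings, full_matrices=False)[2]
        for k in range(2):
            rec = decomp.cnv_loadings[:, k]
            idx = [groups.index(c) for c in decomp.contrast_ids]
            congr = abs(
                rec @ loadings[idx] @ planted_axes[k]
                / np.linalg.norm(rec @ np.eye(2) if False else rec)
                / np.linalg.norm(loadings[idx] @ planted_axes[k])
            )
            assert congr > 0.95

    def test_opposite_generating_loadings_recover_opposite_signs(self):
        atlas = make_effect_atlas(
            R=150,
            groups=["16p11.2_del", "16p11.2_dup"],
            K=1,
            loading_spec=np.array([[2.5], [-2.5]]),
            distinct_sd=0.05,
            seed=7,
        )
        maps = [_emap(atlas.group_map(g), cid=g) for g in atlas.groups]
        decomp = pca_latent(build_dmatrix(maps, zscore=False), K=1)
        i = decomp.contrast_ids.index("16p11.2_del")
        j = decomp.contrast_ids.index("16p11.2_dup")
        assert decomp.cnv_loadings[i, 0] * decomp.cnv_loadings[j, 0] < 0

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        M = rng.standard_normal((30, 4))
        a = pca_latent(build_dmatrix(_maps_from_matrix(M)), K=2)
        b = pca_latent(build_dmatrix(_maps_from_matrix(M)), K=2)
        np.testing.assert_array_equal(a.cnv_loadings, b.cnv_loadings)
        for k in range(2):
            jmax = np.argmax(np.abs(a.cnv_loadings[:, k]))
            assert a.cnv_loadings[jmax, k] > 0

    def test_invalid_k(self):
        M = np.random.default_rng(9).standard_normal((10, 4))
        dm = build_dmatrix(_maps_from_matrix(M))
        with pytest.raises(ValueError, match="K"):
            pca_latent(dm, K=5)


class TestR2PerCnv:
    def test_columns_in_and_out_of_the_pc_plane(self):
        # columns inside the top-2 principal plane have R^2 = 100%;
        # a column orthogonal to it has R^2 ~ 0
        rng = np.random.default_rng(10)
        U = np.linalg.qr(rng.standard_normal((60, 3)))[0]
        M = np.column_stack(
            [3 * U[:, 0], 2 * U[:, 1], 3 * U[:, 0] + 2 * U[:, 1], 0.5 * U[:, 2]]
        )
        dm = build_dmatrix(_maps_from_matrix(M), zscore=False)
        decomp = pca_latent(dm, K=2)
        r2 = r2_per_cnv(decomp, dm)
        order = [dm.contrast_ids.index(_maps_from_matrix(M)[j].contrast_id)
                 for j in range(4)]
        in_plane = [r2[order[j]] for j in range(3)]
        out_plane = r2[order[3]]
        assert all(v > 99.999 for v in in_plane)
        assert out_plane < 1.0

    def test_matches_brute_force_regression_oracle(self):
        rng = np.random.default_rng(11)
        M = rng.standard_normal((50, 6))
        dm = build_dmatrix(_maps_from_matrix(M), zscore=True)
        decomp = pca_latent(dm, K=2)
        r2 = r2_per_cnv(decomp, dm)
        Z = np.column_stack(
            [np.ones(50), decomp.roi_scores[:, 0], decomp.roi_scores[:, 1]]
        )
        for g in range(6):
            y = dm.matrix[:, g]
            beta = linalg.lstsq(Z, y)[0]
            sse = np.sum((y - Z @ beta) ** 2)
            sst = np.sum((y - y.mean()) ** 2)
            assert r2[g] == pytest.approx(100 * (1 - sse / sst), abs=1e-10)

    def test_wrong_dmatrix_rejected(self):
        rng = np.random.default_rng(12)
        dm1 = build_dmatrix(_maps_from_matrix(rng.standard_normal((20, 4))))
        dm2 = build_dmatrix(
            _maps_from_matrix(rng.standard_normal((21, 4))), zscore=True
        )
        decomp = pca_latent(dm1, K=2)
        with pytest.raises(ValidationError):
            r2_per_cnv(decomp, dm2)


class TestGeneDosageDesign:
    def test_coding_convention(self):
        table = CohortTable(make_cohort_frame({"1q21.1_del": 2, "16p11.2_dup": 1}))
        X, loci = gene_dosage_design(table)
        assert loci == ["1q21.1", "16p11.2", "22q11.2", "15q11.2"]
        np.testing.assert_array_equal(X[0], [-1, 0, 0, 0])
        np.testing.assert_array_equal(X[2], [0, 1, 0, 0])

    def test_full_carrier_census_is_484_by_4(self):
        # the study's complete carrier census across clinical and biobank
        # arms: 448 in the eight analyzed groups plus the small biobank
        # 1q21.1 (10/9), 16p11.2 (4/4) and 22q11.2 (1/8) groups
        sizes = {
            "1q21.1_del": 29 + 10, "1q21.1_dup": 19 + 9,
            "16p11.2_del": 83 + 4, "16p11.2_dup": 73 + 4,
            "22q11.2_del": 74 + 1, "22q11.2_dup": 22 + 8,
            "15q11.2_del": 72, "15q11.2_dup": 76,
        }
        table = CohortTable(make_cohort_frame(sizes, n_roi=3))
        X, _ = gene_dosage_design(table)
        assert X.shape == (484, 4)

    def test_control_rejected(self, small_cohort):
        with pytest.raises(ValidationError, match="control"):
            gene_dosage_design(small_cohort)


class TestResidualizeRois:
    def test_residuals_orthogonal_to_design_in_sample(self):
        table = CohortTable(make_cohort_frame({"16p11.2_del": 60}, n_roi=4, seed=13))
        Y, model = residualize_rois(table)
        da = table.data["age"] - table.data["age"].mean()
        for j in range(4):
            assert abs(np.corrcoef(Y[:, j], da)[0, 1]) < 1e-10
            assert abs(np.corrcoef(Y[:, j], table.data["total_GM"])[0, 1]) < 1e-10

    def test_no_covariate_effects_residuals_near_centered_values(self):
        table = CohortTable(make_cohort_frame({"16p11.2_del": 200}, n_roi=4,
                                              seed=14))
        Y, _ = residualize_rois(table)
        centered = table.roi_values - table.roi_values.mean(axis=0)
        # iid values: fitted nuisance coefficients are ~0, residual shift
        # bounded by a few standard errors
        assert np.max(np.abs(Y - centered)) < 3 * 6 / np.sqrt(200)

    def test_stored_coefficients_reused_on_held_out_controls(self):
        # null generator (no planted group effects): carrier-fitted
        # coefficients transfer, so held-out control residuals center at 0
        atlas = make_effect_atlas(
            R=12, groups=["16p11.2_del"], K=1,
            loading_spec=np.zeros((1, 1)), mirror=False, seed=0,
        )
        cohort, _ = simulate_cohort(
            atlas, CovariateModel(), {"16p11.2_del": 150}, n_controls=300, seed=3
        )
        carriers = filter_cohort(cohort, group_in=["16p11.2_del"])
        controls = filter_cohort(cohort, group_in=["control"])
        _, model = residualize_rois(carriers)
        Yc = model.apply(controls)
        se = 1.5 / np.sqrt(controls.n_subjects)
        assert np.all(np.abs(Yc.mean(axis=0)) < 6 * se + 0.5)

    def test_singular_design_rejected(self):
        df = make_cohort_frame({"16p11.2_del": 30}, n_roi=3, seed=15)
        df["age"] = 40.0  # age and age^2 both constant -> collinear
        with pytest.raises(ValueError, match="singular"):
            residualize_rois(CohortTable(df))


def brute_force_canonical_correlations(X, Y):
    """Generalized-eigenvalue oracle for canonical correlations."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = len(X)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = linalg.solve(Sxx, Sxy) @ linalg.solve(Syy, Sxy.T)
    ev = np.sort(np.linalg.eigvals(M).real)[::-1]
    return np.sqrt(np.clip(ev, 0, 1))


class TestCcaGeneMorph:
    def _xy(self, n=60, r=6, l=3, seed=0, couple=None):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, l))
        Y = rng.standard_normal((n, r))
        if couple is not None:
            Y[:, 0] = couple * (X[:, 0] - X[:, 1]) + rng.normal(0, 0.5, n)
        return X, Y

    def test_exact_linear_dependence_gives_correlation_one(self):
        X, Y = self._xy(seed=1)
        Y[:, 0] = X @ np.array([1.0, 2.0, -1.0])
        fit = cca_gene_morph(X, Y, K=2, n_perm=19, seed=0)
        assert fit.canonical_correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_generalized_eigenvalue_oracle(self):
        X, Y = self._xy(n=50, r=10, l=4, seed=2, couple=0.8)
        fit = cca_gene_morph(X, Y, K=3, n_perm=19, seed=0)
        oracle = brute_force_canonical_correlations(X, Y)
        np.testing.assert_allclose(
            fit.canonical_correlations, oracle[:3], atol=1e-8
        )

    def test_matches_sklearn_scores_correlation(self):
        from sklearn.cross_decomposition import CCA as SkCCA

        X, Y = self._xy(n=80, r=8, l=4, seed=3, couple=1.0)
        fit = cca_gene_morph(X, Y, K=2, n_perm=19, seed=0)
        sk = SkCCA(n_components=2, max_iter=2000, tol=1e-10).fit(X, Y)
        xs, ys = sk.transform(X, Y)
        for k in range(2):
            r_sk = abs(np.corrcoef(xs[:, k], ys[:, k])[0, 1])
            assert fit.canonical_correlations[k] == pytest.approx(r_sk, abs=1e-5)

    def test_successive_variates_uncorrelated(self):
        X, Y = self._xy(n=100, r=12, l=4, seed=4, couple=0.5)
        fit = cca_gene_morph(X, Y, K=3, n_perm=19, seed=0)
        for scores in (fit.x_scores, fit.subject_scores):
            c = np.corrcoef(scores.T)
            off = c - np.diag(np.diag(c))
            assert np.max(np.abs(off)) < 1e-8

    def test_correlations_in_unit_interval_and_nonincreasing(self):
        X, Y = self._xy(n=70, r=9, l=4, seed=5)
        fit = cca_gene_morph(X, Y, K=4, n_perm=19, seed=0)
        rho = fit.canonical_correlations
        assert np.all((0 <= rho) & (rho <= 1))
        assert np.all(np.diff(rho) <= 1e-12)

    def test_rank_deficient_y_requires_reduction(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 30))
        with pytest.raises(ValueError, match="pca90"):
            cca_gene_morph(X, Y, K=2, n_perm=19)
        fit = cca_gene_morph(X, Y, K=2, n_perm=19, y_reduce="pca90")
        assert fit.y_reduction == "pca90"
        assert fit.y_weights.shape == (30, 2)

    def test_roi_reordering_invariance_up_to_sign(self):
        X, Y = self._xy(n=60, r=8, l=3, seed=7, couple=0.7)
        fit = cca_gene_morph(X, Y, K=2, n_perm=19, seed=0)
        perm = np.random.default_rng(8).permutation(8)
        fit_p = cca_gene_morph(X, Y[:, perm], K=2, n_perm=19, seed=0)
        np.testing.assert_allclose(
            fit_p.canonical_correlations, fit.canonical_correlations, atol=1e-10
        )
        for k in range(2):
            dot = fit_p.y_loadings[:, k] @ fit.y_loadings[perm, k]
            norm = np.linalg.norm(fit_p.y_loadings[:, k]) * np.linalg.norm(
                fit.y_loadings[perm, k]
            )
            assert abs(dot) / norm == pytest.approx(1.0, abs=1e-8)

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            cca_gene_morph(np.zeros((5, 2)), np.zeros((6, 3)), K=1, n_perm=19)


class TestProjectControls:
    def test_training_projection_reproduces_subject_scores(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 6))
        fit = cca_gene_morph(X, Y, K=2, n_perm=19, seed=0)
        np.testing.assert_allclose(
            project_controls(fit, Y), fit.subject_scores, atol=1e-10
        )

    def test_empty_controls_give_empty_scores(self):
        rng = np.random.default_rng(10)
        fit = cca_gene_morph(
            rng.standard_normal((30, 3)), rng.standard_normal((30, 5)),
            K=2, n_perm=19, seed=0,
        )
        out = project_controls(fit, np.empty((0, 5)))
        assert out.shape == (0, 2)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        fit = cca_gene_morph(
            rng.standard_normal((30, 3)), rng.standard_normal((30, 5)),
            K=2, n_perm=19, seed=0,
        )
        with pytest.raises(ValueError, match="controls_Y"):
            project_controls(fit, np.zeros((4, 7)))


class TestCompareLoadings:
    def test_self_comparison_gives_unit_magnitude_diagonal(self):
        rng = np.random.default_rng(12)
        M = rng.standard_normal((60, 6))
        dm = build_dmatrix(_maps_from_matrix(M), zscore=True)
        decomp = pca_latent(dm, K=2)

        class FakeCCA:
            y_loadings = decomp.roi_scores

        corr = compare_loadings(FakeCCA(), decomp)
        np.testing.assert_allclose(np.abs(np.diag(corr)), 1.0, atol=1e-10)

    def test_random_loadings_weakly_correlated(self):
        rng = np.random.default_rng(13)
        M = rng.standard_normal((130, 6))
        decomp = pca_latent(build_dmatrix(_maps_from_matrix(M)), K=2)

        class FakeCCA:
            y_loadings = rng.standard_normal((130, 2))

        corr = compare_loadings(FakeCCA(), decomp)
        assert np.max(np.abs(corr)) < 0.3

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        decomp = pca_latent(
            build_dmatrix(_maps_from_matrix(rng.standard_normal((20, 4)))), K=2
        )

        class FakeCCA:
            y_loadings = np.zeros((10, 2))

        with pytest.raises(ValueError, match="mismatch"):
            compare_loadings(FakeCCA(), decomp)
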