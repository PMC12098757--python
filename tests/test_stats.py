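import itertools

import numpy as np
import pytest
from scipy import stats as sps

import tremormap as tm
from tremormap.stats import _patient_folds, _rng

from .conftest import brute_force_spearman


def grid_1d(n):
    return tm.VolumeGrid((n, 1, 1))


class TestComputeRmap:
    def test_perfect_monotone_and_reversed(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 4))
        y = np.exp(X[:, 2])  # monotone transform of voxel 2's connectivity
        rmap = tm.compute_rmap(X, y, grid=grid_1d(4))
        assert rmap.values.values[2] == pytest.approx(1.0)
        rmap_rev = tm.compute_rmap(X, -y, grid=grid_1d(4))
        assert rmap_rev.values.values[2] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_per_voxel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 20))
        y = rng.standard_normal(6)
        rmap = tm.compute_rmap(X, y, grid=grid_1d(20))
        for v in range(20):
            assert rmap.values.values[v] == pytest.approx(
                brute_force_spearman(X[:, v], y), abs=1e-10)

    def test_pearson_matches_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((8, 10))
        y = rng.standard_normal(8)
        rmap = tm.compute_rmap(X, y, method="pearson", grid=grid_1d(10))
        for v in range(10):
            expect = sps.pearsonr(X[:, v], y).statistic
            assert rmap.values.values[v] == pytest.approx(expect, abs=1e-10)

    def test_constant_voxel_excluded_from_valid_mask(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 5))
        X[:, 1] = 7.0
        rmap = tm.compute_rmap(X, rng.standard_normal(6), grid=grid_1d(5))
        assert not rmap.valid_mask[1] and rmap.valid_mask[[0, 2, 3, 4]].all()

    def test_constant_outcomes_rejected(self):
        X = np.random.default_rng(4).standard_normal((6, 3))
        with pytest.raises(ValueError, match="constant"):
            tm.compute_rmap(X, np.ones(6), grid=grid_1d(3))

    def test_too_few_hemispheres_rejected(self):
        with pytest.raises(ValueError, match="3 hemispheres"):
            tm.compute_rmap(np.ones((2, 3)), np.array([1.0, 2.0]), grid=grid_1d(3))


class TestSimilarity:
    def test_dot_hand_value(self):
        g = grid_1d(3)
        a = tm.ScalarMap(g, np.array([1.0, -2.0, 3.0]))
        b = tm.ScalarMap(g, np.array([2.0, 0.0, -1.0]))
        assert tm.similarity_dot(a, b) == pytest.approx(-1.0)

    def test_dot_zero_map_and_self(self):
        g = grid_1d(4)
        rng = np.random.default_rng(5)
        a = tm.ScalarMap(g, rng.standard_normal(4))
        zero = tm.ScalarMap(g, np.zeros(4))
        assert tm.similarity_dot(a, zero) == 0.0
        assert tm.similarity_dot(a, a) == pytest.approx((a.values**2).sum())
        assert tm.similarity_dot(a, a) >= 0

    def test_dot_bilinear(self):
        g = grid_1d(6)
        rng = np.random.default_rng(6)
        a = tm.ScalarMap(g, rng.standard_normal(6))
        b = tm.ScalarMap(g, rng.standard_normal(6))
        a3 = tm.ScalarMap(g, 3.0 * a.values)
        assert tm.similarity_dot(a3, b) == pytest.approx(3 * tm.similarity_dot(a, b))

    def test_dot_respects_coverage_intersection(self):
        g = grid_1d(3)
        a = tm.ScalarMap(g, np.array([1.0, 5.0, 2.0]), np.array([True, False, True]))
        b = tm.ScalarMap(g, np.array([4.0, 9.0, 3.0]), np.array([True, True, False]))
        assert tm.similarity_dot(a, b) == pytest.approx(4.0)  # only voxel 0 shared

    def test_dot_empty_intersection_rejected(self):
        g = grid_1d(2)
        a = tm.ScalarMap(g, np.ones(2), np.array([True, False]))
        b = tm.ScalarMap(g, np.ones(2), np.array([False, True]))
        with pytest.raises(ValueError, match="share no covered"):
            tm.similarity_dot(a, b)

    def test_corr_affine_invariance_and_sign(self):
        g = grid_1d(10)
        rng = np.random.default_rng(7)
        a = tm.ScalarMap(g, rng.standard_normal(10))
        b = tm.ScalarMap(g, 2.0 * a.values + 5.0)
        for method in ("spearman", "pearson"):
            assert tm.similarity_corr(a, b, method=method) == pytest.approx(1.0)
        neg = tm.ScalarMap(g, -a.values)
        assert tm.similarity_corr(a, neg) == pytest.approx(-1.0)

    def test_corr_matches_oracle_and_symmetry(self):
        g = grid_1d(10)
        rng = np.random.default_rng(8)
        a = tm.ScalarMap(g, rng.standard_normal(10))
        b = tm.ScalarMap(g, rng.standard_normal(10))
        assert tm.similarity_corr(a, b) == pytest.approx(
            brute_force_spearman(a.values, b.values), abs=1e-12)
        assert tm.similarity_corr(a, b) == tm.similarity_corr(b, a)

    def test_corr_degenerate_variance_rejected(self):
        g = grid_1d(5)
        a = tm.ScalarMap(g, np.ones(5))
        b = tm.ScalarMap(g, np.arange(5.0))
        with pytest.raises(ValueError, match="degenerate"):
            tm.similarity_corr(a, b)


class TestPredictWithMap:
    def test_own_seedmap_gives_coefficient_one(self, study):
        maps = study["maps_a"][:4]
        coeffs = tm.predict_with_map(maps, maps[0], mode="corr")
        assert coeffs[0] == pytest.approx(1.0)

    def test_zero_reference_dot_gives_zeros(self, study):
        g = study["grid"]
        zero = tm.ScalarMap(g, np.zeros(g.n_voxels))
        coeffs = tm.predict_with_map(study["maps_a"][:3], zero, mode="dot")
        np.testing.assert_allclose(coeffs, 0.0)

    def test_equals_looped_similarity_calls(self, study):
        maps = study["maps_b"][:4]
        ref = study["truth"].truth_map
        coeffs = tm.predict_with_map(maps, ref, mode="corr")
        for i, m in enumerate(maps):
            assert coeffs[i] == tm.similarity_corr(m, ref)


class TestResidualize:
    def test_group_mean_centering_oracle(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 20.0])
        labels = np.array(["a", "a", "a", "b", "b"])
        np.testing.assert_allclose(tm.residualize_on_cohort(values, labels),
                                   [-1.0, 0.0, 1.0, -5.0, 5.0])

    def test_constant_within_cohort_gives_zeros(self):
        values = np.array([4.0, 4.0, 9.0, 9.0])
        labels = np.array(["a", "a", "b", "b"])
        np.testing.assert_allclose(tm.residualize_on_cohort(values, labels), 0.0)

    def test_single_cohort_is_mean_centering(self):
        v = np.array([1.0, 2.0, 6.0])
        np.testing.assert_allclose(tm.residualize_on_cohort(v, ["x"] * 3), v - 3.0)

    def test_equals_ols_dummy_residuals(self):
        rng = np.random.default_rng(9)
        v = rng.standard_normal(12)
        labels = np.array(["a", "b", "c"] * 4)
        D = np.column_stack([np.ones(12)] + [(labels == l).astype(float) for l in "bc"])
        beta, *_ = np.linalg.lstsq(D, v, rcond=None)
        np.testing.assert_allclose(tm.residualize_on_cohort(v, labels), v - D @ beta,
                                   atol=1e-10)

    def test_singleton_cohort_warned(self):
        with pytest.warns(UserWarning, match="single member"):
            res = tm.residualize_on_cohort([1.0, 2.0, 9.0], ["a", "a", "b"])
        assert res[2] == 0.0


class TestSpearmanPerm:
    def test_perfect_correlation_minimal_p(self):
        x = np.arange(10.0)
        res = tm.spearman_perm(x, x, n_perm=999, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.p_perm <= 5 / (999 + 1)
        assert res.df == 8

    def test_p_never_zero_and_bounded_below(self):
        rng = np.random.default_rng(10)
        res = tm.spearman_perm(rng.standard_normal(8), rng.standard_normal(8),
                               n_perm=200, seed=1)
        assert res.p_perm >= 1 / 201

    def test_matches_exhaustive_enumeration_at_n5(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        obs = brute_force_spearman(x, y)
        count = sum(
            abs(brute_force_spearman(x, np.array(p))) >= abs(obs) - 1e-12
            for p in itertools.permutations(y))
        exact = count / 120.0
        res = tm.spearman_perm(x, y, n_perm=5000, seed=2, n_boot=0)
        assert res.rho == pytest.approx(obs, abs=1e-12)
        assert res.p_perm == pytest.approx(exact, abs=0.02)

    def test_ties_use_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 5.0, 7.0])
        res = tm.spearman_perm(x, y, n_perm=100, seed=3, n_boot=0)
        assert res.rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_ci_brackets_rho(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(40)
        y = x + 0.5 * rng.standard_normal(40)
        res = tm.spearman_perm(x, y, n_perm=500, seed=4)
        assert res.ci_low <= res.rho + 1e-9 and res.rho - 1e-9 <= res.ci_high

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tm.spearman_perm(np.ones(5), np.arange(5.0))


class TestJointCohortModel:
    def test_perfect_fit(self):
        rng = np.random.default_rng(12)
        s = rng.standard_normal(20)
        labels = ["a"] * 10 + ["b"] * 10
        res = tm.joint_cohort_model(s, labels, s)
        assert res.r_squared == pytest.approx(1.0)

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(13)
        s = rng.standard_normal(15)
        labels = np.array(["a"] * 8 + ["b"] * 7)
        y = 0.3 * s + 0.2 * (labels == "b") + rng.standard_normal(15) * 0.1
        res = tm.joint_cohort_model(s, labels, y)
        X = np.column_stack([np.ones(15), s, (labels == "b").astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = res.coefficients
        np.testing.assert_allclose(
            [got["const"], got["similarity"], got["cohort_b"]], beta, atol=1e-8)
        resid = y - X @ beta
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert res.r_squared == pytest.approx(r2, abs=1e-8)

    def test_interaction_term_optional(self):
        rng = np.random.default_rng(14)
        s = rng.standard_normal(30)
        labels = ["a"] * 15 + ["b"] * 15
        y = rng.standard_normal(30)
        res = tm.joint_cohort_model(s, labels, y, interaction=True)
        assert "similarity:cohort_b" in res.coefficients

    def test_rank_deficiency_rejected(self):
        # similarity identical to the cohort dummy is collinear with it
        y = np.random.default_rng(20).standard_normal(6)
        s = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            tm.joint_cohort_model(s, ["a"] * 3 + ["b"] * 3, y)


class TestKFoldCV:
    def test_equal_fold_sizes_65_patients(self):
        rng = _rng(0)
        pids = [f"p{i}" for i in range(65)]
        assignment = _patient_folds(pids, ["STN"] * 65, 5, rng)
        sizes = np.bincount([assignment[p] for p in pids], minlength=5)
        assert sizes.tolist() == [13, 13, 13, 13, 13]

    def test_every_hemisphere_predicted_once_and_pairs_share_fold(self, study):
        cv = tm.kfold_cv(study["rec_a"], study["maps_a"], k=5, seed=1, n_perm=200)
        assert np.isfinite(cv.predictions).all()
        by_pid = {}
        for r in study["rec_a"]:
            by_pid.setdefault(r.patient_id, set()).add(cv.fold_assignment[r.patient_id])
        assert all(len(folds) == 1 for folds in by_pid.values())

    def test_no_leakage_from_test_fold_outcomes(self, study):
        """Poisoning one fold's outcomes must not change that fold's training map."""
        records = study["rec_a"]
        maps = study["maps_a"]
        cv = tm.kfold_cv(records, maps, k=5, seed=2, n_perm=200)
        fold0_pids = {p for p, f in cv.fold_assignment.items() if f == 0}
        poisoned = [
            tm.HemisphereRecord(r.patient_id, r.cohort, r.hemisphere,
                                r.baseline, r.baseline, r.scale_max, seed=r.seed)
            if r.patient_id in fold0_pids else r
            for r in records
        ]
        cv_p = tm.kfold_cv(poisoned, maps, k=5, seed=2, n_perm=200)
        np.testing.assert_allclose(cv_p.fold_rmaps[0].values.values,
                                   cv.fold_rmaps[0].values.values, atol=1e-12)

    def test_pooled_cv_stratifies_and_adjusts_cohort(self, study):
        records = study["rec_a"] + study["rec_b"]
        maps = study["maps_a"] + study["maps_b"]
        cv = tm.kfold_cv(records, maps, k=5, seed=3, n_perm=200)
        labels = np.array([r.cohort for r in records])
        for f in range(5):
            fold_pids = {p for p, ff in cv.fold_assignment.items() if ff == f}
            fold_labels = {r.cohort for r in records if r.patient_id in fold_pids}
            assert fold_labels == {"STN", "VIM"}

    def test_planted_effect_recovered(self, study):
        cv = tm.kfold_cv(study["rec_a"], study["maps_a"], k=5, seed=4, n_perm=1000)
        assert cv.pooled.rho > 0
        assert cv.pooled.p_perm < 0.05

    def test_fewer_patients_than_folds_rejected(self, study):
        with pytest.raises(ValueError, match="patients"):
            tm.kfold_cv(study["rec_a"][:6], study["maps_a"][:6], k=5, seed=0)


class TestRmapSimilarityPermtest:
    def test_relabeled_copy_maximal_similarity(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((10, 30))
        y = rng.standard_normal(10)
        res = tm.rmap_similarity_permtest(X, y, X.copy(), y.copy(), n_perm=200,
                                          permute="a", seed=5, grid=grid_1d(30))
        assert res.observed_similarity == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 201)

    def test_null_list_length_contract(self):
        rng = np.random.default_rng(16)
        Xa, Xb = rng.standard_normal((8, 25)), rng.standard_normal((8, 25))
        ya, yb = rng.standard_normal(8), rng.standard_normal(8)
        res = tm.rmap_similarity_permtest(Xa, ya, Xb, yb, n_perm=157, permute="both",
                                          seed=6, grid=grid_1d(25))
        assert res.n_perm == 157 and len(res.null_similarities) == 157

    def test_null_matches_direct_rebuild(self):
        """A permuted-outcome null similarity equals rebuilding the R-map by hand."""
        rng = np.random.default_rng(17)
        Xa, Xb = rng.standard_normal((7, 12)), rng.standard_normal((7, 12))
        ya, yb = rng.standard_normal(7), rng.standard_normal(7)
        g = grid_1d(12)
        res = tm.rmap_similarity_permtest(Xa, ya, Xb, yb, n_perm=5, permute="a",
                                          seed=7, grid=g)
        rmap_b = tm.compute_rmap(Xb, yb, grid=g)
        # regenerate the same permutation stream the test used
        perm_rng = _rng(7)
        ranks = sps.rankdata(ya)
        perms = perm_rng.permuted(np.tile(ranks, (5, 1)), axis=1)
        for i in range(5):
            rmap_perm = tm.compute_rmap(Xa, perms[i], grid=g)
            expect = tm.similarity_corr(rmap_perm, rmap_b)
            assert res.null_similarities[i] == pytest.approx(expect, abs=1e-10)

    def test_shared_truth_cohorts_reject_null(self, study):
        Xa, g = tm.seedmap_matrix(study["maps_a"])
        Xb, _ = tm.seedmap_matrix(study["maps_b"])
        ya = tm.OutcomeVector(study["rec_a"]).normalized_improvement
        yb = tm.OutcomeVector(study["rec_b"]).normalized_improvement
        res = tm.rmap_similarity_permtest(Xa, ya, Xb, yb, n_perm=500, permute="both",
                                          seed=8, grid=g)
        assert res.observed_similarity > 0.5
        assert res.p < 0.05

    def test_bad_permute_mode_rejected(self):
        with pytest.raises(ValueError, match="permute"):
            tm.rmap_similarity_permtest(np.ones((3, 3)), np.ones(3), np.ones((3, 3)),
                                        np.ones(3), permute="c", grid=grid_1d(3))
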