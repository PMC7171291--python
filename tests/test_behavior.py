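"""CCA, cross-validation, permutation inference, bootstrap, transfer."""

import numpy as np
import pandas as pd
import pytest

import restmodes as rm
from restmodes.behavior import _cv_pooled_r
from restmodes.exceptions import (
    DegenerateDataError,
    InvalidParameterError,
    RankDeficientError,
)


class TestCcaFit:
    def test_identical_single_columns_correlate_perfectly(self, rng):
        x = rng.standard_normal(30)
        model = rm.cca_fit(x, x.copy())
        assert model.correlations[0] == pytest.approx(1.0, abs=1e-10)

    def test_constructed_orthogonal_column_gives_zero(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        x = x - x.mean()
        y = y - y.mean()
        y -= (y @ x) / (x @ x) * x  # exact sample-orthogonality
        model = rm.cca_fit(x, y)
        assert model.correlations[0] == pytest.approx(0.0, abs=1e-10)

    def test_first_correlation_matches_eigenvalue_oracle(self, rng):
        X = rng.standard_normal((20, 2))
        Y = X @ rng.standard_normal((2, 2)) + 0.5 * rng.standard_normal((20, 2))
        model = rm.cca_fit(X, Y)
        Zx = (X - X.mean(0)) / X.std(0, ddof=1)
        Zy = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        Sxx = Zx.T @ Zx / 19
        Syy = Zy.T @ Zy / 19
        Sxy = Zx.T @ Zy / 19
        M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
        lam_max = np.max(np.linalg.eigvals(M).real)
        assert model.correlations[0] == pytest.approx(np.sqrt(lam_max), abs=1e-8)

    def test_agrees_with_sklearn_variate_correlation(self, rng):
        from sklearn.cross_decomposition import CCA as SkCCA

        X = rng.standard_normal((60, 4))
        Y = 0.4 * X[:, :2] + rng.standard_normal((60, 3))[:, :2] @ np.eye(2)
        Y = np.column_stack([Y, rng.standard_normal(60)])
        model = rm.cca_fit(X, Y)
        sk = SkCCA(n_components=1, scale=True).fit(X, Y)
        u, v = sk.transform(X, Y)
        r_sk = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert model.correlations[0] == pytest.approx(r_sk, abs=1e-6)

    def test_correlations_invariant_to_affine_column_rescaling(self, rng):
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 2)) + 0.3 * X[:, :2]
        base = rm.cca_fit(X, Y).correlations
        X2 = X * np.array([10.0, -0.2, 3.0]) + np.array([5.0, -1.0, 0.0])
        scaled = rm.cca_fit(X2, Y).correlations
        assert np.allclose(base, scaled, atol=1e-10)

    def test_sign_anchor_first_behavior_weight_nonnegative(self, rng):
        X = rng.standard_normal((40, 3))
        Y = rng.standard_normal((40, 3))
        model = rm.cca_fit(X, Y)
        assert np.all(model.y_weights[0, :] >= 0)

    def test_collinear_columns_named_in_error(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(30)})
        with pytest.raises(RankDeficientError) as err:
            rm.cca_fit(X, rng.standard_normal((30, 2)))
        assert err.value.columns


class TestCcaCrossval:
    def test_planted_link_recovered_at_n300(self):
        coh = rm.simulate_cohort(
            rm.CohortConfig(n_subjects=300, beta=0.5, seed=11), generate_timeseries=False
        )
        X, Y = rm.ground_truth_features(coh)
        cv = rm.cca_crossval(X, Y, k_folds=10, seed=1)
        assert cv.r == pytest.approx(0.5, abs=0.15)

    def test_null_cohort_pooled_r_small(self):
        coh = rm.simulate_cohort(
            rm.CohortConfig(n_subjects=300, beta=0.0, seed=12), generate_timeseries=False
        )
        X, Y = rm.ground_truth_features(coh)
        cv = rm.cca_crossval(X, Y, k_folds=10, seed=2)
        assert abs(cv.r) < 0.15

    def test_leave_one_out_on_collinear_data_gives_unity(self, rng):
        x = rng.standard_normal(12)
        cv = rm.cca_crossval(x, 2.0 * x, k_folds=6, seed=0)
        assert cv.r == pytest.approx(1.0, abs=1e-8)

    def test_lean_permutation_path_matches_model_path_on_identity(self):
        coh = rm.simulate_cohort(
            rm.CohortConfig(n_subjects=120, beta=0.4, seed=5), generate_timeseries=False
        )
        X, Y = rm.ground_truth_features(coh)
        cv = rm.cca_crossval(X, Y, k_folds=6, seed=3)
        r_lean = _cv_pooled_r(X.to_numpy(), Y.to_numpy(), cv.fold_assignments, 0)
        assert r_lean == pytest.approx(cv.r, abs=1e-12)

    def test_explicit_fold_sizes_respected(self, rng):
        X = rng.standard_normal((20, 2))
        Y = 0.5 * X + rng.standard_normal((20, 2))
        cv = rm.cca_crossval(X, Y, fold_sizes=[5, 5, 5, 5], seed=0)
        assert sorted(np.bincount(cv.fold_assignments)) == [5, 5, 5, 5]
        with pytest.raises(InvalidParameterError):
            rm.cca_crossval(X, Y, fold_sizes=[10, 9], seed=0)

    def test_pooled_vectors_cover_every_subject(self, rng):
        X = rng.standard_normal((30, 2))
        Y = rng.standard_normal((30, 2)) + 0.5 * X
        cv = rm.cca_crossval(X, Y, k_folds=5, seed=4)
        assert cv.pooled_u.shape == (30,)
        assert np.all(np.isfinite(cv.pooled_u))


class TestPermTest:
    def test_identity_reaches_minimal_p(self, rng):
        a = rng.standard_normal(20)
        p = rm.perm_test_correlation(a, a, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_anti_identity_reaches_minimal_p_two_sided(self, rng):
        a = rng.standard_normal(20)
        p = rm.perm_test_correlation(a, -a, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_null_p_values_roughly_uniform(self, rng):
        from scipy.stats import kstest

        ps = []
        for _ in range(150):
            a = rng.standard_normal(25)
            b = rng.standard_normal(25)
            ps.append(rm.perm_test_correlation(a, b, n_perm=199, seed=int(rng.integers(1 << 30))))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            rm.perm_test_correlation(np.ones(10), np.arange(10.0), n_perm=99, seed=0)


class TestResidualizeAndPartialCorr:
    def test_orthogonal_confound_leaves_centered_vector(self, rng):
        v = rng.standard_normal(30)
        v -= v.mean()
        c = rng.standard_normal(30)
        c -= c.mean()
        c -= (c @ v) / (v @ v) * v
        assert np.allclose(rm.residualize_variate(v, c), v, atol=1e-10)

    def test_exact_confound_annihilated(self, rng):
        c = rng.standard_normal(25)
        out = rm.residualize_variate(3.0 * c, c)
        assert np.max(np.abs(out)) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        v = rng.standard_normal(40)
        C = rng.standard_normal((40, 3))
        X = np.column_stack([np.ones(40), C])
        expected = v - X @ np.linalg.solve(X.T @ X, X.T @ v)
        assert np.allclose(rm.residualize_variate(v, C), expected, atol=1e-10)

    def test_partial_corr_without_covariates_is_plain_correlation(self, rng):
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        r, p = rm.partial_corr_perm(x, y, None, n_perm=999, seed=0)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert p == rm.perm_test_correlation(
            x - x.mean(), y - y.mean(), n_perm=999, seed=0
        )

    def test_partial_corr_matches_recursive_formula(self, rng):
        x, y, z = rng.standard_normal((3, 60))
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        r, _ = rm.partial_corr_perm(x, y, z, n_perm=99, seed=0)
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_variable_equal_to_covariate_gives_zero(self, rng):
        z = rng.standard_normal(30)
        x = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="fully explained"):
            r, _ = rm.partial_corr_perm(x, z, z, n_perm=99, seed=0)
        assert r == 0.0


class TestBootstrap:
    def test_exact_linear_model_yields_point_interval(self, rng):
        x = rng.standard_normal(40)
        res = rm.bootstrap_regression_ci(x, 2.0 * x, n_boot=200, seed=0)
        assert res.ci_low[0] == pytest.approx(2.0, abs=1e-8)
        assert res.ci_high[0] == pytest.approx(2.0, abs=1e-8)
        assert res.reliable[0]

    def test_interval_spanning_zero_flagged_unreliable(self, rng):
        X = rng.standard_normal((80, 2))
        y = 0.8 * X[:, 0] + rng.standard_normal(80)  # second predictor null
        res = rm.bootstrap_regression_ci(X, y, n_boot=500, seed=1)
        assert res.ci_low[1] < 0 < res.ci_high[1]
        assert not res.reliable[1]
        assert res.reliable[0]

    def test_percentile_flag_switches_method(self, rng):
        X = rng.standard_normal((60, 2))
        y = 0.5 * X[:, 0] + rng.standard_normal(60)
        bca = rm.bootstrap_regression_ci(X, y, n_boot=400, seed=2, method="bca")
        pct = rm.bootstrap_regression_ci(X, y, n_boot=400, seed=2, method="percentile")
        assert bca.method == "bca" and pct.method == "percentile"
        assert not np.allclose(bca.ci_low, pct.ci_low)


class TestTransferProjection:
    def _model(self, rng, p=4):
        coh = rm.simulate_cohort(
            rm.CohortConfig(n_subjects=80, beta=0.5, seed=31), generate_timeseries=False
        )
        X, Y = rm.ground_truth_features(coh)
        return rm.cca_fit(X, Y), X

    def test_one_hot_weights_reproduce_standardized_feature(self, rng):
        model, X = self._model(rng)
        w = np.zeros_like(model.x_weights)
        w[2, 0] = 1.0
        import dataclasses

        model_oh = dataclasses.replace(model, x_weights=w)
        score = rm.transfer_projection(X, model_oh, zero_names=())
        Z = (X.iloc[:, 2] - X.iloc[:, 2].mean()) / X.iloc[:, 2].std(ddof=1)
        assert np.allclose(score, Z.to_numpy(), atol=1e-10)

    def test_zeroed_feature_is_covaried_out(self, rng):
        model, X = self._model(rng)
        name = model.x_names[0]
        score = rm.transfer_projection(X, model, zero_names=[name])
        z = X[name].to_numpy()
        z = (z - z.mean()) / z.std(ddof=1)
        assert abs(score @ z) < 1e-8  # orthogonal after residualization
        # and invariant (pre-residualization) to arbitrary changes in that feature
        X2 = X.copy()
        X2[name] = rng.standard_normal(len(X2))
        w = model.x_weights[:, 0].copy()
        w[0] = 0.0
        raw1 = ((X - X.mean()) / X.std(ddof=1)).to_numpy() @ w
        raw2 = ((X2 - X2.mean()) / X2.std(ddof=1)).to_numpy() @ w
        assert np.allclose(raw1, raw2, atol=1e-10)

    def test_unknown_zero_name_rejected(self, rng):
        model, X = self._model(rng)
        with pytest.raises(InvalidParameterError):
            rm.transfer_projection(X, model, zero_names=["nope"])

    def test_planted_trait_link_transfers_to_small_cohort(self):
        """Zeroed-weight projection keeps power at a second-cohort sample size.

        A discovery model fit on a large cohort is projected onto independent
        n=60 cohorts sharing the planted link; the partial correlation with
        the planted trait should be significant in most replications.
        """
        discovery = rm.simulate_cohort(
            rm.CohortConfig(n_subjects=300, beta=0.5, seed=41), generate_timeseries=False
        )
        Xd, Yd = rm.ground_truth_features(discovery)
        model = rm.cca_fit(Xd, Yd)
        # the mode's sign is anchored to the (noise) age weight, so the
        # expected direction follows the model's own visual-EM weight
        trait_sign = np.sign(model.y_weights[model.y_names.index("visual_em"), 0])
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            coh = rm.simulate_cohort(
                rm.CohortConfig(n_subjects=60, beta=0.5, seed=9000 + rep),
                generate_timeseries=False,
            )
            X, _ = rm.ground_truth_features(coh)
            score = rm.transfer_projection(
                X, model, zero_names=["sim_perceptual", "n_sp"]
            )
            r, p = rm.partial_corr_perm(
                score, coh.behavior["visual_em"].to_numpy(), None,
                n_perm=999, seed=rep,
            )
            hits += (p < 0.05) and (r * trait_sign > 0)
        assert hits >= 0.8 * n_rep

    def test_discovery_weights_mirror_planted_structure(self):
        """Oriented to the trait, the planted drivers carry the top weights.

        The planted composite is fewer perceptual-to-semantic sequences plus
        greater rest-math similarity, so after orienting the mode to a
        positive visual-EM weight, n_ps must weigh negative, sim_math
        positive, and the two must be the largest-magnitude brain weights.
        """
        coh = rm.simulate_cohort(
            rm.CohortConfig(n_subjects=300, beta=0.5, seed=41), generate_timeseries=False
        )
        X, Y = rm.ground_truth_features(coh)
        model = rm.cca_fit(X, Y)
        s = np.sign(model.y_weights[model.y_names.index("visual_em"), 0])
        w = dict(zip(model.x_names, s * model.x_weights[:, 0]))
        assert w["n_ps"] < 0
        assert w["sim_math"] > 0
        top_two = sorted(w, key=lambda k: abs(w[k]), reverse=True)[:2]
        assert set(top_two) == {"n_ps", "sim_math"}
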