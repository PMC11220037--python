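"""Fold construction, PCR fold models, nested K selection, consensus maps."""

import pickle

import numpy as np
import pandas as pd
import pytest

from eeanet.cohort import CohortSpec, generate_covariates_and_clusters
from eeanet.prediction import (
    CrossValidatedPCR,
    build_covariate_design,
    consensus_feature_map,
    fit_pcr_fold,
    make_folds,
    predict_and_correlate,
    run_cv_pipeline,
    select_num_components,
)


def _covariates(n, rng):
    return pd.DataFrame({
        "subject_id": [f"s{i:04d}" for i in range(n)],
        "site": [f"site{i % 4}" for i in range(n)],
        "family": [f"f{i:04d}" for i in range(n)],
        "age": rng.uniform(9, 11, n),
        "age2": 0.0,
        "sex": rng.integers(0, 2, n),
        "raceeth": rng.integers(0, 4, n),
        "fd": rng.uniform(0.05, 0.5, n),
        "fd2": 0.0,
    }).assign(**{"age2": lambda d: d.age**2, "fd2": lambda d: d.fd**2})


class TestCovariateDesign:
    def test_columns_and_dummies(self):
        rng = np.random.default_rng(0)
        cov = _covariates(50, rng)
        design, names = build_covariate_design(cov)
        assert names[0] == "intercept"
        assert {"age", "age2", "sex", "fd", "fd2"} <= set(names)
        assert sum(n.startswith("raceeth_") for n in names) == 3  # reference coded

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        cov = _covariates(50, rng)
        cov["fd2"] = cov["fd"] * 2.0  # exactly collinear with fd
        with pytest.warns(UserWarning, match="collinear"):
            design, names = build_covariate_design(cov)
        assert "fd2" not in names
        assert np.linalg.matrix_rank(design) == design.shape[1]


class TestFolds:
    def test_loso_one_fold_per_site(self):
        rng = np.random.default_rng(2)
        cov = _covariates(80, rng)
        folds = make_folds(cov, scheme="loso")
        assert set(folds) == set(cov.site)
        assert (folds.to_numpy() == cov.site.to_numpy()).all()

    def test_kfold_balanced_singleton_families(self):
        rng = np.random.default_rng(3)
        cov = _covariates(100, rng)
        folds = make_folds(cov, scheme="kfold", k=10, seed=1)
        assert folds.value_counts().eq(10).all()

    def test_families_never_split(self):
        spec = CohortSpec(n_subjects=120)
        cov = generate_covariates_and_clusters(spec, seed=5)
        for seed in range(25):
            folds = make_folds(cov, scheme="kfold", k=5, seed=seed)
            joined = pd.DataFrame({"family": cov.family.to_numpy(),
                                   "fold": folds.to_numpy()})
            assert (joined.groupby("family")["fold"].nunique() == 1).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        cov = _covariates(60, rng)
        f1 = make_folds(cov, scheme="kfold", k=5, seed=9)
        f2 = make_folds(cov, scheme="kfold", k=5, seed=9)
        pd.testing.assert_series_equal(f1, f2)


class TestPCRFold:
    def _planted(self, n=200, p=50, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        # two dominant planted components plus weak feature noise
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        l1, l2 = rng.normal(size=p), rng.normal(size=p)
        X = np.outer(f1, l1) * 4 + np.outer(f2, l2) * 2 + 0.05 * rng.normal(size=(n, p))
        y = 2 * f1 + f2 + noise * rng.normal(size=n)
        cov = _covariates(n, rng)  # covariates are pure noise relative to X and y
        return X, y, cov

    def test_inactive_nuisance_reduces_to_plain_pcr(self):
        n, p = 120, 20
        rng = np.random.default_rng(5)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        cov = _covariates(n, rng)
        cov[["age", "age2", "sex", "fd", "fd2"]] = 0.0
        cov["raceeth"] = 0
        with pytest.warns(UserWarning, match="collinear"):
            model = fit_pcr_fold(X, y, cov, k=5)
        # residualization against an intercept-only design is just centering
        Xc = X - X.mean(0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ vt[:5].T
        w, *_ = np.linalg.lstsq(scores - scores.mean(0), y - y.mean(), rcond=None)
        np.testing.assert_allclose(np.abs(model.weights), np.abs(w), rtol=1e-8)

    def test_full_rank_k_reproduces_ols(self):
        n, p = 80, 10
        rng = np.random.default_rng(6)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        cov = _covariates(n, rng)
        model = fit_pcr_fold(X, y, cov, k=p)
        r_in, y_pred, y_resid = predict_and_correlate(model, X, y, cov)
        design, _ = build_covariate_design(cov)
        yr = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        Xc = X - X.mean(0)
        Xr = Xc - design @ np.linalg.lstsq(design, Xc, rcond=None)[0]
        beta, *_ = np.linalg.lstsq(Xr, yr, rcond=None)
        np.testing.assert_allclose(y_pred, Xr @ beta, atol=1e-8)

    def test_betas_match_independent_solver(self):
        n, p = 150, 30
        rng = np.random.default_rng(7)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        cov = _covariates(n, rng)
        model = fit_pcr_fold(X, y, cov, k=8)
        design, _ = build_covariate_design(cov)
        scores = (X - X.mean(0)) @ model.loadings
        ref = np.linalg.solve(design.T @ design, design.T @ scores)
        np.testing.assert_allclose(model.score_betas, ref, atol=1e-8)

    def test_noiseless_two_component_signal_recovered(self):
        X, y, cov = self._planted(noise=0.0)  # y an exact function of the factors
        tr = np.arange(100)
        te = np.arange(100, 200)
        model = fit_pcr_fold(X[tr], y[tr], cov.iloc[tr].reset_index(drop=True), k=5)
        r, *_ = predict_and_correlate(model, X[te], y[te],
                                      cov.iloc[te].reset_index(drop=True))
        assert r > 0.99

    def test_identical_train_test_equals_in_sample(self):
        X, y, cov = self._planted(noise=1.0)
        model = fit_pcr_fold(X, y, cov, k=5)
        r, y_pred, y_resid = predict_and_correlate(model, X, y, cov)
        assert r == pytest.approx(float(np.corrcoef(y_pred, y_resid)[0, 1]))

    def test_tiny_test_fold_undefined(self):
        X, y, cov = self._planted()
        model = fit_pcr_fold(X, y, cov, k=3)
        with pytest.warns(UserWarning, match="fewer than 3"):
            r, *_ = predict_and_correlate(model, X[:2], y[:2],
                                          cov.iloc[:2].reset_index(drop=True))
        assert np.isnan(r)

    def test_k_beyond_rank_rejected(self):
        X, y, cov = self._planted(n=40, p=50)
        with pytest.raises(ValueError):
            fit_pcr_fold(X, y, cov, k=45)


class TestSelectK:
    def test_planted_one_component_prefers_small_k(self):
        rng = np.random.default_rng(8)
        n, p = 150, 40
        load = rng.normal(size=p)
        f = rng.normal(size=n)
        X = np.outer(f, load) * 3 + rng.normal(size=(n, p))
        y = f + 0.1 * rng.normal(size=n)
        cov = _covariates(n, rng)
        k = select_num_components(X, y, cov, candidate_ks=(1, 2, 3, 5, 10, 25), seed=0)
        assert k <= 3

    def test_null_outcome_returns_some_candidate(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 30))
        y = rng.normal(size=120)
        cov = _covariates(120, rng)
        k = select_num_components(X, y, cov, candidate_ks=(2, 5, 10), seed=1)
        assert k in (2, 5, 10)

    def test_infeasible_candidates_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 20))
        y = rng.normal(size=60)
        cov = _covariates(60, rng)
        with pytest.warns(UserWarning, match="dropped"):
            k = select_num_components(X, y, cov, candidate_ks=(5, 500), seed=2)
        assert k == 5

    def test_matches_brute_force_inner_loop(self):
        # independently coded nested 5-fold loop on a small fixture
        rng = np.random.default_rng(11)
        n, p = 200, 50
        X = rng.normal(size=(n, p))
        X[:, :3] *= 4
        beta = np.zeros(p)
        beta[:3] = (0.6, 0.4, 0.3)
        y = (X - X.mean(0)) @ beta + rng.normal(size=n)
        cov = _covariates(n, rng)
        ks = (1, 2, 3, 5, 10)
        seed = 5
        levels = tuple(np.unique(cov.raceeth))
        picked = select_num_components(X, y, cov, candidate_ks=ks, seed=seed,
                                       families=cov.family.to_numpy())

        # brute force with the same fold assignment
        rng2 = np.random.default_rng(seed)
        groups = pd.Series(range(n)).groupby(cov.family.to_numpy()).apply(list)
        order = rng2.permutation(len(groups))
        fold_of = np.empty(n, dtype=int)
        sizes = np.zeros(5, dtype=int)
        for gi in order:
            members = groups.iloc[gi]
            f = int(np.argmin(sizes))
            fold_of[members] = f
            sizes[f] += len(members)
        means = {}
        for k in ks:
            rs = []
            for f in range(5):
                tr, te = fold_of != f, fold_of == f
                m = fit_pcr_fold(X[tr], y[tr], cov[tr].reset_index(drop=True), k,
                                 raceeth_levels=levels)
                r, *_ = predict_and_correlate(m, X[te], y[te],
                                              cov[te].reset_index(drop=True))
                rs.append(r)
            means[k] = np.mean(rs)
        assert picked == max(ks, key=lambda k: (means[k], -k))


class TestPipeline:
    def test_mean_is_unweighted_average_and_coverage(self):
        rng = np.random.default_rng(12)
        n, p = 120, 15
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         index=[f"s{i:04d}" for i in range(n)])
        y = pd.Series(rng.normal(size=n), index=X.index)
        cov = _covariates(n, rng)
        folds = make_folds(cov, scheme="kfold", k=4, seed=0)
        res = run_cv_pipeline(X, y, cov, folds, candidate_ks=(2, 5), seed=1)
        assert res.mean_r == pytest.approx(np.mean(list(res.fold_rs.values())))
        # every subject scored exactly once out of fold
        assert sorted(res.predictions.subject_id) == sorted(X.index)

    def test_training_artifacts_immune_to_test_outcome(self):
        rng = np.random.default_rng(13)
        n, p = 90, 12
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         index=[f"s{i:04d}" for i in range(n)])
        y = pd.Series(rng.normal(size=n), index=X.index)
        cov = _covariates(n, rng)
        folds = make_folds(cov, scheme="kfold", k=3, seed=0)
        lab = folds.iloc[0]
        te = (folds == lab).to_numpy()
        y2 = y.copy()
        y2[te] = rng.permutation(y2[te].to_numpy())  # scramble test-fold outcome
        r1 = run_cv_pipeline(X, y, cov, folds, candidate_ks=(2, 5), seed=7)
        r2 = run_cv_pipeline(X, y2, cov, folds, candidate_ks=(2, 5), seed=7)
        m1, m2 = r1.fold_models[lab], r2.fold_models[lab]
        assert pickle.dumps(m1) == pickle.dumps(m2)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(14)
        n, p = 80, 10
        ids = [f"s{i:04d}" for i in range(n)]
        X = pd.DataFrame(rng.normal(size=(n, p)), index=ids)
        y = pd.Series(rng.normal(size=n), index=ids)
        cov = _covariates(n, rng)
        folds = make_folds(cov, scheme="kfold", k=4, seed=0)
        res1 = run_cv_pipeline(X, y, cov, folds, candidate_ks=(3,), seed=2)
        perm = rng.permutation(n)
        Xp = X.iloc[perm]
        yp = y.iloc[perm]
        covp = cov.iloc[perm].reset_index(drop=True)
        foldsp = folds.iloc[perm]
        res2 = run_cv_pipeline(Xp, yp, covp, foldsp, candidate_ks=(3,), seed=2)
        for lab in res1.fold_rs:
            assert res1.fold_rs[lab] == pytest.approx(res2.fold_rs[lab], abs=1e-10)


class TestConsensusMap:
    def test_single_component_proportional_to_loading(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(100, 12))
        y = rng.normal(size=100)
        cov = _covariates(100, rng)
        m = fit_pcr_fold(X, y, cov, k=1)
        raw = consensus_feature_map(m, zscore=False)
        np.testing.assert_allclose(raw, m.loadings[:, 0] * m.weights[0], atol=1e-12)

    def test_zero_betas_give_flagged_raw_map(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(60, 8))
        y = rng.normal(size=60)
        cov = _covariates(60, rng)
        m = fit_pcr_fold(X, y, cov, k=2)
        m.weights = np.zeros_like(m.weights)
        with pytest.warns(UserWarning, match="constant"):
            out = consensus_feature_map(m)
        assert np.all(out == 0)

    def test_matches_matrix_composition_and_zscore(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(150, 25))
        y = X[:, 0] + rng.normal(size=150)
        cov = _covariates(150, rng)
        m = fit_pcr_fold(X, y, cov, k=6)
        ref = m.loadings @ m.weights
        z = consensus_feature_map(m)
        np.testing.assert_allclose(z, (ref - ref.mean()) / ref.std(), atol=1e-10)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_fold_averaging(self):
        rng = np.random.default_rng(18)
        maps = []
        models = []
        for s in range(3):
            X = rng.normal(size=(80, 10))
            y = rng.normal(size=80)
            cov = _covariates(80, rng)
            m = fit_pcr_fold(X, y, cov, k=3)
            models.append(m)
            maps.append(m.loadings @ m.weights)
        ref = np.mean(maps, axis=0)
        out = consensus_feature_map(models, zscore=False)
        np.testing.assert_allclose(out, ref, atol=1e-12)


class TestModelFacade:
    def test_results_summary_and_consensus(self):
        rng = np.random.default_rng(19)
        n, p = 150, 20
        ids = [f"s{i:04d}" for i in range(n)]
        X = pd.DataFrame(rng.normal(size=(n, p)), index=ids,
                         columns=[f"p{j}" for j in range(p)])
        f = X.iloc[:, 0].to_numpy()
        y = pd.Series(f + 0.5 * rng.normal(size=n), index=ids)
        cov = _covariates(n, rng)
        model = CrossValidatedPCR(y, X, cov, scheme="kfold", k=5, seed=0)
        res = model.fit(candidate_ks=(2, 5), seed=0)
        tab = res.summary()
        assert "mean" in tab.fold.values
        cmap = res.consensus_map()
        assert list(cmap.index) == list(X.columns)
        full = res.consensus_map(mode="full")
        assert full.shape == cmap.shape
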