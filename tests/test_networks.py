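"""Network means, residualization, clustered bootstrap, bins, quadrants."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from eeanet.cohort import generate_clustered_xy
from eeanet.networks import (
    BootstrapCI,
    bootstrap_diff_ci,
    clustered_bootstrap_ci,
    decile_bin_summary,
    extract_network_means,
    network_regression_compare,
    quadrant_summary,
    residualize_on_covariates,
    zscore,
)


def _cov(n, rng):
    d = pd.DataFrame({
        "subject_id": [f"s{i:04d}" for i in range(n)],
        "site": [f"site{i % 5}" for i in range(n)],
        "family": [f"f{i:04d}" for i in range(n)],
        "age": rng.uniform(9, 11, n),
        "sex": rng.integers(0, 2, n),
        "raceeth": rng.integers(0, 4, n),
        "fd": rng.uniform(0.05, 0.5, n),
    })
    d["age2"] = d.age**2
    d["fd2"] = d.fd**2
    return d


class TestNetworkMeans:
    def test_constant_and_two_feature_networks(self):
        act = pd.DataFrame({"a1": [0.7, 0.7], "a2": [0.7, 0.7],
                            "b1": [1.0, 0.0], "b2": [3.0, 4.0]})
        labels = pd.DataFrame({"parcel_id": ["a1", "a2", "b1", "b2"],
                               "network": ["A", "A", "B", "B"]})
        out = extract_network_means(act, labels)
        np.testing.assert_allclose(out["A"], [0.7, 0.7])
        np.testing.assert_allclose(out["B"], [2.0, 2.0])

    def test_matches_independent_groupby(self):
        rng = np.random.default_rng(0)
        act = pd.DataFrame(rng.normal(size=(50, 20)),
                           columns=[f"p{j}" for j in range(20)])
        nets = [f"N{j % 4}" for j in range(20)]
        labels = pd.DataFrame({"parcel_id": act.columns, "network": nets})
        out = extract_network_means(act, labels)
        for name in set(nets):
            cols = [c for c, n in zip(act.columns, nets) if n == name]
            ref = act[cols].to_numpy().mean(axis=1)
            np.testing.assert_allclose(out[name], ref, atol=1e-12)

    def test_unlabelled_feature_rejected(self):
        act = pd.DataFrame({"p0": [1.0], "mystery": [2.0]})
        labels = pd.DataFrame({"parcel_id": ["p0"], "network": ["A"]})
        with pytest.raises(ValueError, match="mystery"):
            extract_network_means(act, labels)


class TestResidualize:
    def test_orthogonal_variable_is_only_centered(self):
        rng = np.random.default_rng(1)
        n = 4000
        cov = _cov(n, rng)
        x = rng.normal(5.0, 1.0, n)  # independent of all covariates
        out = residualize_on_covariates(pd.DataFrame({"x": x}), cov)["x"]
        assert abs(out.mean()) < 1e-10
        assert np.corrcoef(out, x)[0, 1] > 0.995

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        n = 300
        cov = _cov(n, rng)
        x = cov.age * 0.5 + cov.fd * 2 + rng.normal(size=n)
        out = residualize_on_covariates(pd.DataFrame({"x": x}), cov)["x"]
        from eeanet.prediction import build_covariate_design
        design, _ = build_covariate_design(cov)
        assert np.abs(design.T @ out.to_numpy()).max() < 1e-8

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        n = 200
        cov = _cov(n, rng)
        x = cov.age * 0.3 - cov.sex + rng.normal(size=n)
        ours = residualize_on_covariates(pd.DataFrame({"x": x}), cov)["x"]
        from eeanet.prediction import build_covariate_design
        design, _ = build_covariate_design(cov)
        ref = sm.OLS(x.to_numpy(), design).fit().resid
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_incomplete_rows_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        cov = _cov(20, rng)
        x = pd.DataFrame({"x": rng.normal(size=20)})
        x.iloc[3] = np.nan
        with pytest.warns(UserWarning, match="incomplete"):
            out = residualize_on_covariates(x, cov)
        assert len(out) == 19


class TestClusteredBootstrap:
    def test_degenerate_clustering_matches_iid_bootstrap(self):
        # every subject its own site and family: replicate distribution
        # indistinguishable from the ordinary case-resampling bootstrap
        rng = np.random.default_rng(5)
        n = 150
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        ids = np.array([f"u{i}" for i in range(n)])
        ci = clustered_bootstrap_ci(x, y, ids, ids, n_boot=800, seed=1)

        rng2 = np.random.default_rng(2)
        iid = np.array([
            np.corrcoef(x[idx], y[idx])[0, 1]
            for idx in rng2.integers(0, n, size=(800, n))
        ])
        # recompute our replicate values for the KS comparison
        from eeanet.networks import _cluster_index, _resample_indices
        clusters = _cluster_index(ids, ids)
        rng3 = np.random.default_rng(3)
        ours = []
        for _ in range(800):
            idx = _resample_indices(clusters, rng3)
            ours.append(np.corrcoef(x[idx], y[idx])[0, 1])
        ours = np.array(ours)
        assert ks_2samp(ours, iid).pvalue > 0.01
        assert ci.lower < 0.5 < ci.upper

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            clustered_bootstrap_ci(np.ones(50), np.random.default_rng(0).normal(size=50),
                                   np.arange(50).astype(str), np.arange(50).astype(str))

    def test_estimate_inside_ci_and_reproducible(self):
        x, y, si, fa = generate_clustered_xy(8, 10, 2, 0.3, seed=3)
        c1 = clustered_bootstrap_ci(x, y, si, fa, n_boot=400, seed=9)
        c2 = clustered_bootstrap_ci(x, y, si, fa, n_boot=400, seed=9)
        assert c1 == c2
        assert c1.lower <= c1.estimate <= c1.upper

    def test_clustered_ci_wider_than_iid_when_dependence_strong(self):
        x, y, si, fa = generate_clustered_xy(8, 5, 5, 0.4, seed=4,
                                             site_share=0.4, family_share=0.3)
        ids = np.arange(len(x)).astype(str)
        clustered = clustered_bootstrap_ci(x, y, si, fa, n_boot=800, seed=0)
        iid = clustered_bootstrap_ci(x, y, ids, ids, n_boot=800, seed=0)
        assert (clustered.upper - clustered.lower) > (iid.upper - iid.lower)


class TestDiffCI:
    def test_identical_predictors_give_zero_width(self):
        rng = np.random.default_rng(6)
        n = 120
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        ids = np.arange(n).astype(str)
        ci = bootstrap_diff_ci(x, y, x, ids, ids, n_boot=300, seed=0)
        assert ci.lower == pytest.approx(0.0, abs=1e-12)
        assert ci.upper == pytest.approx(0.0, abs=1e-12)

    def test_sign_invariance_of_absolute_difference(self):
        rng = np.random.default_rng(7)
        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 0.4 * x1 + 0.2 * x2 + rng.normal(size=n)
        ids = np.arange(n).astype(str)
        a = bootstrap_diff_ci(x1, y, x2, ids, ids, n_boot=300, seed=5)
        b = bootstrap_diff_ci(-x1, y, x2, ids, ids, n_boot=300, seed=5)
        assert a.lower == pytest.approx(b.lower) and a.upper == pytest.approx(b.upper)

    def test_covers_planted_difference(self):
        # moderate simulation: planted |r1| - |r2| = 0.2 at n = 2000
        rng = np.random.default_rng(8)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        e = rng.normal(size=n)
        # y correlated 0.5 with x1 and 0.3 with x2
        y = 0.5 * x1 + 0.3 * x2 + e * np.sqrt(1 - 0.25 - 0.09)
        ids = np.arange(n).astype(str)
        ci = bootstrap_diff_ci(x1, y, x2, ids, ids, n_boot=600, seed=1)
        assert ci.contains(0.2)


class TestRegressionCompare:
    def _tables(self, n, rng, k=4):
        e = rng.normal(size=n)
        nets = {}
        for j, name in enumerate(["FPN", "DAN", "SMN", "VIS"][:k]):
            b = (0.4, 0.25, -0.3, 0.0)[j]
            nets[name] = b * e + rng.normal(size=n) * np.sqrt(1 - b * b)
        return pd.DataFrame(nets), e

    def test_full_model_never_below_subset_in_sample(self):
        rng = np.random.default_rng(9)
        nm, e = self._tables(500, rng)
        ids = np.arange(500).astype(str)
        out = network_regression_compare(nm, e, True, ids, ids,
                                         subset=("FPN", "DAN"), n_boot=100, seed=0)
        assert out["full"].estimate >= out["subset"].estimate - 1e-12

    def test_single_network_subset_equals_bivariate_r(self):
        rng = np.random.default_rng(10)
        nm, e = self._tables(400, rng)
        ids = np.arange(400).astype(str)
        out = network_regression_compare(nm, e, True, ids, ids,
                                         subset=("FPN",), n_boot=100, seed=0)
        assert out["subset"].estimate == pytest.approx(
            abs(np.corrcoef(nm["FPN"], e)[0, 1]), abs=1e-10)

    def test_missing_subset_network_rejected(self):
        rng = np.random.default_rng(11)
        nm, e = self._tables(100, rng, k=2)
        ids = np.arange(100).astype(str)
        with pytest.raises(ValueError, match="absent"):
            network_regression_compare(nm, e, True, ids, ids,
                                       subset=("FPN", "SMN"), n_boot=50, seed=0)

    def test_unresidualized_inputs_rejected(self):
        with pytest.raises(ValueError, match="residualize"):
            network_regression_compare(pd.DataFrame({"FPN": [1.0]}), [1.0],
                                       False, ["a"], ["a"])


class TestDecileBins:
    def test_bin_sizes_and_remainder(self):
        rng = np.random.default_rng(12)
        out = decile_bin_summary(rng.normal(size=20), {"0": rng.normal(size=20)})
        assert out.n.tolist() == [2] * 10
        out = decile_bin_summary(rng.normal(size=23), {"0": rng.normal(size=23)})
        assert out.n.tolist() == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_monotone_transform_gives_increasing_means(self):
        rng = np.random.default_rng(13)
        e = rng.normal(size=200)
        act = 2 * e + 1  # deterministic increasing function
        out = decile_bin_summary(e, {"2": act})
        means = out.sort_values("bin")["mean"].to_numpy()
        assert np.all(np.diff(means) > 0)
        assert out.slope.iloc[0] > 0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            decile_bin_summary(np.arange(5.0), {"0": np.arange(5.0)})


class TestQuadrants:
    def test_constructed_ordering(self):
        rng = np.random.default_rng(14)
        n = 500
        a0 = rng.normal(size=n)
        a2 = 0.6 * a0 + 0.8 * rng.normal(size=n)
        slope, intercept = np.polyfit(zscore(a0), zscore(a2), 1)
        eea = zscore(a2) - (intercept + slope * zscore(a0))  # exactly the residual
        out = quadrant_summary(a0, a2, eea).set_index("quadrant")
        assert out.loc["upper_left", "mean_eea_z"] > out.loc["lower_right", "mean_eea_z"]

    def test_null_relations_give_near_zero_means(self):
        rng = np.random.default_rng(15)
        n = 4000
        out = quadrant_summary(rng.normal(size=n), rng.normal(size=n),
                               rng.normal(size=n))
        se = 1.0 / np.sqrt(n / 4)
        assert np.abs(out.mean_eea_z).max() < 3 * se

    def test_matches_brute_force_classification(self):
        rng = np.random.default_rng(16)
        n = 200
        a0 = rng.normal(size=n)
        a2 = 0.5 * a0 + rng.normal(size=n)
        e = rng.normal(size=n)
        out = quadrant_summary(a0, a2, e).set_index("quadrant")
        z0, z2, ze = zscore(a0), zscore(a2), zscore(e)
        slope, intercept = np.polyfit(z0, z2, 1)
        counts = {"upper_left": 0, "upper_right": 0, "lower_left": 0, "lower_right": 0}
        sums = dict.fromkeys(counts, 0.0)
        for i in range(n):
            vert = "upper" if z2[i] > intercept + slope * z0[i] else "lower"
            horiz = "right" if z0[i] > 0 else "left"
            key = f"{vert}_{horiz}"
            counts[key] += 1
            sums[key] += ze[i]
        for q in counts:
            assert out.loc[q, "n"] == counts[q]
            assert out.loc[q, "mean_eea_z"] == pytest.approx(sums[q] / counts[q])

    def test_zscore_idempotent_and_constant_rejected(self):
        rng = np.random.default_rng(17)
        x = rng.normal(2.0, 3.0, 100)
        np.testing.assert_allclose(zscore(zscore(x)), zscore(x), atol=1e-12)
        with pytest.raises(ValueError):
            zscore(np.ones(10))
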