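"""Percept-mapping statistics against direct-formula oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nlsound.perception_mapping import (
    CollinearPredictorsError,
    RatingsTable,
    ahc_ward,
    category_anova,
    cluster_percept_comparison,
    homogeneity_tally,
    multiple_regression,
    pca,
    percept_intercorrelation,
    simple_regressions,
)
from nlsound.salience import FeatureTable
from oracles import (
    anova_f_sums_of_squares,
    ols_normal_equations,
    pearson_formula,
    scipy_linkage_merge_sequence,
    tukey_mean_diffs,
    ward_bruteforce,
)


def _ratings_from(df):
    return RatingsTable(df)


def _table_from(arr, cols, domain="temporal"):
    df = pd.DataFrame(arr, columns=cols,
                      index=[f"s{i}" for i in range(len(arr))])
    return FeatureTable(df, {c: domain for c in cols})


class TestPerceptIntercorrelation:
    def test_exact_negative_familiarity_complexity_flagged(self, rng):
        c = rng.normal(4, 0.5, 30)
        a = 0.8 - 0.1 * (c - 4) + 0.01 * rng.normal(size=30)
        df = pd.DataFrame({"complexity": c, "pleasantness":
                           rng.normal(4, 0.5, 30),
                           "familiarity": 8 - c,
                           "accuracy": np.clip(a, 0, 1)})
        corr, flags = percept_intercorrelation(_ratings_from(df))
        assert abs(corr.r.loc["complexity", "familiarity"] + 1.0) < 1e-12
        assert "familiarity" in flags

    def test_independent_percepts_weakly_correlated(self, rng):
        df = pd.DataFrame(rng.normal(4, 1, size=(200, 3)),
                          columns=["complexity", "pleasantness",
                                   "familiarity"])
        df["accuracy"] = rng.uniform(size=200)
        corr, flags = percept_intercorrelation(_ratings_from(df))
        off = corr.r.values[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.2
        assert flags == []

    def test_matches_formula_oracle_on_hand_table(self):
        df = pd.DataFrame({"complexity": [1.0, 3, 2, 5],
                           "pleasantness": [2.0, 2, 4, 1],
                           "familiarity": [5.0, 3, 4, 1],
                           "accuracy": [0.9, 0.4, 0.5, 0.1]})
        corr, _ = percept_intercorrelation(_ratings_from(df))
        for a in df.columns:
            for b in df.columns:
                assert abs(corr.r.loc[a, b]
                           - pearson_formula(df[a], df[b])) < 1e-12


class TestSimpleRegressions:
    def test_noiseless_percept_gives_unit_correlation(self, rng):
        x = rng.normal(size=30)
        table = _table_from(x[:, None], ["m"])
        ratings = _ratings_from(pd.DataFrame(
            {"complexity": 4 + 0.5 * (x - x.mean()) / x.std()},
            index=table.data.index))
        out = simple_regressions(table, ratings, percepts=("complexity",))
        assert abs(out.loc[0, "r"] - 1.0) < 1e-9
        assert out.loc[0, "p"] < 1e-10

    def test_independent_percept_weak(self, rng):
        x = rng.normal(size=200)
        table = _table_from(x[:, None], ["m"])
        ratings = _ratings_from(pd.DataFrame(
            {"complexity": rng.normal(4, 1, 200)},
            index=table.data.index))
        out = simple_regressions(table, ratings, percepts=("complexity",))
        assert abs(out.loc[0, "r"]) < 0.2

    def test_slope_intercept_match_normal_equations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
        table = _table_from(x[:, None], ["m"])
        ratings = _ratings_from(pd.DataFrame(
            {"accuracy": y / 20}, index=table.data.index))
        out = simple_regressions(table, ratings, percepts=("accuracy",))
        beta, _ = ols_normal_equations(x[:, None], y / 20)
        assert abs(out.loc[0, "intercept"] - beta[0]) < 1e-10
        assert abs(out.loc[0, "slope"] - beta[1]) < 1e-10


class TestMultipleRegression:
    def test_exact_linear_combination_recovered(self, rng):
        x = rng.normal(size=(40, 2))
        y = 2.0 * x[:, 0] - 1.0 * x[:, 1]
        table = _table_from(x, ["m1", "m2"])
        ratings = _ratings_from(pd.DataFrame(
            {"complexity": 4 + y / (3 * np.abs(y).max())},
            index=table.data.index))
        res = multiple_regression(table, ["m1", "m2"], ratings,
                                  "complexity")
        assert abs(res.r_squared - 1.0) < 1e-9
        scale = res.coefficients["m1"] / 2.0
        assert abs(res.coefficients["m2"] / scale + 1.0) < 1e-6

    def test_duplicated_predictor_raises(self, rng):
        x = rng.normal(size=(20, 1))
        table = _table_from(np.hstack([x, x]), ["m1", "m2"])
        ratings = _ratings_from(pd.DataFrame(
            {"complexity": rng.normal(4, 1, 20)}, index=table.data.index))
        with pytest.raises(CollinearPredictorsError):
            multiple_regression(table, ["m1", "m2"], ratings, "complexity")

    def test_cross_domain_predictors_rejected_by_default(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["t", "s"],
                          index=[f"s{i}" for i in range(20)])
        table = FeatureTable(df, {"t": "temporal", "s": "spectral"})
        ratings = _ratings_from(pd.DataFrame(
            {"complexity": rng.normal(4, 1, 20)}, index=df.index))
        with pytest.raises(ValueError, match="domains"):
            multiple_regression(table, ["t", "s"], ratings, "complexity")
        res = multiple_regression(table, ["t", "s"], ratings, "complexity",
                                  enforce_same_domain=False)
        assert 0.0 <= res.r_squared <= 1.0

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        table = _table_from(x, ["m1", "m2"])
        ratings = _ratings_from(pd.DataFrame(
            {"accuracy": (y - y.min()) / (np.ptp(y) + 1)},
            index=table.data.index))
        res = multiple_regression(table, ["m1", "m2"], ratings, "accuracy")
        beta, r2 = ols_normal_equations(x, ratings.data["accuracy"])
        assert abs(res.r_squared - r2) < 1e-10
        assert abs(res.coefficients["intercept"] - beta[0]) < 1e-10
        assert abs(res.coefficients["m1"] - beta[1]) < 1e-10
        assert abs(res.coefficients["m2"] - beta[2]) < 1e-10

    def test_parameter_recovery_with_planted_r2(self, rng):
        for planted in (0.3, 0.8):
            hits = 0
            for seed in range(20):
                local = np.random.default_rng(seed)
                x = local.normal(size=(60, 2))
                beta = np.array([0.6, -0.4])
                signal = x @ beta
                noise_sd = signal.std() * np.sqrt((1 - planted) / planted)
                y = signal + local.normal(0, noise_sd, 60)
                table = _table_from(x, ["m1", "m2"])
                ratings = _ratings_from(pd.DataFrame(
                    {"complexity": 4 + y / (np.abs(y).max() / 2.9)},
                    index=table.data.index))
                res = multiple_regression(table, ["m1", "m2"], ratings,
                                          "complexity")
                if abs(res.r_squared - planted) <= 0.1:
                    hits += 1
                # each coefficient within 2 SEs of its (rescaled) truth
                scale = (2.9 / np.abs(y).max())
                for name, b_true in zip(["m1", "m2"], beta):
                    err = abs(res.coefficients[name] - scale * b_true)
                    assert err <= 2 * res.coef_se[name] + 1e-9
            assert hits >= 16

    def test_type_one_error_rate_near_alpha(self):
        """Independent ratings trigger p<0.05 in ~5% of regressions."""
        rng = np.random.default_rng(77)
        x = rng.normal(size=(60, 5))
        table = _table_from(x, [f"m{i}" for i in range(5)])
        n_sig = n_tot = 0
        for seed in range(200):
            local = np.random.default_rng(1000 + seed)
            ratings = _ratings_from(pd.DataFrame(
                {"complexity": local.normal(4, 1, 60),
                 "pleasantness": local.normal(4, 1, 60),
                 "accuracy": local.uniform(size=60)},
                index=table.data.index))
            out = simple_regressions(table, ratings)
            n_sig += (out["p"] < 0.05).sum()
            n_tot += len(out)
        rate = n_sig / n_tot
        assert 0.03 <= rate <= 0.07


class TestCategoryAnova:
    def test_identical_groups_give_zero_f(self):
        vals = pd.Series([1.0, 1, 1, 2, 2, 2][::1])
        vals[:] = 3.0
        cats = pd.Series(["a", "a", "a", "b", "b", "b"])
        res = category_anova(vals, cats)
        assert res.f == 0.0
        assert res.significant_pairs == 0

    def test_planted_shift_yields_exactly_two_significant_pairs(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                               rng.normal(5, 1, 20)])
        cats = pd.Series(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        res = category_anova(pd.Series(vals), cats)
        assert res.significant_pairs == 2
        sig = res.tukey[res.tukey["significant"]]
        assert set(map(tuple, sig[["group_a", "group_b"]].values)) == \
            {("a", "c"), ("b", "c")}

    def test_f_matches_sums_of_squares_oracle(self):
        groups = [[6.0, 8, 4, 5, 3], [8.0, 12, 9, 11, 6],
                  [13.0, 9, 11, 8, 12]]
        vals = pd.Series(np.concatenate(groups))
        cats = pd.Series(sum([[g] * 5 for g in "abc"], []))
        res = category_anova(vals, cats)
        assert abs(res.f - anova_f_sums_of_squares(groups)) < 1e-9
        assert [round(d, 10) for d in res.tukey["diff"]] == \
            [round(d, 10) for d in tukey_mean_diffs(groups)]

    def test_undersized_category_dropped_with_warning(self, rng):
        vals = pd.Series(rng.normal(size=11))
        cats = pd.Series(["a"] * 5 + ["b"] * 5 + ["tiny"])
        with pytest.warns(UserWarning, match="tiny"):
            res = category_anova(vals, cats)
        assert res.dropped_groups == ["tiny"]
        assert res.groups_used == ["a", "b"]

    def test_fewer_than_two_usable_groups_raises(self, rng):
        vals = pd.Series(rng.normal(size=3))
        cats = pd.Series(["a", "a", "b"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                category_anova(vals, cats)

    def test_brown_forsythe_flags_unequal_spread(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 30),
                               rng.normal(0, 5.0, 30)])
        cats = pd.Series(["a"] * 30 + ["b"] * 30)
        res = category_anova(pd.Series(vals), cats)
        assert res.brown_forsythe_p < 0.05
        assert res.unreliable


class TestHomogeneityTally:
    def test_trivial_bounds_and_additivity(self):
        rng = np.random.default_rng(3)
        results = []
        for shift in (0.0, 5.0, 5.0):
            vals = np.concatenate([rng.normal(0, 1, 15),
                                   rng.normal(shift, 1, 15),
                                   rng.normal(0, 1, 15)])
            cats = pd.Series(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
            results.append(category_anova(pd.Series(vals), cats))
        tally = homogeneity_tally(results, k=3)
        assert tally["possible"] == 3 * 3
        assert tally["observed"] == sum(r.significant_pairs
                                        for r in results)
        assert tally["ratio"] == tally["observed"] / tally["possible"]
        assert homogeneity_tally([], 3)["ratio"] == 0.0


class TestPCA:
    def test_two_variable_closed_form(self, rng):
        # construct sample correlation exactly rho via Gram-Schmidt
        rho = 0.6
        n = 200
        u = rng.normal(size=(n, 2))
        u -= u.mean(0)
        q, _ = np.linalg.qr(u)
        x1 = q[:, 0]
        x2 = rho * q[:, 0] + np.sqrt(1 - rho**2) * q[:, 1]
        res = pca(pd.DataFrame({"a": x1, "b": x2}))
        assert abs(res.explained[0] - (1 + rho) / 2) < 1e-9

    def test_explained_fractions_sum_to_one(self, rng):
        res = pca(pd.DataFrame(rng.normal(size=(30, 4)),
                               columns=list("abcd")))
        assert abs(res.explained.sum() - 1.0) < 1e-9
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        res = pca(df)
        x = (df - df.mean()) / df.std(ddof=1)
        evals, evecs = np.linalg.eigh(np.cov(x.values, rowvar=False))
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        for j in range(3):
            v = evecs[:, j]
            got = res.loadings.values[:, j]
            assert min(np.abs(got - v).max(), np.abs(got + v).max()) < 1e-9

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 5)),
                          columns=[f"m{i}" for i in range(5)])
        res = pca(df)
        load = res.loadings.values
        assert np.abs(load.T @ load - np.eye(5)).max() < 1e-9
        x = ((df - df.mean()) / df.std(ddof=1)).values
        recon = res.scores.values @ load.T
        assert np.abs(recon - x).max() < 1e-8

    def test_sign_convention_deterministic(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        res = pca(df)
        for j in range(3):
            col = res.loadings.values[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            pca(df)


class TestWardClustering:
    def test_k_equals_n_gives_singletons(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 2)))
        assign = ahc_ward(df, k=6)
        assert assign.labels.nunique() == 6

    def test_two_well_separated_blobs_perfectly_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        a = rng.normal(0, 1, size=(20, 3))
        b = rng.normal(10, 1, size=(20, 3))
        df = pd.DataFrame(np.vstack([a, b]))
        truth = [0] * 20 + [1] * 20
        assign = ahc_ward(df, k=2)
        assert adjusted_rand_score(truth, assign.labels) == 1.0

    def test_merge_sequence_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            x = rng.normal(size=(n, int(rng.integers(1, 4))))
            got = scipy_linkage_merge_sequence(x)
            want = ward_bruteforce(x)
            for (ga, gb, gh), (wa, wb, wh) in zip(got, want):
                assert {ga, gb} == {wa, wb}
                assert abs(gh - wh) < 1e-8

    def test_k_out_of_range_raises(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            ahc_ward(df, k=6)


class TestClusterPerceptComparison:
    def _features(self, rng, n=60):
        data = rng.normal(size=(n, 4))
        cols = ["t1", "t2", "s1", "s2"]
        df = pd.DataFrame(data, columns=cols,
                          index=[f"s{i}" for i in range(n)])
        return FeatureTable(df, {"t1": "temporal", "t2": "temporal",
                                 "s1": "spectral", "s2": "spectral"})

    def test_planted_spectral_structure_detected_in_spectral_space(self,
                                                                   rng):
        features = self._features(rng)
        hits_spec = hits_temp = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            z = features.data[["s1", "s2"]].to_numpy()
            z = (z - z.mean(0)) / z.std(0)
            y = z @ [0.8, -0.6] + local.normal(0, 0.4, len(z))
            ratings = _ratings_from(pd.DataFrame(
                {"complexity": 4 + y / (np.abs(y).max() / 2.9)},
                index=features.data.index))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spec = cluster_percept_comparison(
                    features, ratings, "spectral", [3],
                    percepts=("complexity",))
                temp = cluster_percept_comparison(
                    features, ratings, "temporal", [3],
                    percepts=("complexity",))
            if spec[3]["anova"]["complexity"].p < 0.05:
                hits_spec += 1
            if temp[3]["anova"]["complexity"].p < 0.05:
                hits_temp += 1
        assert hits_spec > 10
        assert hits_spec > hits_temp

    def test_null_ratings_rarely_significant(self, rng):
        features = self._features(rng)
        hits = total = 0
        for seed in range(30):
            local = np.random.default_rng(500 + seed)
            ratings = _ratings_from(pd.DataFrame(
                {"complexity": local.normal(4, 1, 60)},
                index=features.data.index))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = cluster_percept_comparison(
                    features, ratings, "temporal", [3],
                    percepts=("complexity",))
            total += 1
            hits += out[3]["anova"]["complexity"].p < 0.05
        assert hits / total <= 0.2

    def test_all_singletons_level_skipped_with_warning(self, rng):
        features = self._features(rng, n=12)
        ratings = _ratings_from(pd.DataFrame(
            {"complexity": rng.normal(4, 0.5, 12),
             "pleasantness": rng.normal(4, 0.5, 12),
             "accuracy": rng.uniform(size=12)},
            index=features.data.index))
        with pytest.warns(UserWarning, match="usable clusters"):
            out = cluster_percept_comparison(features, ratings,
                                             "temporal", [12])
        assert out[12]["anova"] == {}
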