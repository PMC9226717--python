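"""Metabolite screen: normalization, imputation, Welch t, PLS-DA VIP, calls, QC."""

import numpy as np
import pandas as pd
import pytest

from milletol import dem, pls
from milletol.exceptions import ConfigError, DegenerateInputError


def labelled_matrix(rng, n_features, n_per_group, effect_idx=(), effect=1.0):
    cols = [f"C{i+1}" for i in range(n_per_group)] + [
        f"T{i+1}" for i in range(n_per_group)
    ]
    X = rng.standard_normal((n_features, 2 * n_per_group))
    for i in effect_idx:
        X[i, n_per_group:] += effect
    frame = pd.DataFrame(X, index=[f"m{i}" for i in range(n_features)], columns=cols)
    y = np.array(["control"] * n_per_group + ["treatment"] * n_per_group)
    return frame, y


class TestNormalize:
    def test_proportions(self):
        peaks = pd.DataFrame({"s": [1.0, 3.0]}, index=["a", "b"])
        out = dem.total_area_normalize(peaks)
        assert out["s"].tolist() == [0.25, 0.75]

    def test_idempotent_and_scale_invariant(self, rng):
        peaks = pd.DataFrame(np.exp(rng.standard_normal((5, 4))))
        once = dem.total_area_normalize(peaks)
        pd.testing.assert_frame_equal(once, dem.total_area_normalize(once))
        pd.testing.assert_frame_equal(
            once, dem.total_area_normalize(peaks * [2.0, 7.0, 0.5, 100.0])
        )

    def test_within_sample_ratios_preserved(self, rng):
        peaks = pd.DataFrame(np.exp(rng.standard_normal((5, 4))))
        out = dem.total_area_normalize(peaks)
        for c in peaks.columns:
            assert np.allclose(
                out[c] / out[c].iloc[0], peaks[c] / peaks[c].iloc[0]
            )

    def test_zero_column_rejected(self):
        with pytest.raises(DegenerateInputError):
            dem.total_area_normalize(pd.DataFrame({"s": [0.0, 0.0]}))


class TestImpute:
    def test_half_min(self):
        peaks = pd.DataFrame([[2.0, np.nan, 4.0]], index=["m"], columns=list("abc"))
        out, log = dem.impute_missing(peaks)
        assert out.loc["m"].tolist() == [2.0, 1.0, 4.0]
        assert log["action"].tolist() == ["imputed_half_min"]

    def test_zero_strategy_and_identity(self):
        peaks = pd.DataFrame([[2.0, np.nan]], index=["m"], columns=list("ab"))
        out, _ = dem.impute_missing(peaks, strategy="zero")
        assert out.loc["m"].tolist() == [2.0, 0.0]
        complete = pd.DataFrame([[1.0, 2.0]], index=["m"], columns=list("ab"))
        same, log = dem.impute_missing(complete)
        pd.testing.assert_frame_equal(same, complete)
        assert log.empty

    def test_fully_missing_dropped_with_log(self):
        peaks = pd.DataFrame(
            [[np.nan, np.nan], [1.0, 2.0]], index=["gone", "kept"], columns=list("ab")
        )
        out, log = dem.impute_missing(peaks)
        assert list(out.index) == ["kept"]
        assert ("gone", "dropped") in set(zip(log["metabolite"], log["action"]))

    def test_unknown_strategy(self):
        with pytest.raises(ConfigError):
            dem.impute_missing(pd.DataFrame([[1.0]]), strategy="median")


class TestWelch:
    def test_identical_groups(self):
        t, df, p = dem.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swap_flips_sign(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(1, 2, 6)
        ta, _, pa = dem.welch_t(a, b)
        tb, _, pb = dem.welch_t(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)

    def test_hand_computation(self):
        a = np.array([3.1, 2.9, 3.4, 3.0])
        b = np.array([2.1, 2.5, 2.2, 2.0])
        t, df, p = dem.welch_t(a, b)
        sa, sb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sa + sb)
        df_hand = (sa + sb) ** 2 / (sa**2 / 3 + sb**2 / 3)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand))

    def test_degenerate_conventions(self):
        t, _, p = dem.welch_t([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0
        t, _, p = dem.welch_t([3.0, 3.0], [2.0, 2.0])
        assert p == 0.0 and t == np.inf


class TestPLSDA:
    def test_perfect_predictor_explains_all_y_variance(self):
        n = 20
        y = np.array(["a"] * 10 + ["b"] * 10)
        X = pd.DataFrame({"inf": np.where(y == "a", -2.0, 4.0)})
        m = pls.pls_da_fit(X, y, ncomp=1)
        yc = np.where(y == "a", -1.0, 1.0)
        yc = yc - yc.mean()
        assert m.ssy[0] == pytest.approx((yc**2).sum(), abs=1e-9)

    def test_first_weight_is_covariance_direction(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 6)))
        y = np.array(["a", "b"] * 15)
        m = pls.pls_da_fit(X, y, ncomp=2)
        Xs = (X - X.mean()) / X.std(ddof=1)
        yv = np.where(y == "a", -1.0, 1.0)
        yc = yv - yv.mean()
        w_closed = Xs.T @ yc
        w_closed /= np.linalg.norm(w_closed)
        assert np.allclose(m.weights[:, 0], w_closed, atol=1e-9)

    def test_scores_orthogonal_and_weights_unit(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 8)))
        y = np.array(["a"] * 12 + ["b"] * 13)
        m = pls.pls_da_fit(X, y, ncomp=3)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6
        assert np.allclose(np.linalg.norm(m.weights, axis=0), 1.0, atol=1e-9)

    def test_matches_sklearn_first_component(self, rng):
        """Independent cross-check against scikit-learn's PLS weights."""
        from sklearn.cross_decomposition import PLSRegression

        X = pd.DataFrame(rng.standard_normal((30, 5)))
        y = np.array(["a", "b"] * 15)
        m = pls.pls_da_fit(X, y, ncomp=2)
        sk = PLSRegression(n_components=2, scale=True).fit(
            X, np.where(y == "a", -1.0, 1.0)
        )
        w_sk = sk.x_weights_[:, 0]
        w_sk = w_sk * np.sign(w_sk[np.argmax(np.abs(w_sk))])
        w = m.weights[:, 0]
        w = w * np.sign(w[np.argmax(np.abs(w))])
        assert np.allclose(w, w_sk, atol=1e-6)

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 3)))
        with pytest.raises(ConfigError):
            pls.pls_da_fit(X, np.array(["a"] * 10))

    def test_zero_variance_column_named(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["ok", "flat"])
        X["flat"] = 5.0
        with pytest.raises(DegenerateInputError, match="flat"):
            pls.pls_da_fit(X, np.array(["a", "b"] * 5))


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        p = 4
        m = pls.PLSDAModel(
            weights=np.full((p, 1), 1 / np.sqrt(p)),
            scores=np.zeros((8, 1)),
            x_loadings=np.zeros((p, 1)),
            y_loadings=np.array([1.0]),
            ssy=np.array([2.0]),
            features=pd.Index(list("abcd")),
        )
        assert np.allclose(pls.vip(m), 1.0)

    def test_sum_of_squares_identity(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 7)))
        y = np.array(["a", "b"] * 15)
        v = pls.vip(pls.pls_da_fit(X, y, ncomp=2))
        assert (v**2).sum() == pytest.approx(7.0, abs=1e-6)

    def test_informative_vs_noise(self, rng):
        """p=2: the column tracking the classes should out-rank pure noise."""
        wins = 0
        for s in range(100):
            r = np.random.default_rng(s)
            y = np.array(["a"] * 20 + ["b"] * 20)
            X = pd.DataFrame(
                {
                    "inf": np.where(y == "a", 0.0, 5.0) + r.standard_normal(40),
                    "noise": r.standard_normal(40),
                }
            )
            v = pls.vip(pls.pls_da_fit(X, y, ncomp=1))
            wins += v["inf"] > 1 > v["noise"]
        assert wins >= 95

    def test_feature_order_invariance(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 5)), columns=list("abcde"))
        y = np.array(["a", "b"] * 10)
        v = pls.vip(pls.pls_da_fit(X, y, ncomp=2))
        v_perm = pls.vip(pls.pls_da_fit(X[list("ecabd")], y, ncomp=2))
        pd.testing.assert_series_equal(v.sort_index(), v_perm.sort_index())


class TestCVVIP:
    def test_deterministic_for_fixed_seed(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 5)))
        y = np.array(["a", "b"] * 10)
        v1 = pls.cv_vip(X, y, folds=5, repeats=3, seed=7)
        v2 = pls.cv_vip(X, y, folds=5, repeats=3, seed=7)
        pd.testing.assert_series_equal(v1, v2)

    def test_leave_one_out_ignores_seed(self, rng):
        X = pd.DataFrame(rng.standard_normal((8, 4)))
        y = np.array(["a", "b"] * 4)
        v1 = pls.cv_vip(X, y, folds=8, repeats=1, seed=0)
        v2 = pls.cv_vip(X, y, folds=8, repeats=1, seed=999)
        pd.testing.assert_series_equal(v1, v2)

    def test_cv_close_to_full_fit_on_strong_signal(self, rng):
        y = np.array(["a"] * 20 + ["b"] * 20)
        X = pd.DataFrame(rng.standard_normal((40, 10)))
        X.iloc[:, 0] += np.where(y == "a", 0.0, 4.0)
        X.iloc[:, 1] += np.where(y == "a", 0.0, 3.0)
        full = pls.vip(pls.pls_da_fit(X, y, ncomp=2))
        cv = pls.cv_vip(X, y, folds=7, repeats=10, ncomp=2, seed=1)
        assert (cv - full).abs().max() < 0.2


class TestCalls:
    @pytest.mark.parametrize(
        "fc,v,expected",
        [
            (2.0, 1.3, "up"),
            (0.5, 1.3, "down"),       # 0.5 <= 1/1.5
            (1.6, 0.9, "unchanged"),  # fails VIP gate
            (1.4, 2.0, "unchanged"),  # fails FC gate
        ],
    )
    def test_gates(self, fc, v, expected):
        call, summary = dem.call_dems(
            pd.Series([fc], index=["m"]), pd.Series([v], index=["m"])
        )
        assert call["m"] == expected


class TestQC:
    def test_duplicated_samples_have_spearman_one(self, rng):
        col = np.exp(rng.standard_normal(30))
        peaks = pd.DataFrame({"s1": col, "s2": col, "s3": np.exp(rng.standard_normal(30))})
        rep = dem.qc_repeatability(peaks, qc_samples=["s1", "s2"])
        assert rep.spearman.loc["s1", "s2"] == pytest.approx(1.0)
        assert rep.qc_min_spearman == pytest.approx(1.0)

    def test_independent_columns_weakly_correlated(self, rng):
        peaks = pd.DataFrame(
            np.exp(rng.standard_normal((200, 4))), columns=list("abcd")
        )
        rep = dem.qc_repeatability(peaks)
        off = rep.spearman.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.3

    def test_pca_preserves_sample_distances(self, rng):
        from scipy import stats as ss
        from scipy.spatial.distance import pdist

        # 3 latent dimensions -> 3 PCs capture essentially all variance
        latent = rng.standard_normal((8, 3))
        load = rng.standard_normal((3, 100))
        X = (latent @ load) + 0.001 * rng.standard_normal((8, 100))
        peaks = pd.DataFrame(X.T + 10.0, columns=[f"s{i}" for i in range(8)])
        rep = dem.qc_repeatability(peaks)
        assert rep.explained_variance_ratio.sum() >= 0.99
        z = peaks.T.to_numpy()
        z = (z - z.mean(0)) / z.std(0)
        rho = ss.spearmanr(pdist(rep.pca_coordinates), pdist(z)).statistic
        assert rho >= 0.99


class TestPipeline:
    def test_end_to_end_shapes_and_summary(self, rng):
        from milletol import simulate

        peaks, groups, _ = simulate.simulate_metabolites(
            n_metabolites=40, seed=11, missing_rate=0.05
        )
        table, summary = dem.dem_pipeline(peaks, groups, seed=3)
        assert {"fc", "pvalue", "vip", "call"} <= set(table.columns)
        assert summary.total == summary.up + summary.down
        assert (table["fc"] > 0).all()
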