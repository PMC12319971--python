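"""Association statistics: VAS change tests, SIMPLS PLS, correlations,
median split, order-effect regression, paired t."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainstates.association_stats import (
    median_split,
    order_effect_regression,
    paired_ttest,
    pearson_with_df,
    pls2,
    vas_change_and_tests,
)
from brainstates.synthetic_data import generate_vas


def simpls_oracle(X, Y, A):
    """Literal SIMPLS (de Jong 1993) using an eigendecomposition route,
    independent of the package implementation."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X0 = X - X.mean(0)
    Y0 = Y - Y.mean(0)
    S = X0.T @ Y0
    n, p = X.shape
    P = np.zeros((p, A))
    Q = np.zeros((Y.shape[1], A))
    T = np.zeros((n, A))
    V = np.zeros((p, A))
    for a in range(A):
        evals, evecs = np.linalg.eigh(S @ S.T)
        r = evecs[:, np.argmax(evals)]
        t = X0 @ r
        t -= t.mean()
        t /= np.linalg.norm(t)
        P[:, a] = X0.T @ t
        Q[:, a] = Y0.T @ t
        T[:, a] = t
        v = P[:, a].copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ P[:, a])
        v /= np.linalg.norm(v)
        V[:, a] = v
        S = S - np.outer(v, v @ S)
    return P, Q, T


def _fix_signs(M, ref_loadings):
    signs = np.sign(ref_loadings[np.argmax(np.abs(ref_loadings), axis=0), np.arange(ref_loadings.shape[1])])
    signs[signs == 0] = 1
    return M * signs


class TestVASChangeTests:
    def _frames(self, dmt, pcb):
        items = [f"item_{j + 1:02d}" for j in range(dmt.shape[1])]
        idx = [f"sub-{i + 1:02d}" for i in range(dmt.shape[0])]
        return (
            pd.DataFrame(dmt, index=idx, columns=items),
            pd.DataFrame(pcb, index=idx, columns=items),
        )

    def test_identical_conditions_no_rejections(self, rng):
        vals = rng.uniform(0, 1, (10, 5))
        dmt, pcb = self._frames(vals, vals.copy())
        res = vas_change_and_tests(dmt, pcb)
        assert (res.change.to_numpy() == 0).all()
        assert not res.rejected.any()

    def test_planted_shift_detected_in_most_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pcb = np.clip(0.3 + 0.05 * rng.standard_normal((14, 10)), 0, 1)
            dmt = pcb + 0.05 * rng.standard_normal((14, 10))
            dmt[:, 4] += 0.5
            res = vas_change_and_tests(*self._frames(np.clip(dmt, 0, 1), pcb))
            hits += bool(res.rejected.iloc[4])
        assert hits >= 19

    def test_change_bounded(self, rng):
        dmt, pcb = self._frames(rng.uniform(0, 1, (8, 6)), rng.uniform(0, 1, (8, 6)))
        change = vas_change_and_tests(dmt, pcb).change.to_numpy()
        assert change.min() >= -1 and change.max() <= 1

    def test_missing_item_rejected(self, rng):
        dmt, pcb = self._frames(rng.uniform(0, 1, (8, 4)), rng.uniform(0, 1, (8, 4)))
        with pytest.raises(ValueError, match="missing"):
            vas_change_and_tests(dmt.drop(columns="item_02"), pcb)


class TestPLS:
    def test_exact_linear_relation_first_component_r1(self, rng):
        # orthogonal predictors: the covariance-maximizing direction is the
        # coupled column itself, so the component-1 scores match Y exactly
        A = rng.standard_normal((15, 6))
        A -= A.mean(axis=0)
        X = np.linalg.qr(A)[0]  # zero-mean orthonormal columns
        y = 2.0 * X[:, 2]
        m = pls2(y, X, n_components=1)
        assert m.score_r[0] == pytest.approx(1.0, abs=1e-9)
        # a perfectly explained outcome leaves nothing for component 2
        with pytest.raises(ValueError, match="degenerate"):
            pls2(y, X, n_components=2)

    def test_loadings_match_independent_simpls_oracle(self, rng):
        for _ in range(10):
            X = rng.standard_normal((30, 8))
            Y = rng.standard_normal((30, 3))
            m = pls2(Y, X, n_components=2)
            P, Q, T = simpls_oracle(X, Y, 2)
            np.testing.assert_allclose(_fix_signs(P, P), m.x_loadings, atol=1e-8)
            np.testing.assert_allclose(_fix_signs(Q, P), m.y_loadings, atol=1e-8)
            np.testing.assert_allclose(_fix_signs(T, P), m.x_scores, atol=1e-8)

    def test_predictions_match_sklearn_univariate(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((20, 8))
        y = rng.standard_normal(20)
        for A in (1, 2):
            mine = pls2(y, X, n_components=A).predict(X).ravel()
            theirs = np.ravel(PLSRegression(n_components=A, scale=False).fit(X, y).predict(X))
            np.testing.assert_allclose(mine, theirs, atol=1e-10)

    def test_two_components_nested_rss(self, rng):
        X = rng.standard_normal((25, 10))
        y = X[:, 0] - 0.5 * X[:, 3] + 0.3 * rng.standard_normal(25)
        m = pls2(y, X, n_components=2)
        rss1 = np.sum((y[:, None] - m.predict(X, n_components=1)) ** 2)
        rss2 = np.sum((y[:, None] - m.predict(X, n_components=2)) ** 2)
        assert rss2 <= rss1 + 1e-12

    def test_participant_order_invariance(self, rng):
        X = rng.standard_normal((18, 6))
        y = rng.standard_normal(18)
        m = pls2(y, X)
        perm = np.random.default_rng(1).permutation(18)
        mp = pls2(y[perm], X[perm])
        np.testing.assert_allclose(mp.x_loadings, m.x_loadings, atol=1e-10)
        np.testing.assert_allclose(mp.x_scores, m.x_scores[perm], atol=1e-10)

    def test_constant_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            pls2(np.ones(10), rng.standard_normal((10, 4)))

    def test_planted_coupling_sign_recovered(self):
        """Items coupled (+, -) to the outcome load with opposite signs on
        component 1 in nearly all seeds."""
        hits = 0
        for seed in range(30):
            s = np.random.default_rng(1000 + seed).standard_normal(100)
            coupling = {"item_05": ("s", 0.6), "item_12": ("s", -0.6)}
            dmt, pcb = generate_vas({"s": s}, coupling, noise_sd=0.1, seed=seed)
            X = (dmt - pcb).to_numpy()
            m = pls2(s, X, n_components=2)
            l = m.x_loadings[:, 0]
            hits += bool(l[4] * l[11] < 0)
        assert hits >= 27


class TestSmallStats:
    def test_pearson_perfect(self):
        r, df, p = pearson_with_df(np.arange(10.0), np.arange(10.0) * 2 + 1)
        assert r == pytest.approx(1.0, abs=1e-12) and p < 1e-30

    def test_pearson_df_reporting(self, rng):
        x = rng.standard_normal(14)
        y = rng.standard_normal(14)
        r, df, p = pearson_with_df(x, y)
        assert df == 12

    def test_pearson_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            r, _, p = pearson_with_df(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_median_split_even_distinct(self):
        low, high = median_split(np.arange(14.0))
        assert low.size == 7 and high.size == 7

    def test_median_split_tie_to_low(self):
        low, high = median_split(np.array([1.0, 2.0, 2.0, 3.0]))
        np.testing.assert_array_equal(low, [0, 1, 2])
        np.testing.assert_array_equal(high, [3])

    def test_order_regression_zero_and_unit_slopes(self):
        order = np.repeat([0, 1], 7)
        beta, p = order_effect_regression(np.ones(14), order)
        assert beta == pytest.approx(0.0)
        beta, p = order_effect_regression(order.astype(float), order)
        assert beta == pytest.approx(1.0) and p < 0.05

    def test_order_regression_equals_two_sample_t(self, rng):
        order = np.repeat([0, 1], 7)
        y = rng.standard_normal(14) + order * 0.8
        _, p = order_effect_regression(y, order)
        ref = stats.ttest_ind(y[order == 1], y[order == 0])
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_order_regression_single_order_rejected(self):
        with pytest.raises(ValueError, match="both"):
            order_effect_regression(np.ones(5), np.zeros(5))

    def test_paired_t_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_ttest(np.ones(5), np.ones(5))

    def test_paired_t_zero_mean_differences(self):
        t, df, p = paired_ttest(np.array([1.0, 0.0, 1.0, 0.0]), np.array([0.0, 1.0, 0.0, 1.0]))
        assert t == pytest.approx(0.0) and df == 3

    def test_paired_t_matches_scipy(self, rng):
        a = rng.standard_normal(14)
        b = rng.standard_normal(14) + 0.4
        t, df, p = paired_ttest(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
        assert df == 13
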