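import itertools

import numpy as np
import pytest

from aqnet.qap import (
    QAPConfig,
    QAPRegression,
    qap_correlation,
    qap_regression,
    vectorize_offdiag,
)


def random_binary(n, rng, p=0.5):
    m = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(m, 0)
    return m


class TestVectorizeOffdiag:
    def test_two_by_two_order(self):
        m = np.array([[0.0, 5.0], [7.0, 0.0]])
        assert vectorize_offdiag(m).tolist() == [5.0, 7.0]

    def test_zero_matrix_gives_zero_vector(self):
        assert vectorize_offdiag(np.zeros((3, 3))).tolist() == [0.0] * 6

    @pytest.mark.parametrize("n", [2, 4, 9])
    def test_length_is_n_squared_minus_n(self, n, rng):
        assert len(vectorize_offdiag(rng.random((n, n)))) == n * n - n

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            vectorize_offdiag(np.zeros((2, 3)))


class TestQAPRegression:
    def test_self_regression_is_perfect_with_minimal_p(self, rng):
        x = random_binary(12, rng)
        fit = qap_regression(x, [x], QAPConfig(n_permutations=199, seed=1))
        assert fit.coefficients["x1"]["estimate"] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients["x1"]["p_value"] == pytest.approx(1 / 200)
        assert fit.r_squared_p == pytest.approx(1 / 200)

    def test_observed_fit_matches_normal_equations(self, rng):
        y = rng.random((8, 8))
        xs = [rng.random((8, 8)) for _ in range(3)]
        fit = qap_regression(y, xs, QAPConfig(n_permutations=100, seed=0))
        Z = np.column_stack(
            [np.ones(56)] + [vectorize_offdiag(m) for m in xs]
        )
        yv = vectorize_offdiag(y)
        beta = np.linalg.solve(Z.T @ Z, Z.T @ yv)
        assert fit.intercept["estimate"] == pytest.approx(beta[0], rel=1e-10)
        for j, name in enumerate(fit.predictors):
            assert fit.coefficients[name]["estimate"] == pytest.approx(
                beta[j + 1], rel=1e-10
            )
        resid = yv - Z @ beta
        sst = np.sum((yv - yv.mean()) ** 2)
        assert fit.r_squared == pytest.approx(1 - resid @ resid / sst, rel=1e-10)
        n_obs, k = 56, 3
        assert fit.adj_r_squared == pytest.approx(
            1 - (1 - fit.r_squared) * (n_obs - 1) / (n_obs - k - 1), rel=1e-10
        )

    def test_planted_predictor_significant_noise_predictor_not(self, rng):
        x1 = random_binary(20, rng)
        x2 = random_binary(20, rng)
        noise = rng.normal(0, 0.3, size=(20, 20))
        y = 0.9 * x1 + noise
        np.fill_diagonal(y, 0)
        fit = qap_regression(y, [x1, x2], QAPConfig(n_permutations=499, seed=2),
                             predictor_names=["planted", "noise"])
        assert fit.coefficients["planted"]["p_value"] < 0.01
        assert fit.coefficients["noise"]["p_value"] > 0.05

    def test_deterministic_given_seed(self, rng):
        y = random_binary(10, rng)
        x = random_binary(10, rng)
        a = qap_regression(y, [x], QAPConfig(n_permutations=199, seed=9))
        b = qap_regression(y, [x], QAPConfig(n_permutations=199, seed=9))
        assert a == b

    def test_joint_relabeling_leaves_estimates_unchanged(self, rng):
        y = random_binary(10, rng)
        xs = [random_binary(10, rng) for _ in range(2)]
        pi = rng.permutation(10)
        a = qap_regression(y, xs, QAPConfig(n_permutations=100, seed=0))
        b = qap_regression(
            y[np.ix_(pi, pi)],
            [x[np.ix_(pi, pi)] for x in xs],
            QAPConfig(n_permutations=100, seed=0),
        )
        assert a.r_squared == pytest.approx(b.r_squared, rel=1e-10)
        for name in a.coefficients:
            assert a.coefficients[name]["estimate"] == pytest.approx(
                b.coefficients[name]["estimate"], rel=1e-10
            )

    def test_exhaustive_p_matches_independent_enumeration(self, rng):
        """On 5 nodes, the exhaustive permutation p equals a brute-force
        enumeration using an independent covariance-based slope."""
        y = rng.random((5, 5))
        x = rng.random((5, 5))
        np.fill_diagonal(y, 0)
        np.fill_diagonal(x, 0)
        fit = qap_regression(y, [x], QAPConfig(n_permutations=100, exhaustive=True))
        xv = vectorize_offdiag(x)

        def slope(m):
            v = vectorize_offdiag(m)
            return np.cov(xv, v)[0, 1] / np.var(xv, ddof=1)

        obs = slope(y)
        count = 0
        for pi in itertools.permutations(range(5)):
            pi = np.array(pi)
            s = slope(y[np.ix_(pi, pi)])
            if (obs >= 0 and s >= obs - 1e-12) or (obs < 0 and s <= obs + 1e-12):
                count += 1
        assert fit.coefficients["x1"]["estimate"] == pytest.approx(obs, rel=1e-10)
        assert fit.coefficients["x1"]["p_value"] == pytest.approx(
            count / 120, abs=1e-12
        )

    def test_pvalues_never_zero(self, rng):
        y = random_binary(8, rng)
        fit = qap_regression(y, [y], QAPConfig(n_permutations=100, seed=0))
        assert all(v["p_value"] > 0 for v in fit.coefficients.values())
        assert fit.r_squared_p > 0

    def test_collinear_predictors_rejected(self, rng):
        x = random_binary(8, rng)
        with pytest.raises(ValueError, match="collinear"):
            qap_regression(random_binary(8, rng), [x, 2 * x],
                           QAPConfig(n_permutations=100))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            qap_regression(random_binary(8, rng), [random_binary(9, rng)],
                           QAPConfig(n_permutations=100))

    def test_estimator_attributes_exposed(self, rng):
        y = random_binary(10, rng)
        x = random_binary(10, rng)
        est = QAPRegression(n_permutations=100, random_state=0).fit([x], y)
        assert est.coef_.shape == (1,)
        assert est.pvalues_.shape == (1,)
        assert 0 <= est.r_squared_ <= 1
        assert est.adj_r_squared_ <= est.r_squared_
        params = est.get_params()
        assert params["n_permutations"] == 100

    def test_dsp_mode_close_to_plain_for_orthogonal_predictors(self, rng):
        x1 = random_binary(15, rng)
        x2 = random_binary(15, rng)
        y = 0.8 * x1 + rng.normal(0, 0.5, (15, 15))
        np.fill_diagonal(y, 0)
        plain = qap_regression(y, [x1, x2], QAPConfig(n_permutations=499, seed=3))
        dsp = qap_regression(
            y, [x1, x2], QAPConfig(n_permutations=499, seed=3, method="dsp")
        )
        assert dsp.coefficients["x1"]["estimate"] == pytest.approx(
            plain.coefficients["x1"]["estimate"]
        )
        assert dsp.coefficients["x1"]["p_value"] < 0.01


class TestQAPCorrelation:
    def test_identical_matrices_correlate_perfectly(self, rng):
        a = random_binary(10, rng)
        out = qap_correlation(a, a, QAPConfig(n_permutations=199, seed=0))
        assert out["r"] == pytest.approx(1.0)
        assert out["p_value"] == pytest.approx(1 / 200)

    def test_binary_complement_is_minus_one(self, rng):
        a = random_binary(10, rng)
        b = 1.0 - a
        np.fill_diagonal(b, 0)
        out = qap_correlation(a, b, QAPConfig(n_permutations=199, seed=0))
        assert out["r"] == pytest.approx(-1.0)

    def test_independent_matrices_small_r(self, rng):
        a = random_binary(20, rng)
        b = random_binary(20, rng)
        out = qap_correlation(a, b, QAPConfig(n_permutations=199, seed=1))
        assert abs(out["r"]) < 0.25

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            qap_correlation(np.zeros((5, 5)), random_binary(5, rng),
                            QAPConfig(n_permutations=100))
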