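"""CAR scores: shrinkage intensity, the dual-trick inverse square root,
t-based significance and the null degrees-of-freedom fit."""

import numpy as np
import pytest
from scipy import stats

import gmb
from gmb.car import (
    CARParameters,
    car_pvalues,
    car_scores,
    estimate_kappa,
    estimate_lambda,
    marginal_correlations,
)
from gmb.errors import GmbError

from conftest import make_geno, make_traits
import oracles


def _orthogonal_panel(n=16, m=4, seed=0):
    """Float-coded panel whose standardized columns are exactly uncorrelated:
    QR of [1 | random] makes the non-intercept columns mean-zero and mutually
    orthogonal."""
    rng = np.random.default_rng(seed)
    M = np.column_stack([np.ones(n), rng.standard_normal((n, m))])
    Q, _ = np.linalg.qr(M)
    return make_geno(Q[:, 1:])


class TestMarginalCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        codes = rng.choice([-1, 0, 1], size=(30, 5), p=[0.25, 0.5, 0.25]).astype(float)
        r = marginal_correlations(make_geno(codes), make_traits(codes[:, 2]))
        assert r[2] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        codes = np.array([[-1, 0, 1], [0, 1, 1], [1, 1, -1], [0, -1, 0], [-1, 0, 0]], dtype=float)
        y = np.array([0.3, 1.2, -0.4, 0.1, -0.5])
        r = marginal_correlations(make_geno(codes), make_traits(y))
        for j in range(3):
            assert r[j] == pytest.approx(np.corrcoef(codes[:, j], y)[0, 1], abs=1e-12)

    def test_null_correlations_small(self):
        rng = np.random.default_rng(2)
        codes = rng.choice([-1, 0, 1], size=(5000, 20), p=[0.25, 0.5, 0.25]).astype(float)
        r = marginal_correlations(make_geno(codes), make_traits(rng.standard_normal(5000)))
        assert np.max(np.abs(r)) < 0.06

    def test_constant_trait_rejected(self):
        g = _orthogonal_panel()
        with pytest.raises(GmbError):
            marginal_correlations(g, make_traits(np.ones(g.n_individuals)))


class TestLambda:
    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([-1, 0, 1], size=(40, 8), p=[0.25, 0.5, 0.25]).astype(float)
        assert estimate_lambda(make_geno(codes)) == pytest.approx(
            oracles.shrinkage_lambda_loops(codes), abs=1e-10
        )

    def test_duplicated_column_pair(self):
        rng = np.random.default_rng(4)
        base = rng.choice([-1, 0, 1], size=(200, 6), p=[0.25, 0.5, 0.25]).astype(float)
        codes = np.column_stack([base, base[:, 0]])
        codes += rng.normal(0, 1e-6, codes.shape)  # break exact duplication
        lam = estimate_lambda(make_geno(codes))
        assert 0.0 < lam < 1.0
        assert lam == pytest.approx(oracles.shrinkage_lambda_loops(codes), abs=1e-8)

    def test_independent_snps_shrink_hard(self):
        rng = np.random.default_rng(5)
        codes = rng.choice([-1, 0, 1], size=(3000, 10), p=[0.25, 0.5, 0.25]).astype(float)
        assert estimate_lambda(make_geno(codes)) > 0.7

    def test_clipped_to_unit_interval(self):
        rng = np.random.default_rng(6)
        codes = rng.choice([-1, 0, 1], size=(10, 60), p=[0.25, 0.5, 0.25]).astype(float)
        assert 0.0 <= estimate_lambda(make_geno(codes)) <= 1.0


class TestCarScores:
    def test_lambda_one_returns_marginal_correlations(self, small_population):
        g = small_population["imputed"]
        tr = small_population["traits"]
        omega = car_scores(g, tr, CARParameters(lam=1.0, kappa=2.0))
        assert np.allclose(omega, marginal_correlations(g, tr), atol=1e-12)

    def test_uncorrelated_panel_any_lambda(self):
        g = _orthogonal_panel()
        rng = np.random.default_rng(7)
        tr = make_traits(rng.standard_normal(g.n_individuals))
        r = marginal_correlations(g, tr)
        for lam in (0.0, 0.3, 0.9):
            omega = car_scores(g, tr, CARParameters(lam=lam, kappa=2.0))
            assert np.allclose(omega, r, atol=1e-10)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(8)
        base = rng.choice([-1, 0, 1], size=(25, 2), p=[0.25, 0.5, 0.25]).astype(float)
        codes = np.column_stack([base, base + rng.normal(0, 0.5, base.shape)])
        y = rng.standard_normal(25)
        for lam in (0.1, 0.5, 0.95):
            omega = car_scores(make_geno(codes), make_traits(y),
                               CARParameters(lam=lam, kappa=2.0))
            dense = oracles.car_scores_dense(codes, y, lam)
            assert np.allclose(omega, dense, atol=1e-10)

    def test_dual_equals_dense_wide_panel(self):
        # m > n: the m x m matrix route must agree with the dual trick
        rng = np.random.default_rng(9)
        codes = rng.choice([-1, 0, 1], size=(30, 50), p=[0.25, 0.5, 0.25]).astype(float)
        y = rng.standard_normal(30)
        omega = car_scores(make_geno(codes), make_traits(y),
                           CARParameters(lam=0.4, kappa=2.0))
        assert np.allclose(omega, oracles.car_scores_dense(codes, y, 0.4), atol=1e-10)

    def test_lambda_zero_singular_rejected(self):
        rng = np.random.default_rng(10)
        codes = rng.choice([-1, 0, 1], size=(10, 30), p=[0.25, 0.5, 0.25]).astype(float)
        with pytest.raises(GmbError):
            car_scores(make_geno(codes), make_traits(rng.standard_normal(10)),
                       CARParameters(lam=0.0, kappa=2.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        codes = rng.choice([-1, 0, 1], size=(40, 6), p=[0.25, 0.5, 0.25]).astype(float)
        y = rng.standard_normal(40)
        p = CARParameters(lam=0.5, kappa=2.0)
        base = car_scores(make_geno(codes), make_traits(y), p)
        scaled = car_scores(make_geno(codes * 3.7), make_traits(y * -0.2 + 5), p)
        # y rescaling flips all signs with the negative factor
        assert np.allclose(np.abs(base), np.abs(scaled), atol=1e-10)

    def test_decorrelation_identity(self):
        # at lambda = 0, sum omega^2 = squared multiple correlation R^2
        rng = np.random.default_rng(12)
        codes = rng.choice([-1, 0, 1], size=(100, 5), p=[0.25, 0.5, 0.25]).astype(float)
        beta = np.array([0.5, 0.0, -0.3, 0.0, 0.2])
        y = codes @ beta + rng.standard_normal(100)
        omega = car_scores(make_geno(codes), make_traits(y),
                           CARParameters(lam=0.0, kappa=2.0))
        X = np.column_stack([np.ones(100), codes])
        yhat = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r2 = 1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert np.sum(omega**2) == pytest.approx(r2, abs=1e-10)


class TestCarPvalues:
    def test_zero_score_gives_p_one(self):
        assert car_pvalues(np.array([0.0]), kappa=100)[0] == pytest.approx(1.0)

    def test_monotone_in_magnitude(self):
        p = car_pvalues(np.array([0.05, -0.1, 0.2]), kappa=200)
        assert p[0] > p[1] > p[2]

    def test_matches_t_transform_oracle(self):
        # independent evaluation of the correlation t-transform
        omega, kappa = 0.3, 101.0
        t = omega * np.sqrt((kappa - 1) / (1 - omega**2))
        expected = 2 * (1 - stats.t.cdf(t, df=kappa - 1))
        assert car_pvalues(np.array([omega]), kappa)[0] == pytest.approx(expected, rel=1e-10)

    def test_boundary_scores_warn_not_crash(self):
        with pytest.warns(UserWarning):
            p = car_pvalues(np.array([1.0, 0.0]), kappa=50)
        assert p[0] == 0.0 and p[1] == pytest.approx(1.0)


class TestKappa:
    def test_recovers_true_null_df(self):
        kappas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = rng.standard_t(df=199, size=5000)
            omega = t / np.sqrt(199 + t**2)  # exact null with kappa = 200
            kappas.append(estimate_kappa(omega))
        assert abs(np.mean(kappas) - 200) < 50  # within 25%

    def test_degenerate_scores_fall_back(self):
        with pytest.warns(UserWarning):
            k = estimate_kappa(np.zeros(100), n_individuals=321)
        assert k == 321

    def test_few_scores_fall_back(self):
        with pytest.warns(UserWarning):
            k = estimate_kappa(np.array([0.1, -0.2]), n_individuals=77)
        assert k == 77

    def test_always_above_one(self):
        rng = np.random.default_rng(13)
        omega = np.tanh(rng.normal(0, 0.8, size=200))  # very wide scores
        assert estimate_kappa(omega) > 1
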