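"""Newton logistic fitter and the 1-df interaction likelihood-ratio test.

statsmodels serves as the independent oracle: both models are refitted with
its Newton optimizer and the deviance difference is compared with ours.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from episcan import (
    MISSING,
    build_pair_design,
    chi2_sf_1df,
    fit_logistic,
    log_likelihood,
    lrt_pair,
)
from episcan.interaction import (
    STATUS_CONVERGED,
    STATUS_SEPARATED,
    STATUS_SINGULAR,
    EmptyDesignError,
    worse_status,
)


def oracle_lrt(g1, g2, y):
    """Independent LRT: statsmodels Newton fits of the full and null models."""
    n = len(y)
    X = np.column_stack([np.ones(n), g1, g2, np.asarray(g1) * np.asarray(g2)]).astype(float)
    llf = sm.Logit(np.asarray(y, float), X).fit(disp=0, method="newton").llf
    lln = sm.Logit(np.asarray(y, float), X[:, :3]).fit(disp=0, method="newton").llf
    return 2.0 * (llf - lln)


class TestBuildPairDesign:
    def test_interaction_column_is_elementwise_product(self):
        X, y, n = build_pair_design(
            np.array([0, 1, 2]), np.array([2, 1, 0]), np.array([1, 0, 1])
        )
        assert X.shape == (3, 4)
        np.testing.assert_array_equal(X[:, 3], [0, 1, 0])
        assert n == 3

    def test_complete_case_drops_missing_rows(self):
        g1 = np.array([0, MISSING, 2])
        X, y, n = build_pair_design(g1, np.array([1, 1, 1]), np.array([1, 0, 1]))
        assert n == 2
        np.testing.assert_array_equal(X[:, 1], [0, 2])
        np.testing.assert_array_equal(y, [1, 1])

    def test_identical_snps_still_build(self):
        g = np.array([0, 1, 2, 1])
        X, _, _ = build_pair_design(g, g, np.array([1, 0, 1, 0]))
        np.testing.assert_array_equal(X[:, 3], g.astype(float) ** 2)

    def test_all_missing_raises(self):
        g = np.array([MISSING, MISSING])
        with pytest.raises(EmptyDesignError):
            build_pair_design(g, g, np.array([1, 0]))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        X = np.ones((10, 1))
        y = np.array([1.0] * 3 + [0.0] * 7)
        fit = fit_logistic(X, y)
        assert fit.status == STATUS_CONVERGED
        assert fit.beta[0] == pytest.approx(np.log(3 / 7), abs=1e-8)
        assert fit.loglik == pytest.approx(3 * np.log(0.3) + 7 * np.log(0.7), abs=1e-8)

    def test_exact_collinearity_is_singular(self):
        X = np.column_stack([np.ones(8), np.full(8, 2.0)])
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        assert fit_logistic(X, y).status == STATUS_SINGULAR

    def test_constant_response_is_separated_not_an_exception(self):
        X = np.ones((12, 1))
        assert fit_logistic(X, np.ones(12)).status == STATUS_SEPARATED
        assert fit_logistic(X, np.zeros(12)).status == STATUS_SEPARATED

    def test_perfect_separation_flagged(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([np.ones(10), x])
        y = (x >= 5).astype(float)
        assert fit_logistic(X, y).status == STATUS_SEPARATED

    def test_matches_reference_fit_on_fixed_dataset(self):
        # 40 individuals, outcome realized from beta = (-0.5, 0.4, 0.0, 0.8)
        rng = np.random.default_rng(42)
        g1 = rng.binomial(2, 0.35, 40)
        g2 = rng.binomial(2, 0.25, 40)
        X = np.column_stack([np.ones(40), g1, g2, g1 * g2]).astype(float)
        eta = X @ np.array([-0.5, 0.4, 0.0, 0.8])
        y = (rng.random(40) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0, method="newton")
        assert fit.status == STATUS_CONVERGED
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)


class TestLogLikelihood:
    def test_zero_coefficients_give_n_log_half(self):
        X = np.column_stack([np.ones(9), np.arange(9.0)])
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        assert log_likelihood(np.zeros(2), X, y) == pytest.approx(9 * np.log(0.5))

    def test_saturated_predictor_is_stable(self):
        X = np.array([[1.0, 1000.0]])
        assert log_likelihood(np.array([0.0, 1.0]), X, np.array([1.0])) == pytest.approx(0.0)
        assert np.isfinite(log_likelihood(np.array([0.0, 1.0]), X, np.array([0.0])))

    def test_six_row_hand_sum(self):
        X = np.column_stack([np.ones(6), np.array([0, 1, 2, 0, 1, 2.0])])
        y = np.array([1, 1, 0, 0, 1, 1], dtype=float)
        beta = np.array([0.5, -0.25])
        mu = 1 / (1 + np.exp(-(X @ beta)))
        by_hand = sum(
            yi * np.log(mi) + (1 - yi) * np.log(1 - mi) for yi, mi in zip(y, mu)
        )
        assert log_likelihood(beta, X, y) == pytest.approx(by_hand, abs=1e-12)


class TestChi2Tail:
    def test_reference_points(self):
        assert chi2_sf_1df(0.0) == 1.0
        assert chi2_sf_1df(3.841458820694124) == pytest.approx(0.05, abs=1e-12)
        assert 0.0 < chi2_sf_1df(100.0) < 1e-20

    def test_strictly_decreasing_on_working_range(self):
        xs = np.linspace(0, 50, 201)
        ps = [chi2_sf_1df(x) for x in xs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chi2_sf_1df(-0.1)


@pytest.fixture(scope="module")
def fixed_pair():
    """200 individuals with a planted interaction (beta12 = 1.0)."""
    rng = np.random.default_rng(2024)
    g1 = rng.binomial(2, 0.3, 200)
    g2 = rng.binomial(2, 0.3, 200)
    eta = -0.3 + 0.2 * g1 + 0.1 * g2 + 1.0 * g1 * g2
    y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
    return g1, g2, y


class TestLrtPair:
    def test_matches_oracle_on_fixed_planted_dataset(self, fixed_pair):
        g1, g2, y = fixed_pair
        res = lrt_pair(g1, g2, y)
        assert res.status == STATUS_CONVERGED
        assert res.lrt_stat == pytest.approx(oracle_lrt(g1, g2, y), abs=1e-4)
        assert res.p_value == pytest.approx(chi2_sf_1df(res.lrt_stat))

    def test_oracle_equivalence_many_random_datasets(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 50:
            n = 300
            g1 = rng.binomial(2, rng.uniform(0.1, 0.5), n)
            g2 = rng.binomial(2, rng.uniform(0.1, 0.5), n)
            y = rng.integers(0, 2, n).astype(float)
            res = lrt_pair(g1, g2, y)
            if res.status != STATUS_CONVERGED:
                continue
            assert res.lrt_stat == pytest.approx(oracle_lrt(g1, g2, y), abs=1e-4)
            checked += 1

    def test_symmetry_in_the_two_snps(self, fixed_pair):
        g1, g2, y = fixed_pair
        a = lrt_pair(g1, g2, y)
        b = lrt_pair(g2, g1, y)
        assert a.lrt_stat == b.lrt_stat and a.p_value == b.p_value

    def test_invariant_to_individual_order(self, fixed_pair):
        g1, g2, y = fixed_pair
        perm = np.random.default_rng(5).permutation(len(y))
        a = lrt_pair(g1, g2, y)
        b = lrt_pair(g1[perm], g2[perm], y[perm])
        assert a.lrt_stat == pytest.approx(b.lrt_stat, abs=1e-10)
        assert a.n_used == b.n_used and a.status == b.status

    def test_monomorphic_snp_is_singular_without_p_value(self):
        g1 = np.zeros(50, dtype=int)
        g2 = np.tile([0, 1], 25)
        y = np.tile([1, 0], 25).astype(float)
        res = lrt_pair(g1, g2, y)
        assert res.status == STATUS_SINGULAR
        assert res.p_value is None and res.lrt_stat is None

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_statistic_nonnegative_under_null(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.binomial(2, 0.3, 150)
        g2 = rng.binomial(2, 0.3, 150)
        y = rng.integers(0, 2, 150).astype(float)
        res = lrt_pair(g1, g2, y)
        if res.status == STATUS_CONVERGED:
            assert res.lrt_stat >= 0.0
            assert 0.0 < res.p_value <= 1.0


def test_worse_status_ordering():
    assert worse_status("converged", "max_iter") == "max_iter"
    assert worse_status("separated", "singular") == "singular"
    assert worse_status("converged", "converged") == "converged"
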