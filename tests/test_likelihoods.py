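import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from histborrow.data import DesignMatrices
from histborrow.likelihoods import (
    LMMParams,
    conditional_loglik,
    marginal_loglik,
    tempered_conditional_dalpha,
    tempered_conditional_integrated_loglik,
    tempered_marginal_loglik,
)


def make_design(times_per_subject, ys, q=2, treated=None):
    """Hand-built design matrices for unit tests."""
    subjects, X, Z, Y = [], [], [], []
    with_trt = treated is not None
    for i, (t, y) in enumerate(zip(times_per_subject, ys)):
        t = np.asarray(t, float)
        cols = [np.ones_like(t), t]
        if with_trt:
            cols.append((1.0 if treated[i] else 0.0) * t)
        subjects.append(f"s{i}")
        X.append(np.column_stack(cols))
        Z.append(np.column_stack([np.ones_like(t), t])[:, :q])
        Y.append(np.asarray(y, float))
    cols = ("intercept", "time") + (("treatment:time",) if with_trt else ())
    return DesignMatrices(subjects, X, Z, Y, cols, with_trt)


@pytest.fixture(scope="module")
def toy_params():
    return LMMParams(
        betaC=[2.0, 1.0], betaT=0.0,
        G=np.array([[0.3, 0.05], [0.05, 0.2]]), sigma2=0.8,
    )


class TestConditional:
    def test_standard_normal_at_mean(self):
        d = make_design([[0.0]], [[2.0]])
        p = LMMParams(betaC=[2.0, 1.0], betaT=0.0, G=np.zeros((2, 2)), sigma2=1.0)
        val = conditional_loglik(p, np.zeros((1, 2)), d)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_additivity_over_subjects(self, toy_params):
        d2 = make_design([[0, 0.5], [0, 1.0]], [[1.9, 2.4], [2.2, 3.4]])
        da = make_design([[0, 0.5]], [[1.9, 2.4]])
        db = make_design([[0, 1.0]], [[2.2, 3.4]])
        b = np.array([[0.1, -0.2], [0.3, 0.0]])
        total = conditional_loglik(toy_params, b, d2)
        parts = conditional_loglik(toy_params, b[:1], da) + conditional_loglik(
            toy_params, b[1:], db
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_sigma2_domain(self):
        with pytest.raises(ValueError):
            LMMParams(betaC=[0.0, 0.0], betaT=0.0, G=np.eye(2), sigma2=-1.0)

    def test_monte_carlo_integration_matches_marginal(self, toy_params):
        """E_b[exp(conditional)] equals exp(marginal) (Monte Carlo oracle)."""
        t = np.array([0.0, 0.5, 1.0])
        d = make_design([t], [[2.1, 2.8, 3.3]])
        rng = np.random.default_rng(7)
        n_mc = 1_200_000
        b = rng.multivariate_normal(np.zeros(2), toy_params.G, size=n_mc)
        Z = np.column_stack([np.ones(3), t])
        mu = d.X[0] @ np.array([2.0, 1.0])
        resid = d.y[0] - mu - b @ Z.T
        ll = -0.5 * (
            3 * np.log(2 * np.pi * toy_params.sigma2)
            + np.sum(resid**2, axis=1) / toy_params.sigma2
        )
        mc = np.log(np.mean(np.exp(ll)))
        exact = marginal_loglik(toy_params, d)
        assert mc == pytest.approx(exact, rel=0.01)


class TestMarginal:
    def test_zero_G_reduces_to_conditional(self, toy_params):
        d = make_design([[0, 0.5, 1.0]], [[2.0, 2.5, 3.1]])
        p0 = LMMParams(
            betaC=toy_params.betaC, betaT=0.0, G=np.zeros((2, 2)),
            sigma2=toy_params.sigma2,
        )
        assert marginal_loglik(p0, d) == pytest.approx(
            conditional_loglik(p0, np.zeros((1, 2)), d), rel=1e-12
        )

    def test_matches_dense_multivariate_normal(self, toy_params):
        d = make_design([[0.0, 1.0]], [[2.3, 3.6]])
        Z = d.Z[0]
        V = Z @ toy_params.G @ Z.T + toy_params.sigma2 * np.eye(2)
        mu = d.X[0] @ np.array([2.0, 1.0])
        oracle = stats.multivariate_normal(mu, V).logpdf(d.y[0])
        assert marginal_loglik(toy_params, d) == pytest.approx(oracle, abs=1e-10)

    def test_additivity(self, toy_params):
        d2 = make_design([[0, 0.5], [0, 1.0]], [[1.9, 2.4], [2.2, 3.4]])
        da = make_design([[0, 0.5]], [[1.9, 2.4]])
        db = make_design([[0, 1.0]], [[2.2, 3.4]])
        assert marginal_loglik(toy_params, d2) == pytest.approx(
            marginal_loglik(toy_params, da) + marginal_loglik(toy_params, db),
            rel=1e-12,
        )

    def test_non_psd_surfaces_error(self):
        with pytest.raises(ValueError):
            LMMParams(
                betaC=[0.0, 0.0], betaT=0.0,
                G=np.array([[1.0, 2.0], [2.0, 1.0]]), sigma2=1.0,
            )


class TestTemperedMarginal:
    def test_endpoints_and_linearity(self, toy_params):
        d = make_design([[0, 0.5, 1.0]], [[2.0, 2.5, 3.1]])
        full = marginal_loglik(toy_params, d)
        assert tempered_marginal_loglik(toy_params, 0.0, d) == 0.0
        assert tempered_marginal_loglik(toy_params, 1.0, d) == pytest.approx(full)
        assert tempered_marginal_loglik(toy_params, 0.5, d) == pytest.approx(
            0.5 * full
        )

    @pytest.mark.parametrize("alpha", [-0.1, 1.5])
    def test_alpha_domain(self, toy_params, alpha):
        d = make_design([[0.0]], [[2.0]])
        with pytest.raises(ValueError):
            tempered_marginal_loglik(toy_params, alpha, d)

    @given(alpha=st.floats(0.01, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_alpha(self, alpha):
        d = make_design([[0, 0.5, 1.0]], [[2.0, 2.5, 3.1]])
        p = LMMParams(betaC=[2.0, 1.0], betaT=0.0, G=0.2 * np.eye(2), sigma2=1.0)
        assert tempered_marginal_loglik(p, alpha, d) == pytest.approx(
            alpha * marginal_loglik(p, d), rel=1e-12
        )


class TestTemperedConditionalIntegrated:
    def test_alpha_one_equals_marginal(self, toy_params):
        d = make_design([[0, 0.2, 0.7]], [[2.0, 2.4, 2.9]])
        assert tempered_conditional_integrated_loglik(
            toy_params, 1.0, d
        ) == pytest.approx(marginal_loglik(toy_params, d), rel=1e-12)

    def test_vanishes_as_alpha_to_zero(self, toy_params):
        d = make_design([[0, 0.2, 0.7]], [[2.0, 2.4, 2.9]])
        assert abs(
            tempered_conditional_integrated_loglik(toy_params, 1e-6, d)
        ) < 1e-3
        assert tempered_conditional_integrated_loglik(toy_params, 0.0, d) == 0.0
        with pytest.raises(ValueError):
            tempered_conditional_integrated_loglik(
                toy_params, 0.0, d, on_zero="error"
            )

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.9])
    def test_quadrature_oracle_q1(self, alpha):
        """1-D adaptive quadrature over the random intercept, to 1e-6."""
        g_var = 0.4
        s2 = 0.7
        beta = np.array([2.0, 1.0])
        d = make_design([[0.0, 1.0]], [[2.5, 3.6]], q=1)
        p = LMMParams(betaC=beta, betaT=0.0, G=[[g_var]], sigma2=s2)
        y = d.y[0]
        mu = d.X[0] @ beta

        def integrand(b):
            ll = -0.5 * (
                2 * np.log(2 * np.pi * s2) + np.sum((y - mu - b) ** 2) / s2
            )
            return np.exp(alpha * ll) * stats.norm(0, np.sqrt(g_var)).pdf(b)

        oracle, err = integrate.quad(integrand, -12, 12, epsabs=1e-12)
        val = tempered_conditional_integrated_loglik(p, alpha, d)
        assert val == pytest.approx(np.log(oracle), abs=1e-6)

    def test_continuity_in_alpha(self, toy_params):
        d = make_design([[0, 0.2, 0.7]], [[2.0, 2.4, 2.9]])
        alphas = np.linspace(0.02, 1.0, 25)
        vals = [
            tempered_conditional_integrated_loglik(toy_params, a, d)
            for a in alphas
        ]
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(np.diff(vals, 2))) < 1.0  # no jumps


class TestPathIntegrand:
    @pytest.mark.parametrize("alpha", [0.1, 0.4, 0.8])
    def test_matches_finite_differences(self, toy_params, alpha):
        d = make_design([[0, 0.3, 0.9], [0, 0.6]], [[2.1, 2.2, 3.0], [1.8, 2.9]])
        h = 1e-6
        fd = (
            tempered_conditional_integrated_loglik(toy_params, alpha + h, d)
            - tempered_conditional_integrated_loglik(toy_params, alpha - h, d)
        ) / (2 * h)
        assert tempered_conditional_dalpha(toy_params, alpha, d) == pytest.approx(
            fd, rel=1e-5
        )

    def test_zero_limit_is_expected_conditional_loglik(self, toy_params):
        """At alpha=0 the integrand is E over b ~ N(0, G) of the conditional
        log-likelihood (Monte Carlo oracle)."""
        t = np.array([0.0, 0.5, 1.0])
        d = make_design([t], [[2.1, 2.8, 3.3]])
        rng = np.random.default_rng(11)
        b = rng.multivariate_normal(np.zeros(2), toy_params.G, size=400_000)
        Z = np.column_stack([np.ones(3), t])
        resid = d.y[0] - d.X[0] @ np.array([2.0, 1.0]) - b @ Z.T
        ll = -0.5 * (
            3 * np.log(2 * np.pi * toy_params.sigma2)
            + np.sum(resid**2, axis=1) / toy_params.sigma2
        )
        assert tempered_conditional_dalpha(toy_params, 0.0, d) == pytest.approx(
            ll.mean(), rel=0.005
        )
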