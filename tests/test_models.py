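"""Model fits: determinism, oracles, reduction identities, borrowing order."""

import warnings

import numpy as np
import pytest

from histborrow import (
    BayesianLMM,
    CommensurateLMM,
    ConditionalMPP,
    LongitudinalDataset,
    MarginalMPP,
    PooledLMM,
)
from histborrow import test_treatment_effect as treatment_effect_test
from histborrow.models import PosteriorSamples, alpha_mode, tail_probability
from histborrow.simstudy import ScenarioSpec, simulate_trial


def _combined_mcse(a, b, name="betaT"):
    return np.hypot(a.mc_se(name), b.mc_se(name))


def _fake_samples(draws_1d, extra=None):
    draws = {"betaT": np.asarray(draws_1d)[None, :]}
    if extra:
        draws.update({k: np.asarray(v)[None, :] for k, v in extra.items()})
    diags = {k: {"rhat": 1.0, "ess": float(v.size)} for k, v in draws.items()}
    return PosteriorSamples(draws=draws, diagnostics=diags, method="test", seed=0)


class TestTreatmentEffectTest:
    def test_degenerate_positive_draws_significant(self):
        res = treatment_effect_test(_fake_samples(np.full(1000, 0.5)))
        assert res.significant
        assert res.ci == (0.5, 0.5)

    def test_zero_centered_draws_not_significant(self):
        draws = np.tile([1.0, -1.0], 500)
        res = treatment_effect_test(_fake_samples(draws))
        assert not res.significant

    def test_normal_draws_around_036_significant(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(0.36, 0.05, 4000)
        res = treatment_effect_test(_fake_samples(draws))
        assert res.significant
        assert res.ci_lower == pytest.approx(0.36 - 1.96 * 0.05, abs=0.01)

    def test_low_ess_warns(self):
        with pytest.warns(UserWarning, match="effective sample size"):
            treatment_effect_test(_fake_samples(np.random.randn(100)))

    def test_alpha_summary_present_for_mpp_draws(self):
        rng = np.random.default_rng(0)
        res = treatment_effect_test(
            _fake_samples(
                rng.normal(0.3, 0.1, 2000),
                extra={"alpha": rng.uniform(0.8, 1.0, 2000)},
            )
        )
        assert res.alpha_summary is not None
        assert 0.8 < res.alpha_summary["mean"] < 1.0

    def test_tail_probability_definition(self):
        draws = np.concatenate([np.full(900, 1.0), np.full(100, -1.0)])
        assert tail_probability(_fake_samples(draws)) == pytest.approx(0.2)


class TestAlphaMode:
    def test_boundary_bin_reports_one(self):
        draws = np.clip(np.random.default_rng(0).normal(0.99, 0.02, 5000), 0, 1)
        assert alpha_mode(draws) == 1.0

    def test_interior_mode_is_bin_midpoint(self):
        draws = np.random.default_rng(0).normal(0.5, 0.03, 20000)
        assert abs(alpha_mode(draws) - 0.5) <= 0.02


class TestNoBorrowing:
    def test_seeded_determinism(self, toy_pair, fast):
        cur, _ = toy_pair
        a = BayesianLMM(seed=9, **fast).fit(cur).posterior_
        b = BayesianLMM(seed=9, **fast).fit(cur).posterior_
        np.testing.assert_array_equal(a.combined("betaT"), b.combined("betaT"))
        c = BayesianLMM(seed=10, **fast).fit(cur).posterior_
        assert not np.array_equal(a.combined("betaT"), c.combined("betaT"))

    def test_single_arm_current_rejected(self, toy_pair):
        cur, _ = toy_pair
        controls = cur.frame[cur.frame["arm"] == "control"]
        with pytest.raises(ValueError, match="both arms"):
            BayesianLMM().fit(LongitudinalDataset(controls.copy()))

    def test_posterior_mean_near_reml_estimate(self, toy_pair, fast):
        """Frequentist LMM (statsmodels MixedLM, REML) as oracle."""
        import statsmodels.formula.api as smf

        cur, _ = toy_pair
        df = cur.frame.copy()
        df["trt_time"] = (df["arm"] == "treatment") * df["time"]
        model = smf.mixedlm(
            "y ~ time + trt_time", df, groups=df["subject"],
            re_formula="~time",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reml = model.fit(reml=True)
        est = BayesianLMM(seed=1, **fast).fit(cur)
        res = est.treatment_effect()
        assert abs(res.mean - reml.params["trt_time"]) < 3 * res.sd

    def test_sklearn_params_roundtrip(self):
        est = BayesianLMM(iterations=500, burn_in=100)
        params = est.get_params()
        assert params["iterations"] == 500
        clone = BayesianLMM(**params)
        assert clone.get_params() == params


class TestPooling:
    def test_empty_historical_warns_and_matches_no_borrowing(self, toy_pair, fast):
        cur, _ = toy_pair
        with pytest.warns(UserWarning, match="historical"):
            pooled = PooledLMM(seed=3, **fast).fit(cur, None).posterior_
        nb = BayesianLMM(seed=3, **fast).fit(cur).posterior_
        np.testing.assert_array_equal(
            pooled.combined("betaT"), nb.combined("betaT")
        )

    def test_information_gain_on_homogeneous_data(self, fast):
        """Pooling the historical arm tightens the shared time effect."""
        spec = ScenarioSpec.named("No", beta2=0.36, n_per_arm=20)
        sds_nb, sds_pool = [], []
        for r in range(12):
            cur, hist = simulate_trial(spec, seed=100 + r)
            nb = BayesianLMM(seed=r, **fast).fit(cur).posterior_
            po = PooledLMM(seed=r, **fast).fit(cur, hist).posterior_
            sds_nb.append(nb.combined("betaC")[:, 1].std())
            sds_pool.append(po.combined("betaC")[:, 1].std())
        assert np.mean(sds_pool) < np.mean(sds_nb)


class TestReductionIdentities:
    @pytest.mark.parametrize("cls", [MarginalMPP, ConditionalMPP])
    def test_alpha_zero_equals_no_borrowing(self, toy_pair, fast_mpp, cls):
        cur, hist = toy_pair
        mpp = cls(seed=4, fixed_alpha=0.0, **fast_mpp).fit(cur, hist).posterior_
        nb = BayesianLMM(
            seed=4,
            **{k: v for k, v in fast_mpp.items() if not k.startswith("grid")},
            target_accept=cls().target_accept,
        ).fit(cur).posterior_
        np.testing.assert_allclose(
            mpp.combined("betaT"), nb.combined("betaT"), rtol=1e-12
        )

    @pytest.mark.parametrize("cls", [MarginalMPP, ConditionalMPP])
    def test_alpha_one_equals_pooling(self, toy_pair, fast_mpp, cls):
        cur, hist = toy_pair
        mpp = cls(seed=4, fixed_alpha=1.0, **fast_mpp).fit(cur, hist).posterior_
        pool = PooledLMM(
            seed=4,
            **{k: v for k, v in fast_mpp.items() if not k.startswith("grid")},
            target_accept=cls().target_accept,
        ).fit(cur, hist).posterior_
        np.testing.assert_allclose(
            mpp.combined("betaT"), pool.combined("betaT"), rtol=1e-12
        )


class TestComparativeBorrowing:
    def test_conditional_borrows_more_at_equal_alpha(self, toy_pair, fast):
        """With known (G, sigma2) and the same fixed alpha, the conditional
        MPP's tempered covariance (sigma2/alpha) dominates the marginal
        MPP's alpha-weighting, so its posterior SD is no larger."""
        cur, hist = toy_pair
        G = np.diag([0.25, 0.25])
        kw = dict(fixed_alpha=0.5, fixed_variance=(G, 1.0), seed=8,
                  chains=2, iterations=3000, burn_in=500)
        cond = ConditionalMPP(**kw).fit(cur, hist).posterior_
        marg = MarginalMPP(**kw).fit(cur, hist).posterior_
        sd_c = cond.combined("betaC")[:, 1].std()
        sd_m = marg.combined("betaC")[:, 1].std()
        assert sd_c <= sd_m * 1.02

    def test_exact_gaussian_posterior_sd_ordering(self, toy_pair):
        """Same property from the closed-form Gaussian posterior."""
        from histborrow._blocks import hist_beta_blocks, wls_blocks
        from histborrow.data import build_design

        cur, hist = toy_pair
        curd = build_design(cur)
        histd = build_design(hist, for_study="historical")
        G, s2, alpha = np.diag([0.25, 0.25]), 1.0, 0.5
        Xs, _ = curd.stacked()
        P = (Xs.T @ Xs) / (curd.n_obs * s2)
        Ac, _ = wls_blocks(curd, G, s2)
        for mode, out in (("conditional", {}), ("marginal", {})):
            A = P + Ac
            Ah, _ = hist_beta_blocks(mode, G, s2, alpha, histd)
            A[:2, :2] += Ah
            out["sd"] = np.sqrt(np.linalg.inv(A)[2, 2])
            if mode == "conditional":
                sd_cond = out["sd"]
            else:
                sd_marg = out["sd"]
        assert sd_cond <= sd_marg


class TestMarginalMPPSampling:
    def test_dynamic_discounting(self, fast_mpp):
        """Posterior mean of alpha falls as the historical time trend is
        shifted away from the current one."""
        spec = ScenarioSpec.named("No", beta2=0.0, n_per_arm=60)
        cur, hist = simulate_trial(spec, seed=11)
        means = []
        for shift in (0.0, 0.3, 0.6):
            df = hist.frame.copy()
            df["y"] = df["y"] + shift * df["time"]
            est = MarginalMPP(seed=4, **{**fast_mpp, "iterations": 1000,
                                         "burn_in": 500}).fit(
                cur, LongitudinalDataset(df)
            )
            means.append(est.posterior_.combined("alpha").mean())
        assert means[0] > means[1] > means[2]

    def test_skeptical_prior_discounts_more(self, toy_pair, fast_mpp):
        """Beta(1, 2) on alpha is skeptical of borrowing: it lowers the
        posterior mean of the power parameter relative to Beta(1, 1)."""
        cur, hist = toy_pair
        uni = MarginalMPP(seed=2, alpha_prior=(1.0, 1.0), **fast_mpp).fit(
            cur, hist
        ).posterior_
        skep = MarginalMPP(seed=2, alpha_prior=(1.0, 2.0), **fast_mpp).fit(
            cur, hist
        ).posterior_
        assert skep.combined("alpha").mean() < uni.combined("alpha").mean()

    def test_alpha_draws_in_unit_interval(self, toy_pair, fast_mpp):
        cur, hist = toy_pair
        est = MarginalMPP(seed=2, **fast_mpp).fit(cur, hist)
        a = est.posterior_.combined("alpha")
        assert np.all((a > 0) & (a < 1))
        assert est.grid_ is not None

    def test_conditional_has_elevated_acceptance_target(self):
        assert ConditionalMPP().target_accept > BayesianLMM().target_accept

    def test_grid_required_when_alpha_free(self, toy_pair):
        cur, _ = toy_pair
        with pytest.raises(ValueError):
            MarginalMPP().fit(cur, None)


class TestCommensurate:
    def test_requires_historical(self, toy_pair):
        cur, _ = toy_pair
        with pytest.raises(ValueError):
            CommensurateLMM().fit(cur, None)

    def test_strong_link_approaches_pooling(self, toy_pair, fast):
        cur, hist = toy_pair
        strong = CommensurateLMM(
            seed=6, fixed_commensurate_sd=0.01, **fast
        ).fit(cur, hist).posterior_
        weak = CommensurateLMM(
            seed=6, fixed_commensurate_sd=25.0, **fast
        ).fit(cur, hist).posterior_
        pool = PooledLMM(seed=6, **fast).fit(cur, hist).posterior_
        nb = BayesianLMM(seed=6, **fast).fit(cur).posterior_
        # shared time effect: strong link near pooling, weak link near none
        t_strong = strong.combined("betaC")[:, 1].mean()
        t_weak = weak.combined("betaC")[:, 1].mean()
        t_pool = pool.combined("betaC")[:, 1].mean()
        t_nb = nb.combined("betaC")[:, 1].mean()
        assert abs(t_strong - t_pool) < abs(t_weak - t_pool)
        assert abs(t_weak - t_nb) < abs(t_strong - t_nb)

    def test_weak_link_betaT_matches_no_borrowing(self, toy_pair, fast):
        cur, hist = toy_pair
        weak = CommensurateLMM(
            seed=6, fixed_commensurate_sd=25.0, **fast
        ).fit(cur, hist).posterior_
        nb = BayesianLMM(seed=6, **fast).fit(cur).posterior_
        diff = abs(
            weak.combined("betaT").mean() - nb.combined("betaT").mean()
        )
        assert diff < 3 * np.hypot(weak.mc_se(), nb.mc_se())

    def test_recovers_treatment_effect(self, fast):
        spec = ScenarioSpec.named("No", beta2=0.36, n_per_arm=50)
        cur, hist = simulate_trial(spec, seed=21)
        est = CommensurateLMM(seed=2, **fast).fit(cur, hist)
        res = est.treatment_effect()
        assert abs(res.mean - 0.36) < 3 * res.sd

class TestDiagnosticsContract:
    def test_default_settings_meet_convergence_contract(self):
        """Default 4x2000 chains: monitored R-hat < 1.05 and bulk ESS >= 400
        on a full-size simulated trial, for the plain fit and the MPP."""
        cur, hist = simulate_trial(ScenarioSpec.named("No", beta2=0.36), seed=17)
        nb = BayesianLMM(seed=17).fit(cur).posterior_
        assert nb.max_rhat() < 1.05
        assert nb.min_ess() >= 400
        mpp = MarginalMPP(seed=17, grid_step=0.05, grid_iterations=60,
                          grid_burn_in=20, grid_prior_draws=500).fit(
            cur, hist
        ).posterior_
        assert mpp.max_rhat() < 1.05
        assert mpp.min_ess() >= 400
        assert mpp.diagnostics["alpha"]["ess"] >= 400

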