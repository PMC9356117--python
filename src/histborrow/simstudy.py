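"""Trial simulator and operating-characteristics study harness.

The data-generating process is a two-arm current trial (100 subjects per
arm by default) plus one historical control arm (100 subjects), each
subject measured at six visits (times 0, 0.2, ..., 1):

``y = b0 + b1 t + b2 trt t + u0 + u1 t + d0 + d1 t + e``

with subject effects ``u ~ N(0, diag(0.25, 0.25))``, study effects
``d_j ~ N(0, diag(sd0^2, sd1^2))`` drawn independently for the current and
the historical study (exchangeable between-study heterogeneity), and
``e ~ N(0, 1)``.  Generating parameters: intercept 2, time slope 1,
treatment-by-time 0 (null) or 0.36 (alternative).  Seven named scenarios
set the heterogeneity variances, from none to a large random intercept and
slope.

The study harness fits every requested method to the *same* simulated
pair per replicate (a paired design, enabling the McNemar comparison of
rejection rates), applies the credible-interval decision rule, and
accumulates type I error / power, calibrated power, bias, posterior SD
and MSE with Monte-Carlo standard errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .config import ModelConfig
from .data import CONTROL, CURRENT, HISTORICAL, TREATMENT, LongitudinalDataset
from .models import (
    BayesianLMM,
    CommensurateLMM,
    ConditionalMPP,
    MarginalMPP,
    PooledLMM,
    alpha_mode,
    tail_probability,
    test_treatment_effect,
)

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "GenParams",
    "OperatingCharacteristics",
    "simulate_trial",
    "run_scenario",
    "calibrated_power",
    "mcnemar_paired",
    "summarize_alpha",
    "METHODS",
]

logger = logging.getLogger("histborrow")

#: between-study heterogeneity variances (sd0^2, sd1^2) per named scenario
SCENARIOS: dict[str, tuple[float, float]] = {
    "No": (0.0, 0.0),
    "RI+Low": (0.01, 0.0),
    "RI+Moderate": (0.09, 0.0),
    "RI+High": (0.16, 0.0),
    "RIS+Low": (0.01, 0.01),
    "RIS+Moderate": (0.09, 0.09),
    "RIS+High": (0.16, 0.16),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial design: heterogeneity level x effect."""

    name: str
    sigma_d0_sq: float
    sigma_d1_sq: float
    beta2: float = 0.0
    n_per_arm: int = 100
    times: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

    def __post_init__(self) -> None:
        if self.sigma_d0_sq < 0 or self.sigma_d1_sq < 0:
            raise ValueError("heterogeneity variances must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.name in SCENARIOS:
            expected = SCENARIOS[self.name]
            if (self.sigma_d0_sq, self.sigma_d1_sq) != expected:
                raise ValueError(
                    f"scenario {self.name!r} must have heterogeneity "
                    f"variances {expected}"
                )

    @classmethod
    def named(cls, name: str, beta2: float = 0.0, **kw) -> "ScenarioSpec":
        if name not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {name!r}; valid names: {list(SCENARIOS)}"
            )
        sd0, sd1 = SCENARIOS[name]
        return cls(name=name, sigma_d0_sq=sd0, sigma_d1_sq=sd1, beta2=beta2, **kw)


@dataclass(frozen=True)
class GenParams:
    """Generating-model parameters."""

    beta0: float = 2.0
    beta1: float = 1.0
    beta2: float = 0.0
    sigma_b0_sq: float = 0.25
    sigma_b1_sq: float = 0.25
    sigma_b0b1: float = 0.0
    sigma_eps_sq: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma_b0_sq, self.sigma_b1_sq, self.sigma_eps_sq) < 0:
            raise ValueError("variances must be nonnegative")


def simulate_trial(
    scenario: ScenarioSpec,
    params: GenParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[LongitudinalDataset, LongitudinalDataset]:
    """Simulate one (current, historical) trial pair.

    Study-level effects are redrawn independently for each study, so the
    two control arms are exchangeable rather than equal.
    """
    params = params or GenParams(beta2=scenario.beta2)
    if params.beta2 != scenario.beta2:
        params = replace(params, beta2=scenario.beta2)
    rng = np.random.default_rng(seed)
    t = np.asarray(scenario.times, float)
    m = len(t)
    n = scenario.n_per_arm

    G_subj = np.array(
        [
            [params.sigma_b0_sq, params.sigma_b0b1],
            [params.sigma_b0b1, params.sigma_b1_sq],
        ]
    )
    d_sd = np.sqrt([scenario.sigma_d0_sq, scenario.sigma_d1_sq])

    def one_study(study: str, arms: list[str], prefix: str) -> pd.DataFrame:
        d = rng.standard_normal(2) * d_sd  # study-specific intercept/slope
        rows = []
        for arm in arms:
            trt = 1.0 if arm == TREATMENT else 0.0
            b = rng.multivariate_normal(np.zeros(2), G_subj, size=n)
            eps = rng.standard_normal((n, m)) * np.sqrt(params.sigma_eps_sq)
            mean = (
                params.beta0
                + params.beta1 * t
                + params.beta2 * trt * t
                + d[0]
                + d[1] * t
            )
            y = mean + b[:, [0]] + b[:, [1]] * t + eps
            tag = "T" if arm == TREATMENT else "C"
            for i in range(n):
                sid = f"{prefix}-{tag}-{i + 1:04d}"
                for j in range(m):
                    rows.append((sid, study, arm, t[j], y[i, j]))
        return pd.DataFrame(
            rows, columns=["subject", "study", "arm", "time", "y"]
        )

    cur = LongitudinalDataset(one_study(CURRENT, [TREATMENT, CONTROL], "C"))
    hist = LongitudinalDataset(one_study(HISTORICAL, [CONTROL], "H"))
    return cur, hist


# ---------------------------------------------------------------------------
# method registry


def _make_estimator(method: str, config: ModelConfig, seed: int):
    prior, mcmc, grid = config.prior, config.mcmc, config.grid
    common = dict(
        g=prior.g, re_sd_scale=prior.re_sd_scale,
        err_sd_scale=prior.err_sd_scale, lkj_eta=prior.lkj_eta,
        chains=mcmc.chains, iterations=mcmc.iterations, burn_in=mcmc.burn_in,
        seed=seed,
    )
    mpp = dict(
        alpha_prior=tuple(prior.alpha_prior), grid_step=grid.step,
        grid_iterations=grid.iterations_per_node,
        grid_burn_in=grid.node_burn_in, grid_prior_draws=grid.prior_draws,
        interpolation=grid.interpolation,
    )
    if method == "no_borrowing":
        return BayesianLMM(target_accept=mcmc.target_accept, **common)
    if method == "pooling":
        return PooledLMM(target_accept=mcmc.target_accept, **common)
    if method == "marginal_mpp":
        return MarginalMPP(target_accept=mcmc.target_accept, **common, **mpp)
    if method == "conditional_mpp":
        return ConditionalMPP(**common, **mpp)
    if method == "commensurate":
        return CommensurateLMM(
            target_accept=mcmc.target_accept,
            commensurate_sd_scale=prior.commensurate_sd_scale, **common,
        )
    raise ValueError(f"unknown method {method!r}")


METHODS = ("no_borrowing", "pooling", "conditional_mpp", "marginal_mpp",
           "commensurate")


# ---------------------------------------------------------------------------
# operating characteristics


@dataclass
class OperatingCharacteristics:
    """Per-method summaries plus the replicate-level table."""

    scenario: ScenarioSpec
    replicates: pd.DataFrame  # method, rep, seed, estimate, post_sd, reject,
    #                           tail_prob, alpha_mean, rhat_max, excluded
    n_replicates: int
    excluded: dict[str, int] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Rejection rate, bias, mean posterior SD, MSE with MC-SEs."""
        truth = self.scenario.beta2
        rows = []
        for method, tab in self.replicates.groupby("method", sort=False):
            ok = tab[~tab["excluded"]]
            R = len(ok)
            rate = float(ok["reject"].mean())
            est = ok["estimate"].to_numpy()
            bias = float(est.mean() - truth)
            rows.append(
                {
                    "method": method,
                    "R": R,
                    "rejection_rate": rate,
                    "rejection_rate_mcse": float(
                        np.sqrt(rate * (1 - rate) / R)
                    ),
                    "bias": bias,
                    "bias_mcse": float(est.std(ddof=1) / np.sqrt(R)),
                    "mean_post_sd": float(ok["post_sd"].mean()),
                    "mean_post_sd_mcse": float(
                        ok["post_sd"].std(ddof=1) / np.sqrt(R)
                    ),
                    "mse": float(np.mean((est - truth) ** 2)),
                    "mse_mcse": float(
                        np.std((est - truth) ** 2, ddof=1) / np.sqrt(R)
                    ),
                    "excluded": int(self.excluded.get(method, 0)),
                }
            )
        return pd.DataFrame(rows)

    def rejections(self, method: str) -> np.ndarray:
        tab = self.replicates
        ok = tab[(tab["method"] == method) & (~tab["excluded"])]
        return ok["reject"].to_numpy(bool)

    def paired_rejections(self, method_a: str, method_b: str):
        """Rejection indicators aligned by replicate, restricted to
        replicates where neither method was excluded (for paired
        comparisons such as McNemar)."""
        tab = self.replicates
        a = tab[(tab["method"] == method_a) & (~tab["excluded"])].set_index("rep")
        b = tab[(tab["method"] == method_b) & (~tab["excluded"])].set_index("rep")
        idx = a.index.intersection(b.index)
        return (
            a.loc[idx, "reject"].to_numpy(bool),
            b.loc[idx, "reject"].to_numpy(bool),
        )


def run_scenario(
    methods: list[str],
    scenario: ScenarioSpec,
    R: int,
    base_seed: int,
    config: ModelConfig | None = None,
    params: GenParams | None = None,
) -> OperatingCharacteristics:
    """Fit every method to R simulated replicates of one scenario.

    Replicate r uses seed ``base_seed + r``; all methods see the identical
    simulated pair (paired design).  Replicates whose fit fails the R-hat
    < 1.05 contract are recorded and excluded from the summaries; the run
    is flagged when exclusions exceed 2%.
    """
    if R < 2:
        raise ValueError("need at least 2 replicates")
    config = config or ModelConfig()
    rows = []
    excluded: dict[str, int] = {m: 0 for m in methods}
    for r in range(R):
        seed = base_seed + r
        cur, hist = simulate_trial(scenario, params, seed=seed)
        for method in methods:
            est = _make_estimator(method, config, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                est.fit(cur, hist)
            post = est.posterior_
            res = test_treatment_effect(post)
            bad = not post.converged()
            if bad:
                excluded[method] += 1
            rows.append(
                {
                    "method": method,
                    "rep": r,
                    "seed": seed,
                    "estimate": res.mean,
                    "post_sd": res.sd,
                    "reject": res.significant,
                    "tail_prob": tail_probability(post),
                    "alpha_mean": (
                        float(post.combined("alpha").mean())
                        if "alpha" in post.draws
                        else np.nan
                    ),
                    "alpha_mode": (
                        alpha_mode(post.combined("alpha"))
                        if "alpha" in post.draws
                        else np.nan
                    ),
                    "rhat_max": post.max_rhat(),
                    "excluded": bad,
                }
            )
            logger.info(
                "scenario=%s rep=%d seed=%d method=%s estimate=%.4f "
                "reject=%s rhat=%.3f%s",
                scenario.name, r, seed, method, res.mean, res.significant,
                post.max_rhat(), " EXCLUDED" if bad else "",
            )
    table = pd.DataFrame(rows)
    for method, n_bad in excluded.items():
        if n_bad / R >= 0.02 and n_bad > 0:
            logger.warning(
                "scenario=%s method=%s excluded %d/%d replicates (>= 2%%)",
                scenario.name, method, n_bad, R,
            )
    return OperatingCharacteristics(
        scenario=scenario, replicates=table, n_replicates=R, excluded=excluded
    )


def calibrated_power(
    null_table: pd.DataFrame,
    alt_table: pd.DataFrame,
    target: float = 0.05,
) -> dict[str, float]:
    """Power after forcing each method's type I error to ``target``.

    Per method the rejection threshold is recalibrated to the empirical
    ``target`` quantile of the null posterior tail probabilities; the
    calibrated power is the fraction of alternative replicates whose tail
    probability falls below that threshold.
    """
    methods = sorted(set(null_table["method"]))
    if set(alt_table["method"]) != set(methods):
        raise ValueError("null and alternative tables must share methods")
    out = {}
    for method in methods:
        p_null = null_table.loc[null_table["method"] == method, "tail_prob"]
        p_alt = alt_table.loc[alt_table["method"] == method, "tail_prob"]
        if len(p_null) * target < 1:
            raise ValueError(
                f"too few null replicates ({len(p_null)}) to estimate the "
                f"{target} quantile"
            )
        t_star = float(np.quantile(p_null.to_numpy(), target))
        out[method] = float(np.mean(p_alt.to_numpy() < t_star))
    return out


def mcnemar_paired(
    reject_a: np.ndarray, reject_b: np.ndarray
) -> tuple[float, float]:
    """McNemar test of paired rejection indicators.

    Exact binomial when there are fewer than 25 discordant pairs,
    continuity-corrected chi-square otherwise; (0, 1) when no pair is
    discordant.
    """
    a = np.asarray(reject_a, bool)
    b = np.asarray(reject_b, bool)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    if n01 + n10 == 0:
        return 0.0, 1.0
    table = np.array(
        [[int(np.sum(a & b)), n01], [n10, int(np.sum(~a & ~b))]]
    )
    exact = (n01 + n10) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(res.pvalue)


def summarize_alpha(table: pd.DataFrame, bin_width: float = 0.02) -> pd.DataFrame:
    """Distributional summaries of replicate-level posterior means of alpha.

    The boundary-mode flag is raised when the histogram mode of the
    posterior means abuts 1.
    """
    rows = []
    for method, tab in table.groupby("method", sort=False):
        a = tab["alpha_mean"].dropna().to_numpy()
        if len(a) == 0:
            continue
        q25, q50, q75 = np.quantile(a, [0.25, 0.5, 0.75])
        if "alpha_mode" in tab and tab["alpha_mode"].notna().any():
            # boundary flag from per-replicate posterior modes of alpha
            modes = tab["alpha_mode"].dropna().to_numpy()
            boundary = bool(np.median(modes) >= 1.0 - bin_width)
        else:
            counts, _ = np.histogram(
                a, bins=np.arange(0.0, 1.0 + 1e-9, bin_width)
            )
            boundary = bool(np.argmax(counts) == len(counts) - 1)
        rows.append(
            {
                "method": method,
                "median": float(q50),
                "iqr_low": float(q25),
                "iqr_high": float(q75),
                "mean": float(a.mean()),
                "boundary_mode": boundary,
            }
        )
    return pd.DataFrame(rows)
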