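"""Sampler building blocks shared by the model fits and the power grid.

The posteriors handled here are linear-Gaussian in the fixed effects, so
every model is sampled by blocked Gibbs: the fixed-effect block is drawn
exactly from its multivariate-normal full conditional, while the
covariance parameters (random-effect SDs, their correlation, the error SD)
and the power parameter move by adaptive random-walk Metropolis on
unconstrained scales.  Proposal covariances adapt during burn-in
(Haario-style running covariance plus Robbins-Monro step-size tuning
toward a target acceptance rate) and are frozen afterwards.

Unconstrained parameterisation of the covariance block ``v``:
``(log tau_0, log tau_1, atanh rho, log sigma)`` with
``G = diag(tau) Omega diag(tau)`` and ``Omega`` the 2 x 2 correlation
matrix.  Prior densities include the log-Jacobians of these transforms.
"""

from __future__ import annotations

from math import lgamma

import numpy as np

from .config import PriorSpec

__all__ = [
    "AdaptiveRW",
    "varpar_unpack",
    "varpar_pack",
    "varpar_logprior",
    "gprior_logpdf",
    "half_normal_logpdf",
    "compute_diagnostics",
    "split_rhat",
    "ess_bulk",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def half_normal_logpdf(x: float, scale: float) -> float:
    """Half-normal(0, scale) log-density; `scale` is the SD of the
    underlying normal."""
    if x <= 0:
        return -np.inf
    return float(
        np.log(2.0) - 0.5 * _LOG2PI - np.log(scale) - x**2 / (2.0 * scale**2)
    )


def varpar_unpack(v: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, float]:
    """(log tau0, log tau1, atanh rho, log sigma) -> (tau, rho, G, sigma2)."""
    tau = np.exp(v[:2])
    rho = float(np.tanh(v[2]))
    G = np.array(
        [
            [tau[0] ** 2, rho * tau[0] * tau[1]],
            [rho * tau[0] * tau[1], tau[1] ** 2],
        ]
    )
    sigma2 = float(np.exp(2.0 * v[3]))
    return tau, rho, G, sigma2


def varpar_pack(tau: np.ndarray, rho: float, sigma2: float) -> np.ndarray:
    return np.array(
        [np.log(tau[0]), np.log(tau[1]), np.arctanh(rho), 0.5 * np.log(sigma2)]
    )


def varpar_logprior(v: np.ndarray, prior: PriorSpec) -> float:
    """Log prior of the covariance block on the unconstrained scale.

    Half-normal(0, re_sd_scale) on each random-effect SD, LKJ(eta) on the
    correlation, half-normal(0, err_sd_scale) on the error SD, plus the
    log-Jacobians of (log, atanh, log).
    """
    tau, rho, _, sigma2 = varpar_unpack(v)
    sigma = np.sqrt(sigma2)
    lp = (
        half_normal_logpdf(tau[0], prior.re_sd_scale)
        + half_normal_logpdf(tau[1], prior.re_sd_scale)
        + half_normal_logpdf(sigma, prior.err_sd_scale)
    )
    # LKJ(eta) on a 2x2 correlation: rho = 2u - 1 with u ~ Beta(eta, eta)
    eta = prior.lkj_eta
    lp += (eta - 1.0) * (np.log1p(-rho**2) - np.log(4.0))
    lp += -(lgamma(eta) + lgamma(eta) - lgamma(2.0 * eta)) - np.log(2.0)
    # Jacobians: dtau/dlogtau = tau, drho/dz = 1 - rho^2, dsigma/dlogsigma = sigma
    lp += float(np.log(tau[0]) + np.log(tau[1]) + np.log1p(-rho**2) + np.log(sigma))
    return float(lp)


def gprior_logpdf(beta: np.ndarray, sigma2: float, M: np.ndarray, g: float) -> float:
    """Log-density of the g-prior N(0, g sigma2 M^-1), with M = X'X."""
    p = beta.shape[0]
    sign, logdet_M = np.linalg.slogdet(M)
    quad = float(beta @ M @ beta) / (g * sigma2)
    return float(
        -0.5 * (p * (_LOG2PI + np.log(g * sigma2)) - logdet_M + quad)
    )


class AdaptiveRW:
    """Adaptive multivariate random-walk Metropolis proposal.

    Tracks a running estimate of the target covariance (Haario) and tunes a
    global log step size toward ``target_rate`` by Robbins-Monro during the
    adaptation phase; both are frozen once :meth:`freeze` is called so the
    post-burn-in chain is a valid Markov chain.
    """

    def __init__(self, dim: int, init_scale: float = 0.2,
                 target_rate: float = 0.3):
        self.dim = dim
        self.target_rate = target_rate
        self.log_scale = np.log(init_scale)
        self.mean = np.zeros(dim)
        self.cov = np.eye(dim)
        self.count = 0
        self.frozen = False
        self._chol = np.linalg.cholesky(self.cov)

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        step = np.exp(self.log_scale) * (self._chol @ rng.standard_normal(self.dim))
        return x + step

    def update(self, x: np.ndarray, accepted: bool) -> None:
        if self.frozen:
            return
        self.count += 1
        n = self.count
        eta = 1.0 / max(n, 10) ** 0.6
        self.log_scale += eta * ((1.0 if accepted else 0.0) - self.target_rate)
        delta = x - self.mean
        self.mean += delta / n
        if n > 1:
            self.cov += (np.outer(delta, x - self.mean) - self.cov) / n
        if n >= 20 and n % 20 == 0:
            reg = self.cov + 1e-8 * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(reg)
            except np.linalg.LinAlgError:
                pass

    def freeze(self) -> None:
        self.frozen = True


def _split_chains(x: np.ndarray) -> np.ndarray:
    c, n = x.shape
    h = n // 2
    return np.vstack([x[:, :h], x[:, n - h:]])


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    z = _split_chains(np.asarray(x, float))
    m, n = z.shape
    if n < 4:
        return float("nan")
    chain_means = z.mean(axis=1)
    W = float(z.var(axis=1, ddof=1).mean())
    B = n * float(chain_means.var(ddof=1))
    if W <= 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def ess_bulk(x: np.ndarray) -> float:
    """Bulk effective sample size (split chains, Geyer initial monotone
    positive sequence on the combined autocorrelation)."""
    z = _split_chains(np.asarray(x, float))
    m, n = z.shape
    if n < 4:
        return float(z.size)
    chain_means = z.mean(axis=1, keepdims=True)
    W = float(z.var(axis=1, ddof=1).mean())
    B = n * float(z.mean(axis=1).var(ddof=1)) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n
    if var_plus <= 0.0 or W <= 0.0:
        return float(z.size)
    # mean autocovariance across chains via FFT
    d = z - chain_means
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(d, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    rho[0] = 1.0
    # Geyer: sum consecutive pairs while positive, enforce monotonicity
    tau = 0.0
    prev = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        tau += pair
        prev = pair
        t += 2
    ess = z.size / (1.0 + 2.0 * tau)
    return float(min(ess, z.size))


def compute_diagnostics(draws: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Split-R-hat and bulk ESS per scalar parameter.

    ``draws`` maps names to arrays of shape (chain, draw) or
    (chain, draw, k); vector parameters are expanded componentwise.
    """
    scalars: dict[str, np.ndarray] = {}
    for name, arr in draws.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            scalars[name] = arr
        else:
            for j in range(arr.shape[2]):
                scalars[f"{name}[{j}]"] = arr[:, :, j]
    out: dict[str, dict[str, float]] = {}
    for name, x in scalars.items():
        r = split_rhat(x) if x.shape[0] >= 2 else float("nan")
        out[name] = {"rhat": r, "ess": ess_bulk(x)}
    return out
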