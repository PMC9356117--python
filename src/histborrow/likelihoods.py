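"""Exact log-likelihood kernels of the linear mixed model.

Four kernels are provided for the cLDA model ``y_i = X_i b + Z_i u_i + e_i``
with ``u_i ~ N(0, G)`` and ``e_i ~ N(0, s2 I)``:

* the conditional likelihood given the random effects,
* the marginal likelihood with the random effects integrated out,
  ``y_i ~ N(X_i b, Z_i G Z_i' + s2 I)``,
* the tempered marginal likelihood ``alpha * loglik`` used by the marginal
  modified power prior, and
* the tempered conditional likelihood with the random effects integrated out
  *after* raising to ``alpha``, used by the conditional modified power prior.

Raising a Gaussian density to a power rescales its variance, so the last
kernel is available in closed form: ``N(y; mu, s2 I)^alpha`` equals
``N(y; mu, (s2/alpha) I)`` times ``exp(((1-alpha) m / 2) log(2 pi s2)
- (m/2) log alpha)``, and the integral over ``u ~ N(0, G)`` is again a
Gaussian with covariance ``Z G Z' + (s2/alpha) I``.

All densities are natural-log; covariance solves use one Cholesky per
visit-time pattern (subjects sharing visit times share the marginal
covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ._kernels import group_loglik
from .data import DesignMatrices

__all__ = [
    "LMMParams",
    "conditional_loglik",
    "marginal_loglik",
    "tempered_marginal_loglik",
    "tempered_conditional_integrated_loglik",
    "tempered_conditional_dalpha",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class LMMParams:
    """Fixed effects, random-effects covariance and error variance.

    ``betaC`` covers the shared coefficients (intercept, covariates, time)
    and ``betaT`` the treatment-by-time interaction; ``G`` is the q x q
    random-effects covariance and ``sigma2`` the residual variance.
    """

    betaC: np.ndarray
    betaT: float
    G: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        betaC = np.atleast_1d(np.asarray(self.betaC, float))
        G = np.atleast_2d(np.asarray(self.G, float))
        object.__setattr__(self, "betaC", betaC)
        object.__setattr__(self, "G", G)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not np.allclose(G, G.T):
            raise ValueError("G must be symmetric")
        if np.linalg.eigvalsh(G).min() < -1e-10:
            raise ValueError("G must be positive semi-definite")

    def beta_for(self, design: DesignMatrices) -> np.ndarray:
        """Coefficient vector matching the design's column layout."""
        if design.has_treatment_column:
            beta = np.append(self.betaC, self.betaT)
        else:
            beta = self.betaC
        if beta.shape[0] != design.p:
            raise ValueError(
                f"coefficient length {beta.shape[0]} does not match design "
                f"columns {design.columns}"
            )
        return beta


def conditional_loglik(
    params: LMMParams, b: np.ndarray, data: DesignMatrices
) -> float:
    """Log-likelihood given the random effects.

    ``b`` holds one q-vector per subject, aligned with ``data.subjects``.
    """
    b = np.asarray(b, float)
    if b.shape != (data.n_subjects, data.q):
        raise ValueError(f"b must have shape {(data.n_subjects, data.q)}")
    beta = params.beta_for(data)
    s2 = params.sigma2
    total = 0.0
    for g in data.groups():
        resid = g.y - g.X @ beta - b[g.indices] @ g.Z.T
        total += -0.5 * (
            g.k * g.m * (_LOG2PI + np.log(s2)) + np.sum(resid**2) / s2
        )
    return float(total)


def _gaussian_groups_loglik(
    beta: np.ndarray, G: np.ndarray, s2: float, data: DesignMatrices
) -> float:
    """Sum of log N(y_i; X_i beta, Z G Z' + s2 I) over subjects."""
    beta = np.ascontiguousarray(beta, float)
    G = np.ascontiguousarray(G, float)
    total = 0.0
    for g in data.groups():
        total += group_loglik(g.X, g.y, g.Z, G, float(s2), beta)
    if not np.isfinite(total):
        raise np.linalg.LinAlgError(
            "non-finite marginal log-likelihood (covariance not PD?)"
        )
    return float(total)


def marginal_loglik(params: LMMParams, data: DesignMatrices) -> float:
    """Log-likelihood with the random effects integrated out."""
    return _gaussian_groups_loglik(
        params.beta_for(data), params.G, params.sigma2, data
    )


def tempered_marginal_loglik(
    params: LMMParams, alpha: float, data: DesignMatrices
) -> float:
    """``alpha`` times the marginal log-likelihood (marginal MPP kernel)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        return 0.0
    return alpha * marginal_loglik(params, data)


def tempered_conditional_integrated_loglik(
    params: LMMParams,
    alpha: float,
    data: DesignMatrices,
    on_zero: str = "limit",
) -> float:
    """Conditional-MPP kernel: random effects integrated out after tempering.

    Returns ``sum_i log int N(y_i; X_i b + Z u, s2 I)^alpha N(u; 0, G) du``.
    At ``alpha = 0`` the tempered density is identically one and the
    integral is 1, so the limit value is 0; set ``on_zero="error"`` to
    reject the endpoint instead.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        if on_zero == "limit":
            return 0.0
        raise ValueError("alpha = 0 not allowed with on_zero='error'")
    beta = params.beta_for(data)
    s2 = params.sigma2
    const_per_obs = 0.5 * (1.0 - alpha) * (_LOG2PI + np.log(s2))
    total = 0.0
    for g in data.groups():
        total += g.k * (g.m * const_per_obs - 0.5 * g.m * np.log(alpha))
    total += _gaussian_groups_loglik(beta, params.G, s2 / alpha, data)
    return float(total)


def tempered_conditional_dalpha(
    params: LMMParams, alpha: float, data: DesignMatrices
) -> float:
    """d/d(alpha) of :func:`tempered_conditional_integrated_loglik`.

    This is the path-sampling integrand of the conditional MPP.  With
    ``W = Z G Z' + (s2/alpha) I`` and residual ``r = y - X beta``:

    ``d/da = -(m/2) log(2 pi s2) - m/(2 a)
             + (s2 / (2 a^2)) (tr W^-1 - || W^-1 r ||^2)``

    per subject.  The ``alpha -> 0`` limit (the expectation of the
    conditional log-likelihood over the random-effects prior) is used at
    the grid origin:

    ``-(m/2) log(2 pi s2) - (tr(Z G Z') + ||r||^2) / (2 s2)``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    beta = params.beta_for(data)
    s2 = params.sigma2
    total = 0.0
    for g in data.groups():
        resid = g.y - g.X @ beta
        if alpha == 0.0:
            tr_zgz = float(np.trace(g.Z @ params.G @ g.Z.T))
            total += (
                -0.5 * g.k * g.m * (_LOG2PI + np.log(s2))
                - 0.5 * (g.k * tr_zgz + np.sum(resid**2)) / s2
            )
            continue
        W = g.Z @ params.G @ g.Z.T + (s2 / alpha) * np.eye(g.m)
        cf = cho_factor(W, lower=True)
        Winv = cho_solve(cf, np.eye(g.m))
        wr = cho_solve(cf, resid.T).T
        total += (
            -0.5 * g.k * g.m * (_LOG2PI + np.log(s2))
            - 0.5 * g.k * g.m / alpha
            + (s2 / (2.0 * alpha**2))
            * (g.k * float(np.trace(Winv)) - np.sum(wr**2))
        )
    return float(total)
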