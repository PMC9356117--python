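"""Internal linear-algebra blocks for the Gibbs samplers.

Every model variant here is linear-Gaussian in the fixed effects, so the
fixed-effect full conditional is multivariate normal with precision
``P0 + sum_i w X_i' V_i^-1 X_i`` and matching linear term.  These helpers
accumulate those sums per visit-time group and evaluate the historical
likelihood term of each borrowing mode.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from ._kernels import group_blocks
from .data import DesignMatrices
from .likelihoods import _gaussian_groups_loglik

_LOG2PI = float(np.log(2.0 * np.pi))


def wls_blocks(
    design: DesignMatrices, G: np.ndarray, s2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (sum_i X_i' V^-1 X_i, sum_i X_i' V^-1 y_i) for V = ZGZ' + s2 I."""
    p = design.p
    G = np.ascontiguousarray(G, float)
    A = np.zeros((p, p))
    b = np.zeros(p)
    for g in design.groups():
        Ag, bg = group_blocks(g.X, g.y, g.Z, G, float(s2))
        A += Ag
        b += bg
    return A, b


def hist_loglik_term(
    mode: str,
    betaC: np.ndarray,
    G: np.ndarray,
    s2: float,
    alpha: float,
    hist: DesignMatrices | None,
) -> float:
    """Historical likelihood contribution to the joint log-posterior.

    mode: "none" (no borrowing), "pool" (full weight), "marginal"
    (alpha times the marginal log-likelihood), or "conditional"
    (conditional likelihood tempered then integrated over the historical
    random effects).
    """
    if mode == "none" or hist is None:
        return 0.0
    if mode == "pool":
        return _gaussian_groups_loglik(betaC, G, s2, hist)
    if mode == "marginal":
        if alpha == 0.0:
            return 0.0
        return alpha * _gaussian_groups_loglik(betaC, G, s2, hist)
    if mode == "conditional":
        if alpha == 0.0:
            return 0.0
        n_obs = hist.n_obs
        const = n_obs * (
            0.5 * (1.0 - alpha) * (_LOG2PI + np.log(s2)) - 0.5 * np.log(alpha)
        )
        return const + _gaussian_groups_loglik(betaC, G, s2 / alpha, hist)
    raise ValueError(f"unknown borrowing mode {mode!r}")


def hist_beta_blocks(
    mode: str,
    G: np.ndarray,
    s2: float,
    alpha: float,
    hist: DesignMatrices | None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Historical contribution to the fixed-effect precision/linear term.

    Returned in the historical design's own column layout (the shared
    coefficients); the caller embeds it into the current layout.
    """
    if mode == "none" or hist is None:
        return None
    if mode == "pool":
        return wls_blocks(hist, G, s2)
    if mode == "marginal":
        if alpha == 0.0:
            return None
        A, b = wls_blocks(hist, G, s2)
        return alpha * A, alpha * b
    if mode == "conditional":
        if alpha == 0.0:
            return None
        return wls_blocks(hist, G, s2 / alpha)
    raise ValueError(f"unknown borrowing mode {mode!r}")


def draw_mvn_from_precision(
    A: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(A^-1 b, A^-1) given precision A and linear term b."""
    L = np.linalg.cholesky(A)
    mean = cho_solve((L, True), b)
    z = rng.standard_normal(b.shape[0])
    # A = L L'  =>  solving L' x = z yields cov A^-1
    return mean + solve_triangular(L, z, trans="T", lower=True)
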