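"""Hot-path group kernels, JIT-compiled when numba is available.

Subjects sharing a visit-time pattern share the marginal covariance
``V = Z G Z' + s2 I``; these kernels factorise V once per group and loop
over the group's subjects.  The pure-numpy fallbacks double as reference
implementations for the consistency tests.
"""

from __future__ import annotations

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _group_loglik_jit(X, y, Z, G, s2, beta):
    k, m, p = X.shape
    V = Z @ G @ Z.T + s2 * np.eye(m)
    L = np.linalg.cholesky(V)
    logdet = 0.0
    for j in range(m):
        logdet += 2.0 * np.log(L[j, j])
    R = np.empty((m, k))
    for i in range(k):
        for j in range(m):
            acc = y[i, j]
            for l in range(p):
                acc -= X[i, j, l] * beta[l]
            R[j, i] = acc
    W = np.linalg.solve(L, R)
    quad = 0.0
    for j in range(m):
        for i in range(k):
            quad += W[j, i] * W[j, i]
    return -0.5 * (k * (m * _LOG2PI + logdet) + quad)


@njit(cache=True)
def _group_blocks_jit(X, y, Z, G, s2):
    k, m, p = X.shape
    V = Z @ G @ Z.T + s2 * np.eye(m)
    Winv = np.linalg.inv(V)
    A = np.zeros((p, p))
    b = np.zeros(p)
    for i in range(k):
        XW = X[i].T @ Winv
        A += XW @ X[i]
        b += XW @ y[i]
    return A, b


def _group_loglik_np(X, y, Z, G, s2, beta):
    from scipy.linalg import cho_factor, cho_solve

    k, m, _ = X.shape
    V = Z @ G @ Z.T + s2 * np.eye(m)
    cf = cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    resid = y - X @ beta
    quad = float(np.sum(resid * cho_solve(cf, resid.T).T))
    return -0.5 * (k * (m * _LOG2PI + logdet) + quad)


def _group_blocks_np(X, y, Z, G, s2):
    V = Z @ G @ Z.T + s2 * np.eye(Z.shape[0])
    Winv = np.linalg.inv(V)
    XW = np.einsum("kmp,mn->knp", X, Winv)
    A = np.einsum("knp,knq->pq", XW, X)
    b = np.einsum("knp,kn->p", XW, y)
    return A, b


if HAVE_NUMBA:
    group_loglik = _group_loglik_jit
    group_blocks = _group_blocks_jit
else:  # pragma: no cover
    group_loglik = _group_loglik_np
    group_blocks = _group_blocks_np
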