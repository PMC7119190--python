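"""Independent brute-force oracles used by the tests.

Everything here evaluates the GxE mixed model by explicit dense linear
algebra in the N x N plot space — deliberately the slow, transparent route,
kept separate from the package's cell-space implementation so the two can
be compared.
"""

import numpy as np


def dense_matrices(model, vc):
    """Explicit V, Z, X for a MultiEnvGBLUP instance at components vc."""
    n, t, N = model.n, model.t, model.N
    Gc = np.kron(vc.G, model.K)
    Z = np.zeros((N, n * t))
    Z[np.arange(N), model.plot_cell] = 1.0
    R = np.diag(vc.sigma2[model.plot_env])
    V = Z @ Gc @ Z.T + R
    return V, Z, Gc


def dense_reml_loglik(model, vc):
    """Restricted log-likelihood via log|V|, log|X'V^-1 X|, y'Py."""
    V, _, _ = dense_matrices(model, vc)
    X, y = model.X, model.y
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    N, p = len(y), X.shape[1]
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1]
                   + y @ P @ y + (N - p) * np.log(2 * np.pi))


def dense_gls_blup(model, vc):
    """GLS fixed effects and BLUPs by direct inversion of V."""
    V, Z, Gc = dense_matrices(model, vc)
    X, y = model.X, model.y
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    u = Gc @ Z.T @ P @ y          # env-major cell order
    return beta, u


def balanced_oneway_reml(y_matrix):
    """Closed-form REML for a balanced one-way random-effects layout.

    ``y_matrix`` is lines x replicates. Returns (genetic variance,
    residual variance) from the expected mean squares, with the genetic
    component truncated at zero. Matches a K = identity, single-environment
    GBLUP fit.
    """
    y = np.asarray(y_matrix, dtype=float)
    n, r = y.shape
    line_means = y.mean(axis=1)
    mse = ((y - line_means[:, None]) ** 2).sum() / (n * (r - 1))
    msb = r * ((line_means - line_means.mean()) ** 2).sum() / (n - 1)
    return max((msb - mse) / r, 0.0), mse


def nelder_mead_best_loglik(model, n_restarts=3, maxiter=2000, seed=0):
    """Best restricted log-likelihood found by a derivative-free search.

    Searches the log-Cholesky / log-sigma2 space with Nelder-Mead from a
    few jittered starts, evaluating the dense oracle likelihood.
    """
    from scipy.optimize import minimize

    from gxegblup.model import VarianceComponents

    t = model.t

    def unpack(zv):
        L = np.zeros((t, t))
        k = 0
        for i in range(t):
            for j in range(i + 1):
                L[i, j] = np.exp(zv[k]) if i == j else zv[k]
                k += 1
        return L @ L.T, np.exp(zv[k:k + t])

    vy = np.log(max(np.var(model.y) / 2.0, 1e-8))

    def neg(zv):
        G, s2 = unpack(zv)
        try:
            vc = VarianceComponents(G, s2, model.env_ids)
            return -dense_reml_loglik(model, vc)
        except Exception:
            return 1e12

    nz = t * (t + 1) // 2 + t
    z0 = np.zeros(nz)
    z0[: t * (t + 1) // 2: 1] = 0.0
    z0[-t:] = vy
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_restarts):
        start = z0 + 0.3 * rng.standard_normal(nz)
        res = minimize(neg, start, method="Nelder-Mead",
                       options={"maxiter": maxiter, "fatol": 1e-10,
                                "xatol": 1e-8})
        best = min(best, res.fun)
    return -best
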