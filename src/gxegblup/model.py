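"""Multi-environment GBLUP with an unstructured genetic covariance.

The model treats the same trait measured in t environments as t correlated
genetic effects:

    y = X beta + Z u + e,   Var(u) = G (x) K,   Var(e) = blockdiag_i sigma2_i I

where ``y`` stacks plot-level records, ``X`` carries environment (and
optionally replicate-within-environment) fixed effects, ``u`` is the vector
of genetic values of every line in every environment, ``K`` is the additive
genomic relationship matrix, ``G`` is the t x t across-environment genetic
covariance (unstructured, estimated), and residual variances are
heterogeneous across environments but iid within. ``(x)`` is the Kronecker
product.

Variance components are estimated by restricted maximum likelihood using
average-information (AI) updates with ridge damping and step-halving, so the
restricted log-likelihood trace is monotone nondecreasing. All heavy linear
algebra is done in the n*t-dimensional cell space through the Woodbury
identity, never in the N x N plot space, which keeps fits fast for a few
hundred lines. Genomic estimated breeding values (GEBVs) for every line in
K — phenotyped or not — are the BLUPs at the converged components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .kinship import GenomicRelationship

__all__ = [
    "PhenotypeTable", "ModelSpec", "VarianceComponents",
    "MultiEnvGBLUP", "MultiEnvGBLUPResults",
    "fit_gxe_gblup", "reml_loglik", "compute_blues",
    "heritability", "genetic_correlations",
]

LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format plot records: one row per plot.

    Canonical columns of ``df``: ``line``, ``env``, ``rep`` (optional),
    ``block`` (optional), ``value``. ``(line, env, rep)`` combinations must
    be unique and values finite.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        for col in ("line", "env", "value"):
            if col not in df.columns:
                raise ValueError(f"phenotype table lacks column {col!r}")
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite phenotype values")
        key_cols = ["line", "env"] + (["rep"] if "rep" in df.columns else [])
        if df.duplicated(subset=key_cols).any():
            raise ValueError(f"duplicate {tuple(key_cols)} combinations")
        object.__setattr__(self, "df", df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, line_col="line", env_col="env",
                       value_col="value", rep_col=None, block_col=None
                       ) -> "PhenotypeTable":
        out = pd.DataFrame({
            "line": df[line_col].astype(str),
            "env": df[env_col].astype(str),
        })
        if rep_col is not None and rep_col in df.columns:
            out["rep"] = df[rep_col].astype(str)
        if block_col is not None and block_col in df.columns:
            out["block"] = df[block_col].astype(str)
        out["value"] = df[value_col].astype(float)
        return cls(out)

    @property
    def environments(self) -> list:
        return sorted(self.df["env"].unique())

    @property
    def lines(self) -> list:
        return sorted(self.df["line"].unique())

    def observed_cells(self) -> set:
        return set(zip(self.df["line"], self.df["env"]))

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect layout and residual structure of the GxE model.

    ``fixed_terms`` always contains ``"environment"``; add ``"replicate"``
    for replicate-within-environment fixed effects (used only when the data
    carry a ``rep`` column). Residuals are one independent variance per
    environment — that structure is fixed, not configurable.
    """

    trait_name: str = "trait"
    fixed_terms: tuple = ("environment", "replicate")

    def __post_init__(self):
        terms = tuple(self.fixed_terms)
        if "environment" not in terms:
            raise ValueError("fixed_terms must include 'environment'")
        unknown = set(terms) - {"environment", "replicate"}
        if unknown:
            raise ValueError(f"unknown fixed terms {sorted(unknown)}")
        object.__setattr__(self, "fixed_terms", terms)


@dataclass(frozen=True)
class VarianceComponents:
    """Across-environment genetic covariance G and residual variances."""

    G: np.ndarray
    sigma2: np.ndarray
    environment_ids: tuple

    def __post_init__(self):
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        s2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        env = tuple(self.environment_ids)
        t = len(env)
        if G.shape != (t, t):
            raise ValueError(f"G is {G.shape} for {t} environments")
        if s2.shape != (t,):
            raise ValueError(f"sigma2 is {s2.shape} for {t} environments")
        if not np.allclose(G, G.T, atol=1e-8 * max(1.0, np.abs(G).max())):
            raise ValueError("G is not symmetric")
        if (s2 <= 0).any():
            raise ValueError("residual variances must be positive")
        ev = np.linalg.eigvalsh(G)
        if ev[0] < -1e-8 * max(ev[-1], 1.0):
            raise ValueError(f"G has negative eigenvalue {ev[0]:.3e}")
        object.__setattr__(self, "G", 0.5 * (G + G.T))
        object.__setattr__(self, "sigma2", s2)
        object.__setattr__(self, "environment_ids", env)

    @property
    def t(self) -> int:
        return len(self.environment_ids)


def heritability(vc: VarianceComponents) -> pd.Series:
    """Plot-level heritability per environment: ``h2_i = g_ii/(g_ii + s2_i)``."""
    g = np.diag(vc.G)
    h2 = g / (g + vc.sigma2)
    return pd.Series(h2, index=list(vc.environment_ids), name="h2")

def genetic_correlations(vc: VarianceComponents) -> pd.DataFrame:
    """Across-environment genetic correlation matrix ``g_ij/sqrt(g_ii g_jj)``."""
    g = np.diag(vc.G)
    if (g <= 0).any():
        raise ValueError("zero genetic variance: correlations undefined")
    d = 1.0 / np.sqrt(g)
    R = vc.G * np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    env = list(vc.environment_ids)
    return pd.DataFrame(np.clip(R, -1.0, 1.0), index=env, columns=env)


def bend_to_pd(G: np.ndarray, rel_floor: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix onto the PD cone by eigenvalue bending.

    Eigenvalues below ``rel_floor * max_eigenvalue`` are raised to that
    floor. Returns (bent matrix, whether bending changed anything).
    """
    G = 0.5 * (G + G.T)
    ev, U = np.linalg.eigh(G)
    top = ev[-1]
    if top <= 0:
        scale = max(np.abs(np.diag(G)).max(), 1.0)
        return np.eye(G.shape[0]) * scale * rel_floor, True
    floor = rel_floor * top
    if ev[0] >= floor:
        return G, False
    ev = np.clip(ev, floor, None)
    return (U * ev) @ U.T, True


# ---------------------------------------------------------------------------
# model


class MultiEnvGBLUP:
    """Genomic BLUP across environments with unstructured genetic covariance.

    Parameters
    ----------
    pheno : PhenotypeTable or DataFrame
        Plot-level records with columns ``line``, ``env``, optional ``rep``,
        ``value``. Every phenotyped line must appear in ``K``.
    K : GenomicRelationship
        Additive relationship matrix; lines present only in K (no records)
        receive genomic predictions through their relationships.
    spec : ModelSpec, optional

    Examples
    --------
    >>> model = MultiEnvGBLUP(pheno, K)
    >>> res = model.fit()
    >>> res.genetic_correlations()
    """

    def __init__(self, pheno, K: GenomicRelationship, spec: ModelSpec | None = None):
        if isinstance(pheno, pd.DataFrame):
            pheno = PhenotypeTable(pheno)
        self.pheno = pheno
        self.K_rel = K
        self.spec = spec or ModelSpec()

        df = pheno.df
        self.env_ids = tuple(pheno.environments)
        self.line_ids = tuple(K.line_ids)
        missing = set(df["line"]) - set(self.line_ids)
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped lines absent from K, e.g. "
                f"{sorted(missing)[:3]}")
        self.t = len(self.env_ids)
        self.n = len(self.line_ids)
        if self.t >= 2:
            per_env = df.groupby("env")["line"].nunique()
            if (per_env < 2).any():
                raise ValueError("each environment needs >= 2 distinct lines")

        line_pos = {l: i for i, l in enumerate(self.line_ids)}
        env_pos = {e: j for j, e in enumerate(self.env_ids)}
        self.y = df["value"].to_numpy(dtype=float)
        self.N = len(self.y)
        self.plot_env = df["env"].map(env_pos).to_numpy()
        plot_line = df["line"].map(line_pos).to_numpy()
        # cells ordered environment-major: cell = env * n + line
        self.plot_cell = self.plot_env * self.n + plot_line
        self.nt = self.n * self.t
        self.r_cell = np.bincount(self.plot_cell, minlength=self.nt).astype(float)
        self.cell_env = np.repeat(np.arange(self.t), self.n)
        self.K = K.K
        self.X, self.exog_names = self._build_design(df)
        self.p = self.X.shape[1]

    # -- design matrix ------------------------------------------------------

    def _build_design(self, df):
        cols, names = [], []
        for j, e in enumerate(self.env_ids):
            cols.append((self.plot_env == j).astype(float))
            names.append(f"env[{e}]")
        if "replicate" in self.spec.fixed_terms and "rep" in df.columns:
            for j, e in enumerate(self.env_ids):
                in_env = self.plot_env == j
                reps = sorted(df.loc[in_env, "rep"].unique())
                for r in reps[1:]:  # first replicate is the reference level
                    col = (in_env & (df["rep"] == r).to_numpy()).astype(float)
                    cols.append(col)
                    names.append(f"rep[{e}:{r}]")
        X = np.column_stack(cols)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, _, piv = sla.qr(X, pivoting=True, mode="economic")
            aliased = [names[i] for i in piv[rank:]]
            raise ValueError(f"aliased fixed-effect columns: {aliased}")
        return X, names

    # -- cell-space algebra -------------------------------------------------

    def _agg(self, v):
        """Z' v : accumulate a plot vector (or matrix) into cells."""
        if v.ndim == 1:
            return np.bincount(self.plot_cell, weights=v, minlength=self.nt)
        out = np.zeros((self.nt, v.shape[1]))
        for k in range(v.shape[1]):
            out[:, k] = np.bincount(self.plot_cell, weights=v[:, k],
                                    minlength=self.nt)
        return out

    def _expand(self, c):
        """Z c : broadcast a cell vector back to plots."""
        return c[self.plot_cell]

    def _factorize(self, vc: VarianceComponents, need_H: bool = False):
        """Woodbury factorisation of V = Z (G x K) Z' + R at ``vc``.

        Returns a dict of reusable pieces; ``H = (G x K)(I + D(G x K))^-1``
        (needed for trace terms) is only formed on request.
        """
        sigma2 = vc.sigma2
        w = 1.0 / sigma2[self.plot_env]          # R^-1 diagonal, per plot
        d = self.r_cell / sigma2[self.cell_env]  # D = Z'R^-1 Z diagonal
        Gc = np.kron(vc.G, self.K)
        B = d[:, None] * Gc
        B[np.diag_indices_from(B)] += 1.0        # B = I + D Gc
        lu, piv = sla.lu_factor(B, check_finite=False)
        logdetB = float(np.log(np.abs(np.diag(lu))).sum())
        fac = {"w": w, "d": d, "Gc": Gc, "lu": (lu, piv), "logdetB": logdetB,
               "sigma2": sigma2}
        if need_H:
            # H = Gc B^-1 = (B^-T Gc)^T ; symmetric
            H = sla.lu_solve((lu, piv), Gc, trans=1, check_finite=False).T
            fac["H"] = H
        return fac

    def _vinv(self, fac, v):
        """V^-1 v for a plot vector or matrix of columns."""
        w = fac["w"]
        wv = v * (w if v.ndim == 1 else w[:, None])
        c = self._agg(wv)
        c = sla.lu_solve(fac["lu"], c, check_finite=False)
        c = fac["Gc"] @ c
        return wv - self._expand(c) * (w if v.ndim == 1 else w[:, None])

    def _gls_pieces(self, fac):
        """V^-1 applied to [X | y] plus the REML building blocks."""
        Xy = np.column_stack([self.X, self.y])
        VinvXy = self._vinv(fac, Xy)
        VinvX, Vinvy = VinvXy[:, :-1], VinvXy[:, -1]
        XtVinvX = self.X.T @ VinvX
        XtVinvy = self.X.T @ Vinvy
        cho = sla.cho_factor(XtVinvX, check_finite=False)
        beta = sla.cho_solve(cho, XtVinvy, check_finite=False)
        Py = Vinvy - VinvX @ beta
        ytPy = float(self.y @ Py)
        logdetXtVinvX = 2.0 * float(np.log(np.diag(cho[0])).sum())
        return {"VinvX": VinvX, "Vinvy": Vinvy, "XtVinvX": XtVinvX,
                "cho": cho, "beta": beta, "Py": Py, "ytPy": ytPy,
                "logdetXtVinvX": logdetXtVinvX}

    def loglike(self, vc: VarianceComponents) -> float:
        """Restricted log-likelihood at the given variance components."""
        vc = self._check_vc(vc)
        fac = self._factorize(vc)
        gls = self._gls_pieces(fac)
        logdetV = fac["logdetB"] + float(
            np.log(vc.sigma2[self.plot_env]).sum())
        return -0.5 * (logdetV + gls["logdetXtVinvX"] + gls["ytPy"]
                       + (self.N - self.p) * LOG2PI)

    def _safe_loglike(self, vc: VarianceComponents) -> float:
        """loglike that reports numerical breakdown as -inf (for line search)."""
        try:
            return self.loglike(vc)
        except (np.linalg.LinAlgError, sla.LinAlgError, ValueError):
            return -np.inf

    def _check_vc(self, vc: VarianceComponents) -> VarianceComponents:
        if tuple(vc.environment_ids) != self.env_ids:
            raise ValueError(
                f"components are for environments {vc.environment_ids}, "
                f"data has {self.env_ids}")
        return vc

    # -- parameter vector <-> components ------------------------------------

    def _param_index(self):
        idx = [("G", j, k) for j in range(self.t) for k in range(j, self.t)]
        idx += [("s2", j, j) for j in range(self.t)]
        return idx

    def _pack(self, vc):
        theta = [vc.G[j, k] for kind, j, k in self._param_index() if kind == "G"]
        return np.array(theta + list(vc.sigma2))

    def _unpack(self, theta):
        G = np.zeros((self.t, self.t))
        pos = 0
        for j in range(self.t):
            for k in range(j, self.t):
                G[j, k] = G[k, j] = theta[pos]
                pos += 1
        sigma2 = np.asarray(theta[pos:])
        return G, sigma2

    # -- log-Cholesky transform ---------------------------------------------
    #
    # Optimisation runs in z = (lower-triangle of L with log-diagonal,
    # log sigma2), G = L L', which keeps every visited point inside the
    # parameter space without bending.

    _Z_CLIP = 25.0  # |log| bound, keeps exp() finite

    def _z_index(self):
        return [(i, j) for i in range(self.t) for j in range(i + 1)]

    def _z_from_vc(self, vc: VarianceComponents) -> np.ndarray:
        G, _ = bend_to_pd(vc.G)
        L = np.linalg.cholesky(G)
        z = [np.log(L[i, i]) if i == j else L[i, j]
             for i, j in self._z_index()]
        return np.clip(np.array(z + list(np.log(vc.sigma2))),
                       -self._Z_CLIP, self._Z_CLIP)

    def _vc_from_z(self, z: np.ndarray) -> VarianceComponents:
        z = np.clip(z, -self._Z_CLIP, self._Z_CLIP)
        L = np.zeros((self.t, self.t))
        for a, (i, j) in enumerate(self._z_index()):
            L[i, j] = np.exp(z[a]) if i == j else z[a]
        nz = self.t * (self.t + 1) // 2
        return VarianceComponents(L @ L.T, np.exp(z[nz:]), self.env_ids)

    def _jacobian(self, z: np.ndarray) -> np.ndarray:
        """d theta / d z, theta in the natural `_param_index` order."""
        zi = self._z_index()
        nz = len(zi)
        L = np.zeros((self.t, self.t))
        for a, (i, j) in enumerate(zi):
            L[i, j] = np.exp(z[a]) if i == j else z[a]
        idx = self._param_index()
        J = np.zeros((len(idx), nz + self.t))
        for b, (i, j) in enumerate(zi):
            M = np.zeros((self.t, self.t))
            M[i, j] = L[i, j] if i == j else 1.0
            dG = M @ L.T + L @ M.T
            for a, (kind, p, q) in enumerate(idx):
                if kind == "G":
                    J[a, b] = dG[p, q]
        sigma2 = np.exp(np.clip(z[nz:], -self._Z_CLIP, self._Z_CLIP))
        for e in range(self.t):
            a = next(a for a, (kind, p, _) in enumerate(idx)
                     if kind == "s2" and p == e)
            J[a, nz + e] = sigma2[e]
        return J

    def _default_start(self) -> VarianceComponents:
        """g_ii = s2_i = half the per-environment phenotypic variance,
        g_ij = 0.3 sqrt(g_ii g_jj)."""
        var_env = np.ones(self.t)
        df = self.pheno.df
        for j, e in enumerate(self.env_ids):
            v = df.loc[df["env"] == e, "value"].var(ddof=1)
            var_env[j] = v if np.isfinite(v) and v > 0 else 1.0
        g = var_env / 2.0
        G = 0.3 * np.sqrt(np.outer(g, g))
        np.fill_diagonal(G, g)
        return VarianceComponents(G, var_env / 2.0, self.env_ids)

    # -- score and average information --------------------------------------

    def _score_ai(self, vc):
        """Score vector and average-information matrix at ``vc``."""
        t, n, nt = self.t, self.n, self.nt
        fac = self._factorize(vc, need_H=True)
        gls = self._gls_pieces(fac)
        H, d, K = fac["H"], fac["d"], self.K
        Py, VinvX, cho = gls["Py"], gls["VinvX"], gls["cho"]
        idx = self._param_index()
        npar = len(idx)

        # S = Z' V^-1 Z = D - D H D, as t x t blocks of n x n
        S = np.diag(d) - (d[:, None] * H) * d[None, :]
        S4 = S.reshape(t, n, t, n)
        trKS = np.einsum("ab,jakb->jk", K, S4)          # tr(K S_jk)

        A = self._agg(VinvX)                            # Z' V^-1 X, nt x p
        A3 = A.reshape(t, n, self.p)
        KA = np.einsum("ab,kbp->kap", K, A3)            # K A_k per block
        c = self._agg(Py)
        c4 = c.reshape(t, n)
        Kc = c4 @ K.T                                   # row j = K c_j

        Hdiag = np.diag(H)
        VinvX_sq = VinvX[:, :, None] * VinvX[:, None, :]

        score = np.zeros(npar)
        qvecs = np.zeros((self.N, npar))
        for a, (kind, j, k) in enumerate(idx):
            if kind == "G":
                if j == k:
                    trV = trKS[j, j]
                    M2 = A3[j].T @ KA[j]
                    qf = float(c4[j] @ Kc[j])
                    u = np.zeros((t, n))
                    u[j] = Kc[j]
                else:
                    trV = 2.0 * trKS[j, k]
                    M2 = A3[j].T @ KA[k] + A3[k].T @ KA[j]
                    qf = 2.0 * float(c4[j] @ Kc[k])
                    u = np.zeros((t, n))
                    u[j] = Kc[k]
                    u[k] = Kc[j]
                qvecs[:, a] = self._expand(u.ravel())
            else:  # sigma2 of environment j
                mask = self.plot_env == j
                in_env = self.cell_env == j
                s2 = vc.sigma2[j]
                trV = mask.sum() / s2 - float(
                    (self.r_cell[in_env] * Hdiag[in_env]).sum()) / s2**2
                M2 = VinvX_sq[mask].sum(axis=0)
                qf = float((Py[mask] ** 2).sum())
                qvecs[:, a] = np.where(mask, Py, 0.0)
            trP = trV - float(np.trace(sla.cho_solve(cho, M2, check_finite=False)))
            score[a] = -0.5 * (trP - qf)

        Pq = self._vinv(fac, qvecs)
        Pq -= VinvX @ sla.cho_solve(cho, VinvX.T @ qvecs, check_finite=False)
        AI = 0.5 * (qvecs.T @ Pq)
        AI = 0.5 * (AI + AI.T)
        ll = -0.5 * (fac["logdetB"]
                     + float(np.log(vc.sigma2[self.plot_env]).sum())
                     + gls["logdetXtVinvX"] + gls["ytPy"]
                     + (self.N - self.p) * LOG2PI)
        return score, AI, ll

    # -- fitting -------------------------------------------------------------

    def fit(self, start: VarianceComponents | None = None, tol: float = 1e-6,
            maxiter: int = 100) -> "MultiEnvGBLUPResults":
        """Estimate variance components by AI-REML and solve for the BLUPs.

        AI (average-information) updates are damped by step-halving whenever
        a proposal decreases the restricted log-likelihood, with a
        Levenberg-Marquardt ridge on the AI matrix as a fallback, so the
        log-likelihood trace is monotone nondecreasing. Convergence requires
        ``|delta logREML| < tol`` and a maximum relative parameter change
        below ``10 * tol``. Non-convergence is flagged, not raised.
        """
        vc = self._check_vc(start) if start is not None else self._default_start()
        bent_any = not np.array_equal(bend_to_pd(vc.G)[0], vc.G)
        z = self._z_from_vc(vc)
        vc = self._vc_from_z(z)
        scale = max(float(np.var(self.y)), 1e-12)

        trace = []
        converged = False
        ll = -np.inf
        n_stalled = 0  # consecutive near-zero steps (boundary optima)
        lam = 1e-6  # Levenberg-Marquardt damping, adapted across iterations
        for it in range(maxiter):
            score, AI, ll = self._score_ai(vc)
            trace.append(ll)
            J = self._jacobian(z)
            score_z = J.T @ score
            AI_z = J.T @ AI @ J
            AI_z = 0.5 * (AI_z + AI_z.T)
            base = max(np.abs(np.diag(AI_z)).max(), 1e-12)

            new_z, new_ll, rel_change = None, None, np.inf
            theta = self._pack(vc)
            used_lam = lam
            for _ in range(40):
                M = AI_z + used_lam * base * np.eye(len(z))
                try:
                    delta = np.linalg.solve(M, score_z)
                except np.linalg.LinAlgError:
                    used_lam *= 10.0
                    continue
                if np.isfinite(delta).all():
                    # step-halve the damped step until the restricted
                    # likelihood does not decrease
                    step, accepted = 1.0, False
                    for _ in range(4):
                        cand_z = z + step * delta
                        cand_vc = self._vc_from_z(cand_z)
                        cand_ll = self._safe_loglike(cand_vc)
                        if np.isfinite(cand_ll) and cand_ll >= ll - 1e-8:
                            accepted = True
                            break
                        step *= 0.5
                    if accepted:
                        new_z, new_vc, new_ll = cand_z, cand_vc, cand_ll
                        rel_change = float(np.max(
                            np.abs(self._pack(cand_vc) - theta)
                            / np.maximum(np.abs(theta), 1e-3 * scale)))
                        break
                used_lam = max(used_lam, 1e-8) * 10.0
            lam = max(used_lam / 10.0, 1e-8)

            if new_z is None:
                # no ascent direction found even under heavy damping:
                # treat as a stationary point
                converged = True
                break
            dll = new_ll - ll
            z, vc, ll = new_z, new_vc, new_ll
            # interior optimum: a lightly damped (near-Newton) step that
            # changes neither the likelihood nor the parameters
            if dll < tol and rel_change < 10.0 * tol and used_lam <= 1e-2:
                converged = True
                trace.append(ll)
                break
            # boundary optimum (e.g. genetic correlation pinned at +-1):
            # the likelihood stalls while parameters oscillate on the ridge
            n_stalled = n_stalled + 1 if dll < tol else 0
            if n_stalled >= 3:
                converged = True
                trace.append(ll)
                break
        n_iter = len(trace)

        fac = self._factorize(vc)
        gls = self._gls_pieces(fac)
        c = self._agg(gls["Py"]).reshape(self.t, self.n)
        u = vc.G @ (c @ self.K.T)          # u_j = sum_k G_jk K c_k
        u_hat = pd.DataFrame(u.T, index=list(self.line_ids),
                             columns=list(self.env_ids))
        beta = pd.Series(gls["beta"], index=self.exog_names, name="beta")
        llf = self.loglike(vc)
        beta_cov = np.linalg.inv(gls["XtVinvX"])
        return MultiEnvGBLUPResults(
            model=self, vc=vc, beta=beta, beta_cov=beta_cov, u_hat=u_hat,
            llf=llf, n_iter=n_iter, converged=converged,
            trace=np.array(trace), bent=bent_any)


@dataclass
class MultiEnvGBLUPResults:
    """Results of a :class:`MultiEnvGBLUP` fit.

    Attributes
    ----------
    vc : VarianceComponents
        REML estimates of G and the per-environment residual variances.
    beta : Series
        Fixed-effect estimates (GLS at the converged components).
    u_hat : DataFrame, lines x environments
        BLUPs / GEBVs for every line in K, including unphenotyped lines.
    llf : float
        Restricted log-likelihood at convergence.
    trace : ndarray
        Per-iteration restricted log-likelihood (monotone nondecreasing).
    """

    model: MultiEnvGBLUP
    vc: VarianceComponents
    beta: pd.Series
    beta_cov: np.ndarray
    u_hat: pd.DataFrame
    llf: float
    n_iter: int
    converged: bool
    trace: np.ndarray
    bent: bool = False

    def heritability(self) -> pd.Series:
        return heritability(self.vc)

    def genetic_correlations(self) -> pd.DataFrame:
        return genetic_correlations(self.vc)

    def predict(self, cells=None) -> pd.DataFrame:
        """Predicted cell values ``env effect (+ mean replicate effect) + GEBV``.

        Parameters
        ----------
        cells : iterable of (line, env), optional
            Cells to predict; defaults to every line x environment cell.
        """
        m = self.model
        env_eff = {}
        df = m.pheno.df
        for j, e in enumerate(m.env_ids):
            val = self.beta[f"env[{e}]"]
            # add frequency-weighted mean of replicate effects so predictions
            # sit on the same scale as replicate-adjusted BLUEs
            rep_cols = [nm for nm in m.exog_names if nm.startswith(f"rep[{e}:")]
            if rep_cols:
                in_env = df["env"] == e
                n_env = int(in_env.sum())
                for nm in rep_cols:
                    r = nm[len(f"rep[{e}:"):-1]
                    frac = float((in_env & (df["rep"] == r)).sum()) / n_env
                    val += frac * self.beta[nm]
            env_eff[e] = val
        if cells is None:
            cells = [(l, e) for e in m.env_ids for l in m.line_ids]
        rows = [(l, e, env_eff[e] + self.u_hat.at[l, e],
                 self.u_hat.at[l, e]) for l, e in cells]
        return pd.DataFrame(rows, columns=["line", "env", "prediction", "gebv"])

    def summary(self) -> str:
        vc = self.vc
        env = list(vc.environment_ids)
        lines = []
        lines.append("Multi-environment GBLUP (unstructured G, AI-REML)")
        lines.append("=" * 56)
        lines.append(f"No. lines in K: {self.model.n:>6d}   "
                     f"No. records: {self.model.N}")
        lines.append(f"Environments:   {len(env):>6d}   "
                     f"logREML: {self.llf:.4f}")
        lines.append(f"Converged: {str(self.converged):>11s}   "
                     f"Iterations: {self.n_iter}")
        lines.append("-" * 56)
        lines.append("Genetic covariance G:")
        lines.append(genetic_correlations(vc).round(3).to_string())
        lines.append("(shown as correlations; variances below)")
        tbl = pd.DataFrame({
            "genetic_var": np.diag(vc.G),
            "residual_var": vc.sigma2,
            "plot_h2": heritability(vc).to_numpy(),
        }, index=env)
        lines.append(tbl.round(4).to_string())
        lines.append("-" * 56)
        lines.append("Fixed effects:")
        lines.append(self.beta.round(4).to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "environments": list(self.vc.environment_ids),
            "G": self.vc.G.tolist(),
            "sigma2": self.vc.sigma2.tolist(),
            "genetic_correlations": self.genetic_correlations().to_numpy().tolist(),
            "plot_h2": self.heritability().to_numpy().tolist(),
            "beta": self.beta.to_dict(),
            "logREML": self.llf,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# functional wrappers


def fit_gxe_gblup(pheno, K: GenomicRelationship, spec: ModelSpec | None = None,
                  init: VarianceComponents | None = None, tol: float = 1e-6,
                  max_iter: int = 100) -> MultiEnvGBLUPResults:
    """Fit the across-environment GBLUP model; see :class:`MultiEnvGBLUP`."""
    return MultiEnvGBLUP(pheno, K, spec).fit(start=init, tol=tol,
                                             maxiter=max_iter)


def reml_loglik(vc: VarianceComponents, pheno, K: GenomicRelationship,
                spec: ModelSpec | None = None) -> float:
    """Restricted log-likelihood of the GxE model at fixed components."""
    return MultiEnvGBLUP(pheno, K, spec).loglike(vc)


def compute_blues(pheno, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Per-environment BLUEs with genotype as a fixed factor.

    Each environment is analysed independently by least squares with one
    fixed effect per line plus (when the ModelSpec includes them and the data
    carry a ``rep`` column) replicate fixed effects. The reported BLUE is
    the line effect evaluated at the frequency-weighted average replicate,
    so for balanced data without blocks it is the per-line plot mean, and
    with a single plot per cell it is the raw observation.

    Returns a DataFrame with columns ``line``, ``env``, ``blue``,
    ``n_plots``; only observed cells appear.
    """
    if isinstance(pheno, pd.DataFrame):
        pheno = PhenotypeTable(pheno)
    spec = spec or ModelSpec()
    df = pheno.df
    use_rep = "replicate" in spec.fixed_terms and "rep" in df.columns
    out = []
    for e in pheno.environments:
        sub = df[df["env"] == e]
        lines = sorted(sub["line"].unique())
        lpos = {l: i for i, l in enumerate(lines)}
        y = sub["value"].to_numpy(dtype=float)
        nL = len(lines)
        Xl = np.zeros((len(sub), nL))
        Xl[np.arange(len(sub)), sub["line"].map(lpos)] = 1.0
        rep_means = 0.0
        if use_rep:
            reps = sorted(sub["rep"].unique())
            Xr = np.zeros((len(sub), max(len(reps) - 1, 0)))
            for i, r in enumerate(reps[1:]):
                Xr[:, i] = (sub["rep"] == r).to_numpy(dtype=float)
            X = np.hstack([Xl, Xr])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            blue = coef[:nL]
            if Xr.shape[1]:
                freqs = Xr.mean(axis=0)
                rep_means = float(freqs @ coef[nL:])
        else:
            coef, *_ = np.linalg.lstsq(Xl, y, rcond=None)
            blue = coef
        counts = sub.groupby("line").size()
        for l in lines:
            out.append((l, e, float(blue[lpos[l]] + rep_means),
                        int(counts[l])))
    return pd.DataFrame(out, columns=["line", "env", "blue", "n_plots"])
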