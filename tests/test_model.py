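import numpy as np
import pandas as pd
import pytest

from gxegblup import (GenomicRelationship, ModelSpec, MultiEnvGBLUP,
                      PhenotypeTable, VarianceComponents, compute_K,
                      compute_blues, genetic_correlations, heritability,
                      reml_loglik)

from conftest import make_small_dataset, random_marker_matrix
from oracles import (balanced_oneway_reml, dense_gls_blup,
                     dense_reml_loglik)


def vc_for(model, G, s2):
    return VarianceComponents(np.asarray(G, dtype=float),
                              np.asarray(s2, dtype=float), model.env_ids)


class TestRestrictedLoglik:
    @pytest.mark.parametrize("t,reps", [(1, 3), (2, 2), (3, 1)])
    def test_matches_dense_evaluation(self, rng, t, reps):
        pheno, K = make_small_dataset(rng, n=10, t=t, reps=reps)
        model = MultiEnvGBLUP(pheno, K)
        G = 0.4 * np.ones((t, t)) + 0.6 * np.eye(t)
        vc = vc_for(model, G, np.linspace(0.5, 1.5, t))
        assert model.loglike(vc) == pytest.approx(
            dense_reml_loglik(model, vc), abs=1e-8)

    def test_pure_function(self, small_model):
        vc = vc_for(small_model, [[1.0, 0.3], [0.3, 1.0]], [0.5, 0.8])
        assert small_model.loglike(vc) == small_model.loglike(vc)

    def test_functional_wrapper(self, small_dataset):
        pheno, K = small_dataset
        model = MultiEnvGBLUP(pheno, K)
        vc = vc_for(model, [[1.0, 0.3], [0.3, 1.0]], [0.5, 0.8])
        assert reml_loglik(vc, pheno, K) == model.loglike(vc)

    def test_scaling_transformation_identity(self, rng):
        """Scaling (G, sigma2) by c and y by sqrt(c) shifts logREML by the
        closed-form Jacobian term -(N - p)/2 * log(c)."""
        pheno, K = make_small_dataset(rng, n=9, t=2, reps=2)
        model = MultiEnvGBLUP(pheno, K)
        vc = vc_for(model, [[0.8, 0.2], [0.2, 1.1]], [0.6, 0.9])
        c = 2.7
        df2 = pheno.df.copy()
        df2["value"] *= np.sqrt(c)
        model2 = MultiEnvGBLUP(PhenotypeTable(df2), K)
        vc2 = vc_for(model2, c * vc.G, c * vc.sigma2)
        expected = model.loglike(vc) - 0.5 * (model.N - model.p) * np.log(c)
        assert model2.loglike(vc2) == pytest.approx(expected, abs=1e-8)

    def test_wrong_environments_rejected(self, small_model):
        vc = VarianceComponents(np.eye(2), np.ones(2), ("X", "Y"))
        with pytest.raises(ValueError, match="environments"):
            small_model.loglike(vc)

    def test_invalid_components_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(np.array([[1.0, 2.0], [2.0, 1.0]]),
                               np.ones(2), ("A", "B"))  # not PSD
        with pytest.raises(ValueError):
            VarianceComponents(np.eye(2), np.array([1.0, -0.5]), ("A", "B"))


class TestBlupOracle:
    def test_fixed_components_match_dense_gls(self, rng):
        """With components held fixed, u_hat and beta must equal the dense
        generalized-least-squares mixed-model solution."""
        pheno, K = make_small_dataset(rng, n=8, t=2, reps=2)
        model = MultiEnvGBLUP(pheno, K)
        vc = vc_for(model, [[1.0, 0.5], [0.5, 0.9]], [0.4, 0.7])
        res = model.fit(start=vc, maxiter=0)
        beta_o, u_o = dense_gls_blup(model, vc)
        np.testing.assert_allclose(res.beta.to_numpy(), beta_o, atol=1e-6)
        u_fast = res.u_hat.to_numpy().T.ravel()  # env-major cell order
        np.testing.assert_allclose(u_fast, u_o, atol=1e-6)

    def test_unphenotyped_lines_predicted_through_K(self, rng):
        pheno, K = make_small_dataset(rng, n=10, t=2, reps=2)
        # drop every record of two lines; they must still get predictions
        dropped = {"l0", "l7"}
        sub = PhenotypeTable(pheno.df[~pheno.df["line"].isin(dropped)])
        res = MultiEnvGBLUP(sub, K).fit(tol=1e-4)
        assert set(res.u_hat.index) == set(K.line_ids)
        assert np.isfinite(res.u_hat.loc[sorted(dropped)].to_numpy()).all()

    def test_unphenotyped_clone_gets_identical_blup(self, rng):
        """A K-identical clone with no records predicts exactly like its
        phenotyped twin."""
        pheno, K = make_small_dataset(rng, n=8, t=2, reps=2)
        Kc = np.zeros((9, 9))
        Kc[:8, :8] = K.K
        Kc[8, :8] = K.K[0, :8]
        Kc[:8, 8] = K.K[0, :8]
        Kc[8, 8] = K.K[0, 0]
        K2 = GenomicRelationship(K.line_ids + ("clone",), Kc)
        res = MultiEnvGBLUP(pheno, K2).fit(tol=1e-4)
        np.testing.assert_allclose(res.u_hat.loc["clone"].to_numpy(),
                                   res.u_hat.loc["l0"].to_numpy(), atol=1e-6)


class TestFit:
    def test_trace_monotone_and_converged(self, rng):
        pheno, K = make_small_dataset(rng, n=12, t=2, reps=2)
        res = MultiEnvGBLUP(pheno, K).fit()
        assert res.converged
        assert (np.diff(res.trace) >= -1e-8).all()
        assert res.llf == pytest.approx(res.trace[-1], abs=1e-6)

    def test_non_convergence_is_flagged_not_raised(self, rng):
        pheno, K = make_small_dataset(rng, n=12, t=2, reps=2)
        res = MultiEnvGBLUP(pheno, K).fit(maxiter=1)
        assert not res.converged
        assert len(res.trace) >= 1

    def test_shift_invariance(self, rng):
        """Adding a constant to one environment's phenotypes moves only that
        environment's fixed effect."""
        pheno, K = make_small_dataset(rng, n=10, t=2, reps=2)
        res1 = MultiEnvGBLUP(pheno, K).fit()
        df2 = pheno.df.copy()
        df2.loc[df2["env"] == "E2", "value"] += 7.5
        res2 = MultiEnvGBLUP(PhenotypeTable(df2), K).fit()
        np.testing.assert_allclose(res2.vc.G, res1.vc.G, atol=1e-6)
        np.testing.assert_allclose(res2.vc.sigma2, res1.vc.sigma2, atol=1e-6)
        np.testing.assert_allclose(res2.u_hat.to_numpy(),
                                   res1.u_hat.to_numpy(), atol=1e-6)
        assert res2.beta["env[E2]"] - res1.beta["env[E2]"] == \
            pytest.approx(7.5, abs=1e-6)
        assert res2.beta["env[E1]"] == pytest.approx(res1.beta["env[E1]"],
                                                     abs=1e-6)

    def test_identity_K_single_env_matches_oneway_reml(self, rng):
        """K = I, one environment, balanced: REML equals the closed-form
        one-way random-effects solution."""
        n, r = 15, 4
        g_true, s_true = 2.0, 1.0
        u = rng.normal(0, np.sqrt(g_true), n)
        y = u[:, None] + rng.normal(0, np.sqrt(s_true), (n, r))
        rows = [(f"l{i}", "E1", f"r{j}", y[i, j])
                for i in range(n) for j in range(r)]
        pheno = PhenotypeTable(pd.DataFrame(
            rows, columns=["line", "env", "rep", "value"]))
        K = GenomicRelationship(tuple(f"l{i}" for i in range(n)), np.eye(n))
        spec = ModelSpec(fixed_terms=("environment",))  # matches the oracle
        res = MultiEnvGBLUP(pheno, K, spec).fit(tol=1e-10)
        g_hat, s_hat = balanced_oneway_reml(y)
        assert res.vc.G[0, 0] == pytest.approx(g_hat, rel=1e-4, abs=1e-6)
        assert res.vc.sigma2[0] == pytest.approx(s_hat, rel=1e-4)

    def test_start_components_respected(self, rng):
        pheno, K = make_small_dataset(rng, n=8, t=2, reps=2)
        model = MultiEnvGBLUP(pheno, K)
        vc = vc_for(model, [[1.0, 0.2], [0.2, 1.0]], [1.0, 1.0])
        res = model.fit(start=vc, maxiter=0)
        np.testing.assert_allclose(res.vc.G, vc.G, atol=1e-10)
        assert not res.converged

    def test_requires_two_lines_per_environment(self, rng):
        mm = random_marker_matrix(rng, n_lines=4)
        K = compute_K(mm)
        rows = [("l0", "E1", 1.0), ("l1", "E1", 2.0), ("l0", "E2", 1.5)]
        pheno = PhenotypeTable(pd.DataFrame(
            rows, columns=["line", "env", "value"]))
        with pytest.raises(ValueError, match="2 distinct lines"):
            MultiEnvGBLUP(pheno, K)

    def test_phenotyped_line_missing_from_K(self, rng):
        mm = random_marker_matrix(rng, n_lines=4)
        K = compute_K(mm)
        rows = [("l0", "E1", 1.0), ("ghost", "E1", 2.0)]
        pheno = PhenotypeTable(pd.DataFrame(
            rows, columns=["line", "env", "value"]))
        with pytest.raises(ValueError, match="absent from K"):
            MultiEnvGBLUP(pheno, K)

    def test_zero_genetic_correlation_recovered(self):
        """Data simulated with independent environment effects should give
        near-zero estimated cross-environment correlation on average."""
        rhos = []
        for rep in range(10):
            r = np.random.default_rng(900 + rep)
            pheno, K = make_small_dataset(r, n=60, t=2, reps=2, rho=0.0,
                                          n_markers=150, h2=0.5)
            res = MultiEnvGBLUP(pheno, K).fit(tol=1e-5)
            g = res.vc.G
            rhos.append(g[0, 1] / np.sqrt(g[0, 0] * g[1, 1]))
        assert abs(np.mean(rhos)) < 0.15

    def test_summary_renders(self, rng):
        pheno, K = make_small_dataset(rng, n=8, t=2, reps=2)
        res = MultiEnvGBLUP(pheno, K).fit(tol=1e-4)
        text = res.summary()
        assert "logREML" in text and "plot_h2" in text
        d = res.to_dict()
        assert set(d) >= {"G", "sigma2", "plot_h2", "logREML", "converged"}


class TestBlues:
    def test_balanced_oneway_means(self):
        rows = [(l, "E1", f"r{j}", v)
                for l, vals in (("a", [1.0, 2.0, 3.0]), ("b", [4.0, 5.0, 6.0]))
                for j, v in enumerate(vals)]
        pheno = PhenotypeTable(pd.DataFrame(
            rows, columns=["line", "env", "rep", "value"]))
        blues = compute_blues(pheno, ModelSpec(fixed_terms=("environment",)))
        assert blues.set_index("line")["blue"].to_dict() == \
            pytest.approx({"a": 2.0, "b": 5.0})
        assert (blues["n_plots"] == 3).all()

    def test_single_plot_cell_equals_observation(self):
        rows = [("a", "E1", 1.3), ("b", "E1", 2.6), ("a", "E2", -0.4),
                ("b", "E2", 0.9)]
        pheno = PhenotypeTable(pd.DataFrame(
            rows, columns=["line", "env", "value"]))
        blues = compute_blues(pheno)
        got = blues.set_index(["line", "env"])["blue"]
        for l, e, v in rows:
            assert got[(l, e)] == pytest.approx(v)

    def test_rcbd_replicate_effect_does_not_move_differences(self, rng):
        """Injecting an additive replicate effect leaves BLUE differences
        between lines untouched."""
        lines = [f"l{i}" for i in range(6)]
        base = dict(zip(lines, rng.normal(size=6)))
        rep_eff = {"r1": 0.0, "r2": 3.0, "r3": -1.5}
        rows = [(l, "E1", r, base[l] + eff)
                for r, eff in rep_eff.items() for l in lines]
        pheno = PhenotypeTable(pd.DataFrame(
            rows, columns=["line", "env", "rep", "value"]))
        blues = compute_blues(pheno)
        got = blues.set_index("line")["blue"]
        diffs = np.array([got[l] - got["l0"] for l in lines])
        expected = np.array([base[l] - base["l0"] for l in lines])
        np.testing.assert_allclose(diffs, expected, atol=1e-8)

    def test_unobserved_cells_absent(self):
        rows = [("a", "E1", 1.0), ("b", "E1", 2.0), ("a", "E2", 3.0)]
        pheno = PhenotypeTable(pd.DataFrame(
            rows, columns=["line", "env", "value"]))
        blues = compute_blues(pheno)
        assert ("b", "E2") not in set(zip(blues["line"], blues["env"]))


class TestDerivedQuantities:
    def test_heritability(self):
        vc = VarianceComponents(np.diag([1.0, 0.0]),
                                np.array([1.0, 2.0]), ("A", "B"))
        h2 = heritability(vc)
        assert h2["A"] == pytest.approx(0.5)
        assert h2["B"] == pytest.approx(0.0)

    def test_genetic_correlations(self):
        vc = VarianceComponents(np.array([[1.0, 0.8], [0.8, 1.0]]),
                                np.ones(2), ("A", "B"))
        R = genetic_correlations(vc)
        assert R.loc["A", "B"] == pytest.approx(0.8)
        np.testing.assert_allclose(np.diag(R), 1.0)
        diag = VarianceComponents(np.diag([1.0, 2.0]), np.ones(2), ("A", "B"))
        np.testing.assert_allclose(genetic_correlations(diag), np.eye(2))

    def test_zero_variance_correlation_errors(self):
        vc = VarianceComponents(np.diag([1.0, 0.0]), np.ones(2), ("A", "B"))
        with pytest.raises(ValueError, match="undefined"):
            genetic_correlations(vc)
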