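"""REML null model, score tests, factored-out residualization, permutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invgwas.lmm_gwa import (
    _reml_profile,
    factored_out_residuals,
    fit_null_lmm,
    run_gwa,
    score_test,
    score_test_many,
)
from invgwas.relatedness import RelatednessMatrix, build_grm

from conftest import make_karyotypes, make_panel


def identity_grm(n):
    return RelatednessMatrix([f"L{i}" for i in range(n)], np.eye(n), "vanraden_full")


def structured_grm(n, seed=0):
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(n, n // 2))
    K = B @ B.T / (n // 2)
    return RelatednessMatrix([f"L{i}" for i in range(n)], K, "vanraden_full")


class TestFitNullLmm:
    def test_identity_grm_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        n = 80
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        y = X @ [1.0, 0.5] + rng.normal(size=n)
        fit = fit_null_lmm(y, X, identity_grm(n))
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)
        resid = y - X @ beta_ols
        s2 = resid @ resid / (n - 2)
        assert fit.tau_g + fit.tau_e == pytest.approx(s2, rel=1e-4)

    def test_reml_optimum_beats_grid(self):
        rng = np.random.default_rng(1)
        n = 60
        K = structured_grm(n, seed=1)
        X = np.ones((n, 1))
        s, U = K.eig()
        b = U @ (rng.normal(size=n) * np.sqrt(np.maximum(s, 0)))
        y = 1.0 + b + rng.normal(size=n)
        fit = fit_null_lmm(y, X, K)
        UtX, Uty = U.T @ X, U.T @ y
        grid = np.logspace(-4, 4, 50)
        grid_ll = max(_reml_profile(l, np.maximum(s, 0), UtX, Uty)[0] for l in grid)
        assert fit.reml_loglik >= grid_ll - 1e-6

    def test_variance_components_nonnegative_boundary_ok(self):
        rng = np.random.default_rng(2)
        n = 50
        K = structured_grm(n, seed=2)
        y = rng.normal(size=n)  # no genetic signal: boundary likely
        fit = fit_null_lmm(y, np.ones((n, 1)), K)
        assert fit.tau_g >= 0 and fit.tau_e > 0

    def test_singular_design_errors(self):
        n = 20
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="singular"):
            fit_null_lmm(np.zeros(n), X, identity_grm(n))

    def test_variance_ratio_recovery(self):
        # tau_g = tau_e = 1 on a structured K; median estimated ratio close to 1
        n = 200
        K = structured_grm(n, seed=3)
        s, U = K.eig()
        X = np.ones((n, 1))
        ratios = []
        rng = np.random.default_rng(4)
        for _ in range(60):
            b = U @ (rng.normal(size=n) * np.sqrt(np.maximum(s, 0)))
            y = b + rng.normal(size=n)
            fit = fit_null_lmm(y, X, K)
            ratios.append(fit.lambda_)
        assert abs(np.median(ratios) - 1.0) < 0.2


class TestScoreTest:
    def test_constant_variant_skipped(self):
        n = 30
        fit = fit_null_lmm(np.random.default_rng(0).normal(size=n), np.ones((n, 1)), identity_grm(n))
        assert score_test(fit, np.full(n, 2.0)) is None

    def test_equals_classical_ols_score_at_identity_K(self):
        # with K = I the projection is the centering projection / sigma^2
        rng = np.random.default_rng(5)
        n = 100
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        fit = fit_null_lmm(y, X, identity_grm(n))
        g = rng.choice([0.0, 2.0], n)
        res = score_test(fit, g)
        M = np.eye(n) - np.ones((n, n)) / n
        sigma2 = fit.tau_g + fit.tau_e
        T_expected = (g @ M @ y) ** 2 / (sigma2 * (g @ M @ g))
        assert res.T == pytest.approx(T_expected, rel=1e-8)

    def test_p_correlates_with_ols_lrt_under_null(self):
        rng = np.random.default_rng(6)
        n, m = 200, 300
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        fit = fit_null_lmm(y, X, identity_grm(n))
        G = rng.choice([0.0, 2.0], size=(n, m), p=[0.7, 0.3])
        T, p, _, _ = score_test_many(fit, G)
        lrt_p = []
        for j in range(m):
            g = G[:, j]
            r = np.corrcoef(g, y)[0, 1]
            lrt = -n * np.log(1 - r**2)
            lrt_p.append(stats.chi2.sf(lrt, 1))
        ok = ~np.isnan(p)
        assert np.corrcoef(np.log(p[ok]), np.log(np.array(lrt_p)[ok]))[0, 1] > 0.999

    def test_affine_invariance_of_T(self):
        rng = np.random.default_rng(7)
        n = 60
        K = structured_grm(n, seed=7)
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        g = rng.choice([0.0, 2.0], n)
        T1 = score_test(fit_null_lmm(y, X, K), g).T
        T2 = score_test(fit_null_lmm(3.5 * y - 2.0, X, K), g).T
        assert T1 == pytest.approx(T2, rel=1e-6)

    def test_power_under_causal_variant(self):
        rng = np.random.default_rng(8)
        n = 200
        X = np.ones((n, 1))
        Ts = []
        for _ in range(30):
            g = rng.choice([0.0, 2.0], n)
            beta = np.sqrt(0.1 / (1 - 0.1) / g.var())
            y = beta * g + rng.normal(size=n)
            fit = fit_null_lmm(y, X, identity_grm(n))
            Ts.append(score_test(fit, g).T)
        assert np.median(Ts) > stats.chi2.ppf(0.95, 1) * 2


class TestFactoredOut:
    def test_exact_inversion_trait_residuals_zero(self):
        kary = make_karyotypes(["INV"] * 5 + ["STD"] * 5)
        y = pd.Series([2.0] * 5 + [0.0] * 5, index=kary.line_ids, name="t")
        resid = factored_out_residuals(y, kary, ("In(2L)t",))
        np.testing.assert_allclose(resid.to_numpy(), 0.0, atol=1e-10)

    def test_orthogonal_trait_just_demeaned(self):
        kary = make_karyotypes(["INV", "STD"] * 6)
        vals = np.tile([1.0, 1.0, -1.0, -1.0], 3)
        y = pd.Series(vals, index=kary.line_ids, name="t")
        resid = factored_out_residuals(y, kary, ("In(2L)t",))
        np.testing.assert_allclose(resid.to_numpy(), vals - vals.mean(), atol=1e-10)

    def test_missing_calls_dropped(self):
        kary = make_karyotypes(["INV", "STD", np.nan, "STD", "INV", "STD"])
        y = pd.Series(np.arange(6.0), index=kary.line_ids, name="t")
        resid = factored_out_residuals(y, kary, ("In(2L)t",))
        assert len(resid) == 5 and "L2" not in resid.index

    def test_absent_inversion_errors(self):
        kary = make_karyotypes(["INV", "STD"])
        y = pd.Series([0.0, 1.0], index=kary.line_ids)
        with pytest.raises(ValueError, match="lacks"):
            factored_out_residuals(y, kary, ("In(3R)Mo",))


class TestRunGwa:
    @pytest.fixture(scope="class")
    def scenario(self, sim_small):
        panel = sim_small["panel"]
        grms = {
            "full": build_grm(panel, "full"),
            "ld": build_grm(panel, "ld"),
            "loco": {a: build_grm(panel, "loco", excluded_arm=a) for a in ("2L", "3R")},
        }
        return {**sim_small, "grms": grms}

    def test_no_permutations_requested(self, scenario):
        run = run_gwa(
            scenario["traits"].values["trait_000"], scenario["panel"], scenario["karyotypes"],
            scenario["covariates"], "full", scenario["grms"], n_perm=0, seed=0,
        )
        assert run.perm_p is None
        assert {"id", "arm", "pos", "maf", "T", "p"} <= set(run.results.columns)
        assert (run.results["maf"] >= 0.05).all()

    def test_permutations_bit_reproducible(self, scenario):
        args = (
            scenario["traits"].values["trait_001"], scenario["panel"], scenario["karyotypes"],
            scenario["covariates"], "ld", scenario["grms"],
        )
        r1 = run_gwa(*args, n_perm=4, seed=11)
        r2 = run_gwa(*args, n_perm=4, seed=11)
        np.testing.assert_array_equal(r1.perm_p, r2.perm_p)
        np.testing.assert_array_equal(r1.results["p"].to_numpy(), r2.results["p"].to_numpy())

    def test_loco_scores_each_arm_with_its_subgrm(self, scenario):
        run = run_gwa(
            scenario["traits"].values["trait_000"], scenario["panel"], scenario["karyotypes"],
            scenario["covariates"], "loco", scenario["grms"], n_perm=0, seed=0,
        )
        assert set(run.null_fits) == {"2L", "3R"}
        assert run.results["p"].notna().mean() > 0.9

    def test_factored_out_removes_inside_signal(self, scenario):
        from invgwas.synthetic_data import TraitSimConfig, simulate_traits

        inv = scenario["inversions"][0]
        strong = simulate_traits(
            scenario["panel"], scenario["karyotypes"], scenario["covariates"],
            TraitSimConfig(n_traits=1, r2_inv=0.3, inv_loading=(1.0,), seed=5),
            inversion_defs=scenario["inversions"],
        )
        tv = strong.values["trait_000"]  # loads on the inversion
        inside = (
            (scenario["panel"].variants["arm"] == inv.arm)
            & scenario["panel"].variants["pos"].between(inv.start, inv.end)
        )
        loco = run_gwa(tv, scenario["panel"], scenario["karyotypes"], scenario["covariates"],
                       "loco", scenario["grms"], n_perm=0, seed=0,
                       )
        fo = run_gwa(tv, scenario["panel"], scenario["karyotypes"], scenario["covariates"],
                     "factored_out", scenario["grms"], n_perm=0, seed=0,
                     factored_inversions=("In(2L)t",))
        ids_inside = set(scenario["panel"].variants.loc[inside, "id"])
        T_loco = loco.results.set_index("id")["T"].reindex(ids_inside).dropna()
        T_fo = fo.results.set_index("id")["T"].reindex(ids_inside).dropna()
        assert T_loco.mean() > 5 * max(T_fo.mean(), 1.0)

    def test_missing_grm_errors(self, scenario):
        with pytest.raises(ValueError, match="missing GRM"):
            run_gwa(
                scenario["traits"].values["trait_000"], scenario["panel"],
                scenario["karyotypes"], scenario["covariates"], "loco",
                {"full": scenario["grms"]["full"]}, n_perm=0, seed=0,
            )
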