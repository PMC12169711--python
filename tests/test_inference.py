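"""Imputation, Rubin pooling, IPW, effective tests, VIF, association grid."""

import numpy as np
import pandas as pd
import pytest

import airdfc as a
from airdfc.inference import vif_check
from airdfc.lmm import FitResult


def _table_with_missing(n, rate, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = 0.8 * x + 0.6 * rng.standard_normal(n)
    tab = pd.DataFrame({"x": x, "z": z})
    tab.loc[rng.random(n) < rate, "z"] = np.nan
    return tab


class TestImputeSimple:
    def test_no_missing_returns_identical_copies(self):
        tab = _table_with_missing(50, 0.0, 0)
        out = a.impute_simple(tab, m=3, seed=1)
        assert len(out) == 3
        for t in out:
            pd.testing.assert_frame_equal(t, tab)

    def test_completions_are_distinct_and_deterministic(self):
        tab = _table_with_missing(200, 0.2, 2)
        out1 = a.impute_simple(tab, m=4, seed=3)
        out2 = a.impute_simple(tab, m=4, seed=3)
        assert not out1[0]["z"].equals(out1[1]["z"])
        for t1, t2 in zip(out1, out2):
            pd.testing.assert_frame_equal(t1, t2)
        assert all(not t["z"].isna().any() for t in out1)

    def test_over_35_percent_missing_rejected(self):
        tab = _table_with_missing(200, 0.4, 4)
        with pytest.raises(ValueError, match="missing"):
            a.impute_simple(tab, m=2, seed=0)

    def test_binary_column_imputed_as_binary(self):
        rng = np.random.default_rng(5)
        tab = pd.DataFrame({"x": rng.standard_normal(300)})
        tab["flag"] = (tab["x"] + rng.standard_normal(300) > 0).astype(float)
        tab.loc[rng.random(300) < 0.2, "flag"] = np.nan
        out = a.impute_simple(tab, m=2, seed=6)
        assert set(out[0]["flag"].unique()) <= {0.0, 1.0}

    def test_mcar_pooled_estimate_unbiased(self):
        """MCAR missingness on a confounder: pooled downstream slope stays
        centered on the planted effect across Monte-Carlo replicates."""
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(60):
            n = 400
            z = rng.standard_normal(n)
            x = 0.7 * z + rng.standard_normal(n)
            y = 0.5 * x + 0.8 * z + rng.standard_normal(n)
            pid = np.arange(n) // 2
            tab = pd.DataFrame({"participant": pid, "x": x, "y": y, "z": z})
            tab.loc[rng.random(n) < 0.25, "z"] = np.nan
            fits = [
                a.fit_lmm(t, "y", "x", ("z",))
                for t in a.impute_simple(tab, m=5, seed=int(rng.integers(2**31)))
            ]
            errs.append(a.pool_rubin(fits, "x").beta - 0.5)
        assert abs(np.mean(errs)) < 3 * np.std(errs) / np.sqrt(len(errs)) + 0.02


class TestPoolRubin:
    def test_hand_example(self):
        """M=2, betas (1,3), SEs (1,1): pooled 2, W=1, B=2, T=4, SE=2."""
        res = a.pool_scalar(np.array([1.0, 3.0]), np.array([1.0, 1.0]))
        assert res.beta == 2.0
        assert res.within == 1.0
        assert res.between == 2.0
        assert res.total == 4.0
        assert res.se == 2.0

    def test_identical_fits_collapse_to_single_fit(self):
        res = a.pool_scalar(np.array([1.5, 1.5, 1.5]), np.array([0.3, 0.3, 0.3]))
        assert res.between == 0.0
        assert res.total == pytest.approx(res.within)
        assert res.se == pytest.approx(0.3)

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            a.pool_scalar(np.array([1.0]), np.array([1.0]))

    def test_total_variance_at_least_within(self, rng):
        betas = rng.normal(0, 1, 10)
        ses = np.abs(rng.normal(1, 0.1, 10))
        res = a.pool_scalar(betas, ses)
        assert res.total >= res.within

    def test_heterogeneous_specs_rejected(self):
        f1 = FitResult(("intercept", "x"), np.zeros(2), np.ones(2), 1.0, 0.0, 10, 5, True)
        f2 = FitResult(("intercept", "y"), np.zeros(2), np.ones(2), 1.0, 0.0, 10, 5, True)
        with pytest.raises(ValueError, match="heterogeneous"):
            a.pool_rubin([f1, f2], "x")


class TestIPW:
    def test_no_selection_weights_near_one(self):
        rng = np.random.default_rng(8)
        cov = pd.DataFrame({"a": rng.standard_normal(5000), "b": rng.standard_normal(5000)})
        included = rng.random(5000) < 0.7
        w = a.ipw_weights(cov, included)
        assert w[included].std() < 0.05
        assert w[included].mean() == pytest.approx(1.0, abs=0.05)

    def test_weighting_restores_covariate_balance(self):
        """Selection on one covariate (unweighted standardized mean
        difference ~0.4): weighted difference shrinks below 0.1."""
        rng = np.random.default_rng(9)
        n = 8000
        x = rng.standard_normal(n)
        cov = pd.DataFrame({"x": x})
        included = rng.random(n) < 1 / (1 + np.exp(-(0.5 + 0.7 * x)))
        smd_raw = (x[included].mean() - x.mean()) / x.std()
        assert smd_raw > 0.1
        w = a.ipw_weights(cov, included)
        smd_w = (np.average(x[included], weights=w[included]) - x.mean()) / x.std()
        assert abs(smd_w) < 0.1

    def test_constant_inclusion_rejected(self):
        cov = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            a.ipw_weights(cov, np.ones(10, dtype=bool))

    def test_separation_capped_not_fatal(self):
        x = np.linspace(-2, 2, 200)
        cov = pd.DataFrame({"x": x})
        included = x > 0  # perfect separation
        w = a.ipw_weights(cov, included)
        assert np.isfinite(w).all()


class TestEffectiveTests:
    def test_independent_outcomes_give_full_count(self):
        outcomes = np.random.default_rng(0).standard_normal((3000, 5))
        res = a.effective_tests(outcomes)
        assert res.m_eff == pytest.approx(5.0, abs=0.1)
        assert round(res.alpha, 2) == 0.01

    def test_rank_one_outcomes_give_one(self):
        base = np.random.default_rng(1).standard_normal(100)
        mat = np.column_stack([base, 2 * base + 1, -base])
        res = a.effective_tests(mat)
        assert res.m_eff == pytest.approx(1.0, abs=1e-8)
        assert res.alpha == pytest.approx(0.05)

    def test_two_outcomes_hand_eigenvalues(self):
        """r = 0.6: eigenvalues 1.6/0.4, m_eff = (sqrt(1.6)+sqrt(0.4))^2/2 = 1.8."""
        rng = np.random.default_rng(2)
        z = rng.standard_normal((200_00, 2))
        x = np.column_stack([z[:, 0], 0.6 * z[:, 0] + np.sqrt(1 - 0.36) * z[:, 1]])
        res = a.effective_tests(x)
        r = np.corrcoef(x.T)[0, 1]
        expected = (np.sqrt(1 + r) + np.sqrt(1 - r)) ** 2 / 2
        assert res.m_eff == pytest.approx(expected, abs=1e-9)
        assert res.m_eff == pytest.approx(1.8, abs=0.02)

    def test_meff_monotone_in_exchangeable_correlation(self):
        """m_eff decreases as the common pairwise correlation rises 0 -> 1."""
        k = 5
        vals = []
        for rho in np.linspace(0.0, 0.99, 12):
            corr = np.full((k, k), rho)
            np.fill_diagonal(corr, 1.0)
            lam = np.clip(np.linalg.eigvalsh(corr), 0, None)
            vals.append(np.sqrt(lam).sum() ** 2 / lam.sum())
        assert all(b <= a_ + 1e-9 for a_, b in zip(vals, vals[1:]))

    def test_constant_column_rejected(self):
        mat = np.column_stack([np.arange(20.0), np.full(20, 3.0)])
        with pytest.raises(ValueError, match="constant"):
            a.effective_tests(mat)


class TestVIF:
    def test_orthogonal_covariates(self, rng):
        n = 200
        x = rng.standard_normal((n, 3))
        x -= x.mean(axis=0)
        q, _ = np.linalg.qr(x)
        out = vif_check(pd.DataFrame(q, columns=list("abc")))
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-6)
        assert out["pass"].all()

    def test_duplicated_covariate_infinite(self, rng):
        x = rng.standard_normal(100)
        out = vif_check(pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)}))
        assert np.isinf(out.loc[out["covariate"] == "a", "vif"]).all()
        assert not out["pass"].all()

    def test_constructed_r2_gives_vif_ten(self, rng):
        """x2 = x1 + noise with R^2 = 0.9 -> VIF = 10, failing the strict
        < 10 rule."""
        n = 200_000
        x1 = rng.standard_normal(n)
        x2 = 3.0 * x1 + np.sqrt(9.0 / 0.9 - 9.0) * rng.standard_normal(n)
        out = vif_check(pd.DataFrame({"x1": x1, "x2": x2}))
        assert out["vif"].iloc[1] == pytest.approx(10.0, rel=0.02)
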