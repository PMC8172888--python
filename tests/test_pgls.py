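"""PGLS estimation: fixed-covariance GLS, lambda profiling, signal, slopes."""

import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phyloacoustics as pa
from phyloacoustics.pgls import PGLSError
from phyloacoustics.trees import lambda_transform

from conftest import random_pd_covariance, whitening_ols_oracle


def random_instance(n, rng, p=None):
    p = p or int(rng.integers(1, 4))
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))]) \
        if p > 1 else np.ones((n, 1))
    y = rng.standard_normal(n) * 2 + X @ rng.standard_normal(p)
    C = random_pd_covariance(n, rng)
    return y, X, C


class TestGlsFit:
    def test_star_tree_intercept_reduces_to_mean(self):
        """With C = I and an intercept, GLS is the sample mean; sigma2 = SSE/n."""
        y = np.array([1.0, 2.0, 3.0])
        res = pa.gls_fit(y, np.ones((3, 1)), np.eye(3))
        assert res.beta[0] == pytest.approx(2.0)
        assert res.sigma2_ml == pytest.approx(2.0 / 3.0)
        expected_ll = -0.5 * (3 * np.log(2 * np.pi * 2 / 3) + 0 + 3)
        assert res.loglik == pytest.approx(expected_ll)
        assert res.loglik == pytest.approx(-3.6486, abs=1e-4)

    def test_matches_whitening_oracle(self, rng):
        """50 random instances (<= 10 taxa) against whitened OLS, to 1e-8."""
        for _ in range(50):
            n = int(rng.integers(5, 11))
            y, X, C = random_instance(n, rng)
            res = pa.gls_fit(y, X, C)
            beta, se, s2, ll = whitening_ols_oracle(y, X, C)
            np.testing.assert_allclose(res.beta, beta, atol=1e-8)
            np.testing.assert_allclose(res.se, se, atol=1e-8)
            assert res.sigma2_ml == pytest.approx(s2, abs=1e-8)
            assert res.loglik == pytest.approx(ll, abs=1e-8)

    def test_identity_covariance_equals_ols(self, rng):
        """With C = I, PGLS estimates equal ordinary least squares exactly."""
        import statsmodels.api as sm

        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ [1.0, -0.5, 0.2] + rng.standard_normal(n)
        res = pa.gls_fit(y, X, np.eye(n))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.beta, ols.params, atol=1e-10)
        np.testing.assert_allclose(res.se, ols.bse, atol=1e-10)

    def test_residual_orthogonality(self, rng):
        """Normal equations: X' C^-1 e = 0 at the GLS solution."""
        y, X, C = random_instance(8, rng, p=3)
        res = pa.gls_fit(y, X, C)
        np.testing.assert_allclose(
            X.T @ np.linalg.solve(C, res.residuals), 0.0, atol=1e-8
        )

    def test_rank_deficient_design_rejected(self, rng):
        X = np.ones((6, 2))  # duplicated column
        with pytest.raises(PGLSError, match="rank"):
            pa.gls_fit(rng.standard_normal(6), X, np.eye(6))

    def test_singular_covariance_rejected(self, rng):
        C = np.ones((5, 5))
        with pytest.raises(PGLSError, match="positive definite"):
            pa.gls_fit(rng.standard_normal(5), np.ones((5, 1)), C)


def grid_search_oracle(y, X, C, step=1e-4):
    """Fine lambda grid over [0, 1]: independent of the profiling code path."""
    best = (None, -np.inf)
    for lam in np.arange(0.0, 1.0 + step / 2, step):
        ll = pa.gls_fit(y, X, lambda_transform(C, lam)).loglik
        if ll > best[1]:
            best = (lam, ll)
    return best


class TestFitLambda:
    def test_matches_fine_grid_search(self):
        """20 random instances: lambda within 1e-3, loglik within 1e-6."""
        rng = np.random.default_rng(7)
        for i in range(20):
            tree = pa.simulate_yule_tree(25, seed=300 + i)
            C = tree.vcv()
            lam_true = rng.uniform(0.1, 0.95)
            y = np.asarray(
                pa.simulate_trait(C, lam_true, 1.0, 0.0, seed=400 + i)
            )
            X = np.column_stack([np.ones(25), rng.standard_normal(25)])
            fit = pa.fit_lambda(y, X, C)
            lam_g, ll_g = grid_search_oracle(y, X, C)
            assert abs(fit.lam - lam_g) < 1e-3
            assert abs(fit.loglik - ll_g) < 1e-6

    def test_spectral_profile_equals_direct_gls(self):
        """The one-eigendecomposition profile shortcut matches a fresh GLS
        factorization at fixed lambdas, including on non-ultrametric trees."""
        from phyloacoustics.pgls import _profile_funcs

        tree = pa.simulate_yule_tree(30, seed=77)
        tree = pa.jitter_tree_sample(tree, 1, cv=0.4, seed=79)[0]
        C = tree.vcv()
        y = np.asarray(pa.simulate_trait(C, 0.6, 1.0, 0.0, seed=78))
        X = np.ones((30, 1))
        profile = _profile_funcs(y, X, C)
        for lam in (0.0, 0.2, 0.5, 0.8, 1.0):
            direct = pa.gls_fit(y, X, lambda_transform(C, lam)).loglik
            assert profile(lam) == pytest.approx(direct, abs=1e-8)

    def test_brownian_data_recovers_high_lambda(self):
        """Traits evolved with lambda = 1 on a 200-tip tree give lambda > 0.9
        on average (10 replicates; the full 100-replicate check is part of
        the acceptance battery)."""
        tree = pa.simulate_yule_tree(200, seed=21)
        C = tree.vcv()
        lams = []
        for r in range(10):
            y = pa.simulate_trait(C, 1.0, 1.0, 0.0, seed=500 + r)
            lams.append(pa.phylogenetic_signal(np.asarray(y), C).lam)
        assert np.mean(lams) > 0.9

    def test_iid_noise_has_no_signal(self):
        tree = pa.simulate_yule_tree(200, seed=22)
        rng = np.random.default_rng(23)
        lams = [
            pa.phylogenetic_signal(rng.standard_normal(200), tree.vcv()).lam
            for _ in range(10)
        ]
        assert np.mean(lams) < 0.1

    def test_star_tree_profile_is_flat(self):
        """Lambda has no effect on a star phylogeny; tie-break returns 0."""
        star = pa.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        y = np.array([0.3, -1.2, 0.5, 2.0, -0.4])
        fit = pa.fit_lambda(y, None, star.vcv())
        assert fit.lam == 0.0
        assert "profile-flat" in fit.flags

    def test_aic_counts_sigma2_and_lambda(self):
        tree = pa.simulate_yule_tree(30, seed=31)
        y = np.asarray(pa.simulate_trait(tree, 0.8, 1.0, 0.0, seed=32))
        fit = pa.fit_lambda(y, None, tree.vcv())
        assert fit.aic == pytest.approx(2 * (1 + 2) - 2 * fit.loglik)

    def test_too_few_species_rejected(self):
        cherry = pa.parse_newick("(A:1,B:1);")
        with pytest.raises(PGLSError, match="at least"):
            pa.fit_lambda(np.array([1.0, 2.0]), None, cherry.vcv())


class TestPhylogeneticSignal:
    def test_moderate_lambda_recovery(self):
        """Mean lambda over 20 replicates at lambda_true 0.6 lands within 0.1
        (300 tips; a slimmed version of the 100-replicate design)."""
        tree = pa.simulate_yule_tree(300, seed=41)
        C = tree.vcv()
        lams = [
            pa.phylogenetic_signal(
                np.asarray(pa.simulate_trait(C, 0.6, 1.0, 0.0, seed=600 + r)), C
            ).lam
            for r in range(20)
        ]
        assert abs(np.mean(lams) - 0.6) < 0.1

    def test_constant_trait_rejected(self, three_taxon_tree):
        star = pa.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        with pytest.raises(PGLSError, match="constant"):
            pa.phylogenetic_signal(np.ones(5), star.vcv())

    def test_series_input_aligns_by_species(self):
        import pandas as pd

        tree = pa.simulate_yule_tree(20, seed=51)
        trait = pa.simulate_trait(tree, 0.7, 1.0, 0.0, seed=52)
        shuffled = trait.sample(frac=1.0, random_state=0)
        a = pa.phylogenetic_signal(trait, tree)
        b = pa.phylogenetic_signal(shuffled, tree)
        assert a.lam == pytest.approx(b.lam, abs=1e-12)


class TestStandardizeCoefficient:
    def test_arithmetic(self):
        assert pa.standardize_coefficient(-2.0, 1.0, 4.0) == pytest.approx(-0.5)
        assert pa.standardize_coefficient(0.0, 3.0, 4.0) == 0.0

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_predictor_units(self, scale):
        """Rescaling x multiplies beta by 1/s and sd_x by s: beta_st fixed."""
        beta, sd_x, sd_y = -2.0, 1.5, 4.0
        base = pa.standardize_coefficient(beta, sd_x, sd_y)
        rescaled = pa.standardize_coefficient(beta / scale, sd_x * scale, sd_y)
        assert rescaled == pytest.approx(base, rel=1e-9)

    def test_zero_response_sd_rejected(self):
        with pytest.raises(PGLSError):
            pa.standardize_coefficient(1.0, 1.0, 0.0)


class TestAgainstRReference:
    """Independent cross-validation against the R comparative-methods stack."""

    def test_lambda_signal_and_gls_match_r(self, tmp_path):
        """phytools::phylosig (lambda) and nlme::gls + ape::corPagel agree
        with fit_lambda on a seeded 40-tip dataset."""
        tree = pa.simulate_yule_tree(40, seed=11)
        trait = pa.simulate_trait(tree, 0.7, 1.0, 0.0, seed=12)
        x2 = pa.simulate_trait(tree, 0.9, 1.0, 0.0, seed=13)
        noise = pa.simulate_trait(tree, 0.5, 0.25, 0.0, seed=14)
        y = 1.0 + 0.5 * np.asarray(x2) + np.asarray(noise)

        (tmp_path / "t.nwk").write_text(tree.to_newick() + "\n")
        trait.to_csv(tmp_path / "x.csv", header=["value"], index_label="species")
        import pandas as pd

        pd.DataFrame(
            {"species": tree.taxa, "x": np.asarray(x2.loc[list(tree.taxa)]),
             "y": y}
        ).to_csv(tmp_path / "xy.csv", index=False)

        sig = pa.phylogenetic_signal(trait, tree)
        X = np.column_stack([np.ones(40), np.asarray(x2.loc[list(tree.taxa)])])
        reg = pa.fit_lambda(y, X, tree.vcv(), terms=("intercept", "x"))

        script = textwrap.dedent("""
            suppressMessages({library(ape); library(phytools); library(nlme)})
            tree <- read.tree("t.nwk")
            x <- read.csv("x.csv"); v <- setNames(x$value, x$species)
            ps <- phylosig(tree, v, method="lambda")
            d <- read.csv("xy.csv"); rownames(d) <- d$species
            fit <- gls(y ~ x, data=d,
                       correlation=corPagel(0.5, phy=tree, form=~species),
                       method="ML")
            tt <- summary(fit)$tTable
            cat(ps$lambda, ps$logL, fit$modelStruct$corStruct[1],
                coef(fit), tt[, "Std.Error"], logLik(fit), sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], cwd=tmp_path, capture_output=True,
            text=True, check=True,
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        r_sig_lam, r_sig_ll, r_lam, r_b0, r_b1, r_se0, r_se1, r_ll = vals
        assert sig.lam == pytest.approx(r_sig_lam, abs=1e-4)
        assert sig.loglik == pytest.approx(r_sig_ll, abs=1e-4)
        assert reg.lam == pytest.approx(r_lam, abs=1e-4)
        np.testing.assert_allclose(reg.beta, [r_b0, r_b1], atol=1e-5)
        np.testing.assert_allclose(reg.se, [r_se0, r_se1], atol=1e-5)
        assert reg.loglik == pytest.approx(r_ll, abs=1e-4)
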