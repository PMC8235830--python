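import shutil
import subprocess

import numpy as np
import pytest

from itscompare import (SeriesParams, build_design, fit_ols, fit_reml,
                        reml_profile_loglik, satterthwaite_df, simulate_series)

from . import _oracles
from .conftest import random_instance


class TestProfileLoglik:
    def test_matches_dense_oracle_on_small_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(8):
            ds, d = random_instance(rng)
            for rho in (-0.6, 0.0, 0.3, 0.85):
                ours = reml_profile_loglik(rho, d, ds.y)
                oracle = _oracles.dense_reml_loglik(rho, d.X, ds.y)
                assert ours == pytest.approx(oracle, abs=1e-10)

    def test_rho_zero_is_iid_restricted_loglik(self, noisy_dataset, noisy_design):
        ours = reml_profile_loglik(0.0, noisy_design, noisy_dataset.y)
        oracle = _oracles.iid_restricted_loglik(noisy_design.X, noisy_dataset.y)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_translation_changes_only_variance_term(self, noisy_dataset, noisy_design):
        # adding a constant shifts y within the column space of the design:
        # the two log-determinant terms are unchanged, only sigma2_hat moves
        y = noisy_dataset.y
        rho = 0.35
        n, p = noisy_design.X.shape
        base = reml_profile_loglik(rho, noisy_design, y)
        shifted = reml_profile_loglik(rho, noisy_design, y + 100.0)
        # intercept absorbs the shift entirely: identical value
        assert shifted == pytest.approx(base, abs=1e-8)

    def test_domain_error_outside_open_interval(self, noisy_dataset, noisy_design):
        with pytest.raises(ValueError):
            reml_profile_loglik(1.0, noisy_design, noisy_dataset.y)


class TestREMLFit:
    def test_rho_matches_dense_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            ds, d = random_instance(rng, n_min=10, n_max=12)
            fit = fit_reml(d, ds.y)
            oracle_rho = _oracles.dense_reml_rho(d.X, ds.y)
            if abs(oracle_rho) > 0.999:
                # boundary solution: excluded by the validity rule
                assert not fit.valid and abs(fit.rho_hat) > 0.999
            else:
                assert fit.rho_hat == pytest.approx(oracle_rho, abs=1e-6)

    def test_fixed_rho_matches_dense_gls(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            ds, d = random_instance(rng)
            rho = float(rng.uniform(-0.8, 0.8))
            fit = fit_reml(d, ds.y, fixed_rho=rho)
            beta, se, s2 = _oracles.dense_gls(d.X, ds.y, rho)
            np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
            np.testing.assert_allclose(fit.se, se, atol=1e-8)

    def test_rho_zero_equals_ols_beta_se(self, noisy_dataset, noisy_design):
        reml = fit_reml(noisy_design, noisy_dataset.y, fixed_rho=0.0)
        ols = fit_ols(noisy_design, noisy_dataset.y)
        np.testing.assert_allclose(reml.beta, ols.beta, atol=1e-10)
        np.testing.assert_allclose(reml.se, ols.se, atol=1e-10)

    def test_white_noise_recovery(self):
        # true rho = 0 at n = 500: estimates concentrate near zero
        hits = 0
        reps = 100
        for i in range(reps):
            ds = simulate_series(SeriesParams(n_pre=250, n_post=250,
                                              beta=(10, 0.5, 2, 0.1),
                                              rho=0.0, sigma=1.0, seed=3000 + i))
            d = build_design(ds)
            fit = fit_reml(d, ds.y)
            if abs(fit.rho_hat) <= 0.1:
                hits += 1
        assert hits / reps >= 0.95

    def test_short_series_rho_biased_downwards(self):
        # n = 10, true rho = 0.2: the REML median estimate is negative
        vals = []
        for i in range(300):
            ds = simulate_series(SeriesParams(n_pre=5, n_post=5,
                                              beta=(10, 0.5, 2, 0.1),
                                              rho=0.2, sigma=1.0, seed=4000 + i))
            d = build_design(ds)
            fit = fit_reml(d, ds.y)
            if fit.valid:
                vals.append(fit.rho_hat)
        assert np.median(vals) < 0

    def test_rho_ci_present_and_ordered(self, noisy_dataset, noisy_design):
        fit = fit_reml(noisy_design, noisy_dataset.y)
        lo, hi = fit.rho_ci
        assert -1 <= lo <= fit.rho_hat <= hi <= 1

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_nlme_gls_oracle(self, tmp_path):
        """Cross-validate against gls(corAR1, method='REML') from R nlme."""
        ds = simulate_series(SeriesParams(n_pre=12, n_post=12,
                                          beta=(10, 0.5, 2, 0.1),
                                          rho=0.4, sigma=1.0, seed=11))
        d = build_design(ds)
        fit = fit_reml(d, ds.y)
        ypath = tmp_path / "y.txt"
        np.savetxt(ypath, ds.y)
        script = f"""
        suppressMessages(library(nlme))
        y <- scan("{ypath}", quiet=TRUE)
        n <- length(y); t <- 1:n; ti <- 13
        D <- as.numeric(t >= ti); S <- ifelse(t > ti, t - ti, 0)
        fit <- gls(y ~ t + D + S, correlation=corAR1(form=~t), method="REML")
        cat(coef(fit), sqrt(diag(vcov(fit))),
            coef(fit$modelStruct$corStruct, unconstrained=FALSE), sep="\\n")
        """
        out = subprocess.run(["Rscript", "-"], input=script, text=True,
                             capture_output=True, timeout=120)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_se, r_rho = vals[:4], vals[4:8], vals[8]
        np.testing.assert_allclose(fit.beta, r_beta, rtol=1e-5)
        np.testing.assert_allclose(fit.se, r_se, rtol=1e-4)
        assert fit.rho_hat == pytest.approx(r_rho, abs=1e-5)


class TestSatterthwaite:
    def test_df_equals_n_minus_p_at_fixed_rho_zero(self, noisy_dataset, noisy_design):
        n, p = noisy_design.X.shape
        fit = fit_reml(noisy_design, noisy_dataset.y, satterthwaite=True,
                       fixed_rho=0.0)
        c = np.zeros(p)
        c[noisy_design.roles["level_change"]] = 1.0
        nu = satterthwaite_df(c, fit.internals)
        assert nu == pytest.approx(n - p, abs=1e-6)

    def test_floor_applied(self, noisy_dataset, noisy_design):
        fit = fit_reml(noisy_design, noisy_dataset.y, satterthwaite=True,
                       df_floor=50.0)
        assert np.all(fit.df >= 50.0)

    def test_df_grows_with_series_length(self):
        nus = []
        for n_half in (10, 25, 100):
            ds = simulate_series(SeriesParams(n_pre=n_half, n_post=n_half,
                                              beta=(10, 0.5, 2, 0.1),
                                              rho=0.3, sigma=1.0, seed=77))
            d = build_design(ds)
            fit = fit_reml(d, ds.y, satterthwaite=True)
            nus.append(fit.df[d.roles["level_change"]])
        assert nus[0] < nus[1] < nus[2]

    def test_satt_only_changes_interval_width_not_se(self, noisy_dataset, noisy_design):
        plain = fit_reml(noisy_design, noisy_dataset.y, satterthwaite=False)
        satt = fit_reml(noisy_design, noisy_dataset.y, satterthwaite=True)
        np.testing.assert_allclose(satt.se, plain.se, atol=1e-12)
        widths_satt = satt.ci[:, 1] - satt.ci[:, 0]
        widths_plain = plain.ci[:, 1] - plain.ci[:, 0]
        assert np.all(widths_satt >= widths_plain - 1e-12)
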