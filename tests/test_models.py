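import shutil
import subprocess

import numpy as np
import pytest
from scipy import optimize, special

from gazemind import fit_binomial_glm, fit_binomial_glmm, lrt
from gazemind.models import (
    _agq_loglik,
    _laplace_loglik_grad,
    aggregate_cells,
    fit_glmm_cells,
)


def binom_loglik(beta, succ, trials, X):
    """Direct binomial log-likelihood (with binomial coefficients)."""
    eta = X @ beta
    return float(
        np.sum(
            special.gammaln(trials + 1)
            - special.gammaln(succ + 1)
            - special.gammaln(trials - succ + 1)
            + succ * eta
            - trials * np.logaddexp(0, eta)
        )
    )


def brute_force_glm(succ, trials, X):
    """Independent Nelder-Mead maximization of the binomial loglik."""
    res = optimize.minimize(
        lambda b: -binom_loglik(b, succ, trials, X),
        np.zeros(X.shape[1]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    return res.x, -res.fun


class TestGlm:
    def test_balanced_data_gives_zero_coefficients(self):
        trials = np.full(20, 100)
        succ = trials // 2
        x = np.linspace(0, 1, 20)
        fit = fit_binomial_glm(succ, trials, x)
        assert np.allclose(fit.coefficients, 0, atol=1e-8)

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 0.15, 40)
        p = special.expit(-0.5 + 6 * x)
        succ = rng.binomial(500, p)
        fit = fit_binomial_glm(succ, np.full(40, 500), x)
        assert abs(fit.coefficients[1] - 6) < 3 * fit.bse[1]

    def test_loglik_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        trials = rng.integers(5, 30, 8)
        x = rng.normal(size=8)
        succ = rng.binomial(trials, special.expit(0.3 + 0.5 * x))
        X = np.column_stack([np.ones(8), x])
        fit = fit_binomial_glm(succ, trials, x)
        bcoef, bll = brute_force_glm(succ.astype(float), trials.astype(float), X)
        assert fit.loglik == pytest.approx(bll, abs=1e-6)
        assert np.allclose(fit.coefficients, bcoef, atol=1e-4)

    def test_intercept_score_identity(self):
        """Trial-weighted mean fitted probability equals the raw proportion."""
        rng = np.random.default_rng(2)
        trials = rng.integers(10, 60, 15)
        x = rng.normal(size=15)
        succ = rng.binomial(trials, special.expit(-0.2 + 0.8 * x))
        fit = fit_binomial_glm(succ, trials, x)
        eta = fit.coefficients[0] + fit.coefficients[1] * x
        fitted = special.expit(eta)
        assert np.sum(trials * fitted) == pytest.approx(succ.sum(), rel=1e-8)

    def test_perfect_separation_flagged(self):
        succ = np.array([0, 0, 0, 10, 10, 10])
        trials = np.full(6, 10)
        x = np.array([0, 0, 0, 1, 1, 1.0])
        fit = fit_binomial_glm(succ, trials, x)
        assert not fit.converged


@pytest.fixture(scope="module")
def bernoulli_fixture():
    rng = np.random.default_rng(12)
    G, npg = 10, 40
    group = np.repeat(np.arange(G), npg)
    x = (rng.random(G * npg) < 0.4).astype(float)
    u = rng.normal(0, 0.7, G)
    y = (rng.random(G * npg) < special.expit(-0.4 + 0.9 * x + u[group])).astype(float)
    return y, group, x


class TestGlmm:
    def test_identical_groups_reduce_to_glm(self):
        rng = np.random.default_rng(4)
        group = np.repeat(np.arange(8), 50)
        x = np.tile((np.arange(400) % 2).astype(float), 1)
        y = (rng.random(400) < special.expit(-0.3 + 0.5 * x)).astype(float)
        gfit = fit_binomial_glmm(y, group, x)
        glm = fit_binomial_glm(y, np.ones_like(y), x)
        assert gfit.random_intercept_sd == pytest.approx(0.0, abs=1e-3)
        assert np.allclose(gfit.fixed_effects, glm.coefficients, atol=1e-4)
        assert gfit.loglik == pytest.approx(glm.loglik, abs=1e-4)

    def test_gradient_matches_numerical(self, bernoulli_fixture):
        y, group, x = bernoulli_fixture
        cg, cX, cn, ck, G, _ = aggregate_cells(y, group, x)
        args = (cg, cX, cn, ck, G)
        rng = np.random.default_rng(5)
        for _ in range(5):
            theta = np.array([rng.normal(), rng.normal(), rng.uniform(0.2, 1.5)])
            _, grad = _laplace_loglik_grad(theta, *args)
            num = optimize.approx_fprime(
                theta, lambda t: _laplace_loglik_grad(t, *args)[0], 1e-7
            )
            assert np.allclose(grad, num, atol=1e-3)

    def test_matches_lme4_glmer(self, bernoulli_fixture, tmp_path):
        """Independent cross-check against R lme4 on the same data."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        y, group, x = bernoulli_fixture
        csv = tmp_path / "d.csv"
        np.savetxt(
            csv,
            np.column_stack([y, group, x]),
            delimiter=",",
            header="y,g,x",
            comments="",
        )
        script = (
            f'suppressMessages(library(lme4)); d <- read.csv("{csv}");'
            "m <- glmer(y ~ x + (1|g), data=d, family=binomial);"
            'cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep=",")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        b0, b1, sd, ll = map(float, out.stdout.strip().split(","))
        fit = fit_binomial_glmm(y, group, x)
        assert fit.fixed_effects[0] == pytest.approx(b0, abs=2e-3)
        assert fit.fixed_effects[1] == pytest.approx(b1, abs=2e-3)
        assert fit.random_intercept_sd == pytest.approx(sd, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_agq_close_to_laplace_at_optimum(self, bernoulli_fixture):
        y, group, x = bernoulli_fixture
        lap = fit_binomial_glmm(y, group, x)
        agq = fit_binomial_glmm(y, group, x, method="agq", nodes=15)
        assert np.allclose(lap.fixed_effects, agq.fixed_effects, atol=5e-3)
        assert abs(lap.loglik - agq.loglik) < 0.2

    def test_agq_matches_direct_quadrature_integral(self):
        """AGQ loglik equals per-group numerical integration to high accuracy."""
        from scipy.integrate import quad

        rng = np.random.default_rng(6)
        G = 4
        cg = np.repeat(np.arange(G), 2)
        cX = np.column_stack([np.ones(2 * G), np.tile([0.0, 1.0], G)])
        cn = np.full(2 * G, 25.0)
        ck = rng.binomial(25, 0.4, 2 * G).astype(float)
        theta = np.array([-0.3, 0.5, 0.6])
        ll_agq = -_agq_loglik(theta, cg, cX, cn, ck, G, 41)
        ll_num = 0.0
        for g in range(G):
            sel = cg == g
            n_g, k_g, x_g = cn[sel], ck[sel], cX[sel] @ theta[:2]

            def integrand(u):
                eta = x_g + u
                logf = np.sum(k_g * eta - n_g * np.logaddexp(0, eta))
                return np.exp(logf) * np.exp(-(u**2) / (2 * 0.36)) / np.sqrt(
                    2 * np.pi * 0.36
                )

            val, _ = quad(integrand, -6, 6, limit=200)
            ll_num += np.log(val)
        assert ll_agq == pytest.approx(ll_num, abs=1e-5)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        G, npg = 40, 300
        group = np.repeat(np.arange(G), npg)
        x = (rng.random(G * npg) < 0.5).astype(float)
        ests, sds = [], []
        for _ in range(6):
            u = rng.normal(0, 0.6, G)
            y = (
                rng.random(G * npg) < special.expit(-1.0 + 0.8 * x + u[group])
            ).astype(float)
            fit = fit_binomial_glmm(y, group, x)
            ests.append(fit.fixed_effects[1])
            sds.append(fit.random_intercept_sd)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.8) < max(3 * se, 0.05)
        assert abs(np.mean(sds) - 0.6) < 0.15

    def test_refit_deterministic(self, bernoulli_fixture):
        y, group, x = bernoulli_fixture
        a = fit_binomial_glmm(y, group, x)
        b = fit_binomial_glmm(y, group, x)
        assert a.loglik == b.loglik
        assert (a.fixed_effects == b.fixed_effects).all()


class TestLrt:
    def test_equal_logliks_give_zero_chi2(self, bernoulli_fixture):
        y, group, x = bernoulli_fixture
        fit = fit_binomial_glmm(y, group, x)
        from gazemind.models import GlmmFit

        clone = GlmmFit(
            fixed_effects=fit.fixed_effects[:1],
            random_intercept_sd=fit.random_intercept_sd,
            loglik=fit.loglik,
            converged=True,
            n_obs=fit.n_obs,
            n_groups=fit.n_groups,
            n_params=fit.n_params - 1,
        )
        res = lrt(fit, clone)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_chi2_matches_bruteforce_deviance_difference(self):
        rng = np.random.default_rng(8)
        trials = rng.integers(8, 20, 9)
        x = rng.normal(size=9)
        succ = rng.binomial(trials, special.expit(0.2 + 0.6 * x))
        X1 = np.column_stack([np.ones(9), x])
        X0 = np.ones((9, 1))
        full = fit_binomial_glm(succ, trials, x)
        null = fit_binomial_glm(succ, trials, None)
        res = lrt(full, null)
        _, ll1 = brute_force_glm(succ.astype(float), trials.astype(float), X1)
        _, ll0 = brute_force_glm(succ.astype(float), trials.astype(float), X0)
        assert res.chi2 == pytest.approx(2 * (ll1 - ll0), abs=1e-4)

    def test_unconverged_fit_rejected(self):
        succ = np.array([0, 0, 10, 10])
        trials = np.full(4, 10)
        x = np.array([0, 0, 1, 1.0])
        bad = fit_binomial_glm(succ, trials, x)
        good = fit_binomial_glm(succ, trials, None)
        with pytest.raises(ValueError):
            lrt(bad, good)
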