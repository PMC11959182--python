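import numpy as np
import pytest
from scipy import stats

from adapt_daa.tobit import (
    CensoredResponse,
    TobitConfig,
    expected_information,
    firth_penalty,
    fit_all_taxa,
    fit_tobit,
    tobit_loglik,
)
from adapt_daa.data_io import CovariateDesign


def _uncensored(y):
    return CensoredResponse(y, np.ones(len(y), dtype=int))


def _naive_loglik(beta, sigma, values, indicators):
    """Term-by-term oracle: unvectorized sum of the censored-Gaussian terms."""
    total = 0.0
    for v, d, x in zip(values, indicators, _naive_loglik.X):
        r = (v - float(np.dot(x, beta))) / sigma
        if d == 1:
            total += stats.norm.logpdf(r) - np.log(sigma)
        else:
            total += stats.norm.logcdf(r)
    return total


class TestLoglik:
    def test_uncensored_equals_gaussian_mle_loglik(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + rng.normal(size=n)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma = float(np.sqrt(np.mean((y - X @ beta) ** 2)))
        ll = tobit_loglik(beta, sigma, _uncensored(y), X)
        closed = -0.5 * n * np.log(2 * np.pi) - n * np.log(sigma) - 0.5 * n
        assert ll == pytest.approx(closed, abs=1e-10)

    def test_single_censored_observation_closed_form(self):
        resp = CensoredResponse([0.0], [0])
        ll = tobit_loglik(np.array([0.0]), 1.0, resp, np.array([[1.0]]))
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        n = 15
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [0.3, -0.7] + rng.normal(size=n)
        delta = (rng.random(n) > 0.4).astype(int)
        v = np.where(delta == 1, y, y - 0.5)
        resp = CensoredResponse(v, delta)
        _naive_loglik.X = X
        beta = np.array([0.1, 0.2])
        assert tobit_loglik(beta, 0.8, resp, X) == pytest.approx(
            _naive_loglik(beta, 0.8, v, delta), abs=1e-10
        )

    def test_nonpositive_sigma_rejected(self):
        resp = _uncensored(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            tobit_loglik(np.array([0.0]), -1.0, resp, np.ones((2, 1)))

    def test_deep_tail_censoring_stays_finite(self):
        """log Phi far in the tail must not underflow to -inf prematurely."""
        resp = CensoredResponse([-50.0], [0])
        ll = tobit_loglik(np.array([0.0]), 1.0, resp, np.array([[1.0]]))
        assert np.isfinite(ll)
        assert ll == pytest.approx(stats.norm.logcdf(-50.0), rel=1e-10)


class TestFirthPenalty:
    def test_gaussian_reduction_closed_form(self, rng):
        n, k = 30, 2
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        sigma = 1.3
        info = expected_information(np.zeros(k), sigma, _uncensored(y), X)
        expected = np.zeros((k + 1, k + 1))
        expected[:k, :k] = X.T @ X / sigma**2
        expected[k, k] = 2 * n
        np.testing.assert_allclose(info, expected, atol=1e-12)
        pen = firth_penalty(np.zeros(k), sigma, _uncensored(y), X)
        sign, logdet = np.linalg.slogdet(expected)
        assert pen == pytest.approx(0.5 * logdet, abs=1e-10)

    def test_doubling_rows_adds_half_k_log2(self, rng):
        n = 25
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        delta = (rng.random(n) > 0.3).astype(int)
        resp = CensoredResponse(y, delta)
        resp2 = CensoredResponse(np.tile(y, 2), np.tile(delta, 2))
        X2 = np.vstack([X, X])
        beta = np.array([0.2, -0.1])
        p1 = firth_penalty(beta, 0.9, resp, X)
        p2 = firth_penalty(beta, 0.9, resp2, X2)
        n_params = X.shape[1] + 1  # beta plus log sigma
        assert p2 - p1 == pytest.approx(0.5 * n_params * np.log(2), abs=1e-10)

    def test_matches_finite_difference_of_expected_loglik(self, rng):
        """The information matrix equals minus the expected Hessian, estimated
        by finite differences of the analytically averaged log-likelihood."""
        n = 12
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        bounds = rng.normal(-0.5, 0.3, size=n)
        beta = np.array([0.3, -0.2])
        sigma = 0.9
        resp = CensoredResponse(np.zeros(n), np.ones(n, dtype=int), bounds=bounds)

        def expected_loglik(params):
            """E[log L] under truth (beta, sigma), as a function of params.

            Exact closed form via truncated-normal moments: the censored
            part contributes Phi(a) * log Phi of the parameterized bound,
            the observed part a quadratic in the truncated first and
            second moments of the latent Gaussian.
            """
            b, ls = params[:2], params[2]
            s = np.exp(ls)
            total = 0.0
            for i in range(n):
                mu_t = X[i] @ beta
                mu_p = X[i] @ b
                a = (bounds[i] - mu_t) / sigma
                Phi_a, phi_a = stats.norm.cdf(a), stats.norm.pdf(a)
                cens = Phi_a * stats.norm.logcdf((bounds[i] - mu_p) / s)
                delta_mu = mu_t - mu_p
                # E[t 1{t>a}] = phi(a), E[t^2 1{t>a}] = (1-Phi(a)) + a phi(a)
                e0 = 1.0 - Phi_a
                e1 = phi_a
                e2 = e0 + a * phi_a
                sq = delta_mu**2 * e0 + 2 * delta_mu * sigma * e1 + sigma**2 * e2
                obs = e0 * (-0.5 * np.log(2 * np.pi) - np.log(s)) - sq / (2 * s**2)
                total += cens + obs
            return total

        info = expected_information(beta, sigma, resp, X)
        params0 = np.array([beta[0], beta[1], np.log(sigma)])
        h = 1e-4
        hess = np.zeros((3, 3))
        for a in range(3):
            for b_ in range(3):
                pa = params0.copy(); pa[a] += h; pa[b_] += h
                pb = params0.copy(); pb[a] += h; pb[b_] -= h
                pc = params0.copy(); pc[a] -= h; pc[b_] += h
                pd = params0.copy(); pd[a] -= h; pd[b_] -= h
                hess[a, b_] = (
                    expected_loglik(pa) - expected_loglik(pb)
                    - expected_loglik(pc) + expected_loglik(pd)
                ) / (4 * h * h)
        np.testing.assert_allclose(info, -hess, rtol=1e-4, atol=1e-5)

    def test_analytic_penalty_gradient_matches_finite_differences(self, rng):
        from adapt_daa.tobit import TobitConfig, _penalty_and_grad

        cfg = TobitConfig()
        n = 25
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        delta = (rng.random(n) > 0.4).astype(int)
        bounds = np.where(delta == 0, y, np.where(rng.random(n) > 0.5, y - 1, -np.inf))
        resp = CensoredResponse(y, delta, bounds=bounds)
        params = np.array([0.3, -0.2, 0.1])
        pen, grad = _penalty_and_grad(params, X, resp, cfg)
        assert pen == pytest.approx(
            firth_penalty(params[:2], np.exp(params[2]), resp, X, cfg), abs=1e-12
        )
        h = 1e-6
        for j in range(3):
            pp, pm = params.copy(), params.copy()
            pp[j] += h
            pm[j] -= h
            fd = (
                firth_penalty(pp[:2], np.exp(pp[2]), resp, X, cfg)
                - firth_penalty(pm[:2], np.exp(pm[2]), resp, X, cfg)
            ) / (2 * h)
            assert grad[j] == pytest.approx(fd, abs=1e-6)

    def test_singular_information_returns_guard_not_nan(self):
        X = np.column_stack([np.ones(3), np.ones(3)])  # rank deficient
        resp = _uncensored(np.array([1.0, 2.0, 3.0]))
        pen = firth_penalty(np.zeros(2), 1.0, resp, X)
        assert np.isfinite(pen)
        assert pen <= -1e5


class TestFitTobit:
    def test_uncensored_unpenalized_equals_least_squares(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [1.0, 0.5, -0.2] + rng.normal(size=n)
        fit = fit_tobit(_uncensored(y), X, penalized=False, tested_index=1)
        bols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.coefficients, bols, atol=1e-6)
        sigma_mle = np.sqrt(np.mean((y - X @ bols) ** 2))
        assert fit.scale == pytest.approx(sigma_mle, abs=1e-6)

    def test_parameter_recovery_under_heavy_censoring(self):
        """n=2000, ~30% censored at a fixed bound: estimates near truth."""
        rng = np.random.default_rng(42)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + rng.normal(size=n)
        bound = np.quantile(y, 0.3)
        delta = (y > bound).astype(int)
        v = np.where(delta == 1, y, bound)
        resp = CensoredResponse(v, delta, bounds=np.full(n, bound))
        fit = fit_tobit(resp, X, penalized=True, tested_index=1)
        assert fit.converged
        assert abs(fit.coefficients[0] - 1.0) < 0.1
        assert abs(fit.coefficients[1] - 0.5) < 0.1
        assert abs(fit.scale - 1.0) < 0.05

    def test_complete_separation_finite_with_penalty(self, rng):
        """A taxon observed only in one condition still gets a finite
        estimate and a usable P-value when penalized."""
        n = 40
        cond = np.repeat([0, 1], n // 2)
        X = np.column_stack([np.ones(n), cond])
        v = np.where(cond == 1, rng.normal(1.5, 0.5, n), -4.0)
        delta = (cond == 1).astype(int)
        resp = CensoredResponse(v, delta, bounds=np.full(n, -4.0))
        fit = fit_tobit(resp, X, penalized=True, tested_index=1)
        assert np.isfinite(fit.tested_estimate)
        assert 0.0 < fit.p_value < 1.0
        assert fit.lrt_stat >= 0.0

    def test_response_shift_moves_only_intercept(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [0.5, 1.0] + rng.normal(size=n)
        delta = (y > -0.5).astype(int)
        v = np.where(delta == 1, y, -0.5)
        resp = CensoredResponse(v, delta, bounds=np.full(n, -0.5))
        fit = fit_tobit(resp, X, penalized=True)
        c = 3.7
        resp_shift = CensoredResponse(v + c, delta, bounds=np.full(n, -0.5 + c))
        fit_s = fit_tobit(resp_shift, X, penalized=True)
        assert fit_s.coefficients[0] == pytest.approx(fit.coefficients[0] + c, abs=1e-4)
        assert fit_s.tested_estimate == pytest.approx(fit.tested_estimate, abs=1e-4)
        assert fit_s.p_value == pytest.approx(fit.p_value, rel=1e-3)

    def test_lrt_invariant_to_recoding_of_untested_covariate(self, rng):
        n = 60
        z = rng.normal(size=n)
        cond = rng.integers(0, 2, n)
        X = np.column_stack([np.ones(n), cond, z])
        y = X @ [0.5, 0.8, 0.3] + rng.normal(size=n)
        delta = (y > -1.0).astype(int)
        v = np.where(delta == 1, y, -1.0)
        resp = CensoredResponse(v, delta, bounds=np.full(n, -1.0))
        X_recoded = np.column_stack([np.ones(n), cond, 2.5 * z - 7.0])
        f1 = fit_tobit(resp, X, penalized=False, tested_index=1)
        f2 = fit_tobit(resp, X_recoded, penalized=False, tested_index=1)
        assert f1.lrt_stat == pytest.approx(f2.lrt_stat, abs=1e-5)

    def test_null_pvalues_uniform(self):
        """Penalized LRT P-values under a true null pass a KS uniformity check."""
        rng = np.random.default_rng(3)
        n = 40
        cond = np.repeat([0, 1], n // 2)
        X = np.column_stack([np.ones(n), cond])
        pvals = []
        for _ in range(400):
            y = rng.normal(size=n)
            bound = np.quantile(y, 0.4)
            delta = (y > bound).astype(int)
            v = np.where(delta == 1, y, bound)
            resp = CensoredResponse(v, delta, bounds=np.full(n, bound))
            pvals.append(fit_tobit(resp, X, penalized=True).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestFitAllTaxa:
    def _make(self, rng, P=6, N=30):
        from adapt_daa import CountTable, censor
        counts = rng.integers(0, 20, size=(P, N))
        counts[:, counts.sum(axis=0) == 0] = 1
        ct = CountTable(counts, [f"t{j}" for j in range(P)], [f"s{i}" for i in range(N)])
        cct = censor(ct, 1.0)
        cond = rng.integers(0, 2, N).astype(float)
        cond[:2] = [0, 1]
        design = CovariateDesign(
            np.column_stack([np.ones(N), cond]), ["intercept", "condition"]
        )
        return cct, design

    def _responses(self, cct):
        from adapt_daa.reference import subset_responses
        return subset_responses(cct, np.arange(cct.n_taxa))

    def test_one_fit_per_taxon_in_order(self, rng):
        cct, design = self._make(rng)
        fits = fit_all_taxa(cct, design, self._responses(cct))
        assert len(fits) == cct.n_taxa

    def test_worker_count_does_not_change_results(self, rng):
        cct, design = self._make(rng)
        f1 = fit_all_taxa(cct, design, self._responses(cct), n_jobs=1)
        f2 = fit_all_taxa(cct, design, self._responses(cct), n_jobs=2)
        for a, b in zip(f1, f2):
            assert a.tested_estimate == b.tested_estimate
            assert a.p_value == b.p_value

    def test_bad_taxon_yields_flagged_fit_not_crash(self, rng):
        cct, design = self._make(rng)
        responses = self._responses(cct)

        class Broken:
            values = None
            indicators = None

        responses[2] = Broken()
        with pytest.warns(RuntimeWarning):
            fits = fit_all_taxa(cct, design, responses)
        assert len(fits) == cct.n_taxa
        assert fits[2].error is not None
        assert fits[2].converged is False
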