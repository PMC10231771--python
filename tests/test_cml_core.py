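import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from _reference import (
    cml_independent_fit,
    cml_independent_select,
    exhaustive_cml,
    nll_via_density,
    numerical_hessian,
)
from conftest import make_pair, perfect_pair
from graphmr import (
    SummaryPair,
    fit_fixed_k,
    ivw_estimate,
    neg_loglik,
    se_fisher,
    se_sandwich,
    select_bic,
    update_b_x,
    update_r,
    update_theta,
)
from graphmr.cml_core import _select_bic_batch
from graphmr.exceptions import ParameterError


def one_snp_pair(beta_x, se_x, beta_y, se_y, rho=0.0):
    return SummaryPair(["rs1"], [beta_x], [se_x], [beta_y], [se_y], rho, 1000, 1000)


class TestNegLoglik:
    def test_perfect_fit_is_zero(self):
        pair = one_snp_pair(0.2, 0.1, 0.1, 0.2)
        assert neg_loglik(0.5, [0.2], [0.0], pair) == 0.0

    def test_single_snp_arithmetic(self):
        # residuals of one SD in each trait at rho=0: (1 + 1) / 2 = 1
        pair = one_snp_pair(0.2, 0.1, 0.3, 0.2)
        assert neg_loglik(1.0, [0.1], [0.0], pair) == pytest.approx(1.0)

    def test_matches_bivariate_density_up_to_constant(self, rng):
        pair = make_pair(rng, m=8, rho=0.5)
        b_x = pair.beta_x + 0.01 * rng.standard_normal(8)
        r = 0.05 * rng.standard_normal(8)
        theta = 0.3
        ours = neg_loglik(theta, b_x, r, pair)
        oracle = nll_via_density(theta, b_x, r, pair)
        assert ours == pytest.approx(oracle, rel=1e-9)

    def test_rho_out_of_range_raises(self):
        pair = one_snp_pair(0.2, 0.1, 0.3, 0.2)
        pair.rho = 1.0
        with pytest.raises(ParameterError):
            neg_loglik(0.5, [0.2], [0.0], pair)


class TestClosedFormUpdates:
    def test_update_r_rho_zero_is_outcome_residual(self, rng):
        pair = make_pair(rng, m=5, rho=0.0)
        b_x = pair.beta_x * 0.9
        np.testing.assert_allclose(
            update_r(0.3, b_x, pair), pair.beta_y - 0.3 * b_x, atol=1e-14
        )

    def test_update_r_exposure_fit_ignores_rho(self, rng):
        pair = make_pair(rng, m=5, rho=0.6)
        np.testing.assert_allclose(
            update_r(0.3, pair.beta_x, pair),
            pair.beta_y - 0.3 * pair.beta_x,
            atol=1e-14,
        )

    def test_update_b_x_reduces_at_null(self, rng):
        pair = make_pair(rng, m=5, rho=0.0)
        np.testing.assert_allclose(
            update_b_x(0.0, np.zeros(5), pair), pair.beta_x, atol=1e-14
        )

    def test_update_b_x_rho_zero_formula(self, rng):
        pair = make_pair(rng, m=5, rho=0.0)
        theta, r = 0.4, 0.02 * rng.standard_normal(5)
        expected = (
            pair.beta_x / pair.se_x**2 + theta * (pair.beta_y - r) / pair.se_y**2
        ) / (1.0 / pair.se_x**2 + theta**2 / pair.se_y**2)
        np.testing.assert_allclose(update_b_x(theta, r, pair), expected, atol=1e-14)

    def test_update_theta_weighted_ls(self):
        pair = SummaryPair(
            ["a", "b"], [1.0, 1.0], [1.0, 1.0], [0.2, 0.4], [1.0, 1.0], 0.0, 100, 100
        )
        assert update_theta([1.0, 1.0], [0.0, 0.0], pair) == pytest.approx(0.3)

    def test_update_theta_zero_numerator(self, rng):
        pair = make_pair(rng, m=4, rho=0.0)
        assert update_theta(pair.beta_x, pair.beta_y, pair) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("rho", [0.4, -0.3])
    def test_updates_match_numeric_minimizers(self, rng, rho):
        pair = make_pair(rng, m=4, rho=rho)
        theta = 0.2
        b_x = pair.beta_x * 0.95
        r_hat = update_r(theta, b_x, pair)
        for i in range(pair.m):
            def f_r(ri, i=i):
                r = r_hat.copy()
                r[i] = ri
                return neg_loglik(theta, b_x, r, pair)

            res = minimize_scalar(f_r, bracket=(r_hat[i] - 1, r_hat[i] + 1))
            assert r_hat[i] == pytest.approx(res.x, abs=1e-8)

        r = 0.01 * rng.standard_normal(pair.m)
        b_hat = update_b_x(theta, r, pair)
        for i in range(pair.m):
            def f_b(bi, i=i):
                b = b_hat.copy()
                b[i] = bi
                return neg_loglik(theta, b, r, pair)

            res = minimize_scalar(f_b, bracket=(b_hat[i] - 1, b_hat[i] + 1))
            assert b_hat[i] == pytest.approx(res.x, abs=1e-8)

        t_hat = update_theta(b_hat, r, pair)
        res = minimize_scalar(
            lambda t: neg_loglik(t, b_hat, r, pair), bracket=(t_hat - 1, t_hat + 1)
        )
        assert t_hat == pytest.approx(res.x, abs=1e-8)


class TestFitFixedK:
    def test_perfect_fit_recovers_theta_exactly(self):
        pair = perfect_pair(m=6, theta=0.5)
        fit = fit_fixed_k(pair, K=0)
        assert fit.theta == pytest.approx(0.5, abs=1e-10)
        assert -fit.loglik == pytest.approx(0.0, abs=1e-12)
        assert fit.converged

    def test_k_out_of_range_raises(self):
        pair = perfect_pair(m=4)
        with pytest.raises(ParameterError):
            fit_fixed_k(pair, K=3)

    def test_single_gross_invalid_matches_exhaustive_oracle(self, rng):
        pair = make_pair(rng, m=4, theta=0.2, rho=0.0, n_invalid=1, r_scale=1.0)
        fit = fit_fixed_k(pair, K=1, tol=1e-12, max_iter=500)
        nll_o, theta_o, subset_o = exhaustive_cml(pair, K=1)
        assert -fit.loglik == pytest.approx(nll_o, abs=1e-6)
        assert fit.theta == pytest.approx(theta_o, abs=1e-6)
        assert tuple(fit.invalid_set) == subset_o

    def test_nll_trace_monotone_nonincreasing(self, rng):
        for n_invalid in (0, 2):
            pair = make_pair(rng, m=10, rho=0.3, n_invalid=n_invalid)
            fit = fit_fixed_k(pair, K=n_invalid)
            diffs = np.diff(fit.nll_trace)
            assert np.all(diffs <= 1e-10)

    def test_selection_gains_nonnegative(self, rng):
        # freeing r_i can only increase the per-SNP likelihood
        pair = make_pair(rng, m=8, rho=0.4, n_invalid=2)
        theta, b_x = 0.1, pair.beta_x * 0.9
        nll0 = np.array([
            neg_loglik(theta, b_x[[i]], [0.0], _sub(pair, i)) for i in range(8)
        ])
        nll_free = 0.5 * ((pair.beta_x - b_x) / pair.se_x) ** 2
        assert np.all(nll0 - nll_free >= -1e-12)

    def test_stationarity_at_convergence(self, rng):
        pair = make_pair(rng, m=10, rho=0.5, n_invalid=2)
        fit = fit_fixed_k(pair, K=2, tol=1e-10, max_iter=500)
        assert fit.converged
        r_new = np.zeros(10)
        r_cand = update_r(fit.theta, fit.b_x, pair)
        r_new[fit.invalid_set] = r_cand[fit.invalid_set]
        np.testing.assert_allclose(r_new, fit.r, atol=1e-6)
        np.testing.assert_allclose(update_b_x(fit.theta, fit.r, pair), fit.b_x, atol=1e-6)
        assert update_theta(fit.b_x, fit.r, pair) == pytest.approx(fit.theta, abs=1e-6)

    def test_invalid_ivs_are_inert(self, rng):
        pair = make_pair(rng, m=10, rho=0.3, n_invalid=2, r_scale=1.0)
        fit = fit_fixed_k(pair, K=2, theta_init=0.0, tol=1e-10, max_iter=500)
        keep = np.setdiff1d(np.arange(10), fit.invalid_set)
        sub = SummaryPair(
            [pair.snp_ids[i] for i in keep],
            pair.beta_x[keep], pair.se_x[keep],
            pair.beta_y[keep], pair.se_y[keep],
            pair.rho, pair.n_x, pair.n_y,
        )
        refit = fit_fixed_k(sub, K=0, theta_init=fit.theta, tol=1e-10, max_iter=500)
        assert refit.theta == pytest.approx(fit.theta, abs=1e-6)


def _sub(pair, i):
    return SummaryPair(
        [pair.snp_ids[i]], pair.beta_x[[i]], pair.se_x[[i]],
        pair.beta_y[[i]], pair.se_y[[i]], pair.rho, pair.n_x, pair.n_y,
    )


class TestSelectBic:
    def test_bic_arithmetic(self, rng):
        pair = make_pair(rng, m=6, rho=0.0)
        sel = select_bic(pair, n_eff=1000, n_starts=1, keep_fits=True)
        for k, fit in sel.fits.items():
            assert sel.bic[k] == pytest.approx(-2 * fit.loglik + np.log(1000) * k)

    def test_noiseless_consistent_data_selects_k0(self):
        pair = perfect_pair(m=8, theta=0.4)
        sel = select_bic(pair, n_starts=1)
        assert sel.k_hat == 0

    def test_gross_invalid_pair_selected_with_high_probability(self):
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            gen = np.random.default_rng(50_000 + rep)
            pair = make_pair(gen, m=10, theta=0.2, rho=0.0, n_invalid=2, r_scale=1.0)
            sel = select_bic(pair, n_eff=100_000, n_starts=3, rng=rep)
            hits += sel.k_hat == 2 and set(sel.fit.invalid_set) == {0, 1}
        assert hits >= 0.95 * n_rep

    def test_empty_grid_raises(self, rng):
        pair = make_pair(rng, m=5)
        with pytest.raises(ParameterError):
            select_bic(pair, k_grid=[])


class TestRhoZeroReduction:
    def test_fit_matches_independent_implementation(self, rng):
        # at rho=0 the method collapses to the working-independence original
        for rep in range(20):
            gen = np.random.default_rng(777 + rep)
            pair = make_pair(gen, m=8, rho=0.0, n_invalid=rep % 3)
            theta0 = ivw_estimate(pair)
            for K in (0, 1, 2):
                ours = fit_fixed_k(pair, K, theta_init=theta0)
                theta_ref, b_ref, r_ref, inv_ref, nll_ref = cml_independent_fit(
                    pair.beta_x, pair.se_x, pair.beta_y, pair.se_y, K, theta0
                )
                assert ours.theta == pytest.approx(theta_ref, abs=1e-10)
                assert -ours.loglik == pytest.approx(nll_ref, abs=1e-10)
                assert list(ours.invalid_set) == inv_ref

    def test_selection_matches_independent_implementation(self, rng):
        pair = make_pair(rng, m=8, rho=0.0, n_invalid=2, r_scale=1.0)
        theta0 = ivw_estimate(pair)
        sel = select_bic(pair, n_eff=100_000, n_starts=1, refine_swaps=False)
        bic_ref, k_ref, theta_ref, _ = cml_independent_select(
            pair.beta_x, pair.se_x, pair.beta_y, pair.se_y, 100_000, theta0
        )
        assert sel.k_hat == k_ref
        assert sel.fit.theta == pytest.approx(theta_ref, abs=1e-10)


class TestBatchEngine:
    def test_batch_matches_scalar_select(self, rng):
        B, m = 12, 8
        pairs = [make_pair(np.random.default_rng(900 + b), m=m, rho=0.4, n_invalid=b % 3)
                 for b in range(B)]
        sx, sy = pairs[0].se_x, pairs[0].se_y
        pairs = [
            SummaryPair(p.snp_ids, p.beta_x, sx, p.beta_y, sy, 0.4, p.n_x, p.n_y)
            for p in pairs
        ]
        bx = np.stack([p.beta_x for p in pairs])
        by = np.stack([p.beta_y for p in pairs])
        theta_b, k_b, _, conv_b = _select_bic_batch(bx, sx, by, sy, 0.4, 100_000)
        for b, p in enumerate(pairs):
            sel = select_bic(p, n_eff=100_000, n_starts=1, refine_swaps=False)
            assert theta_b[b] == pytest.approx(sel.fit.theta, abs=1e-6)
            assert k_b[b] == sel.k_hat


class TestStandardErrors:
    def test_fisher_matches_numerical_hessian(self, rng):
        pair = make_pair(rng, m=6, rho=0.0, n_invalid=1, r_scale=1.0)
        fit = fit_fixed_k(pair, K=1, tol=1e-12, max_iter=500)
        se = se_fisher(fit, pair)
        valid = np.flatnonzero(fit.valid_mask)

        def f(params):
            b_full = fit.b_x.copy()
            b_full[valid] = params[1:]
            r = fit.r.copy()
            r[fit.invalid_set] = pair.beta_y[fit.invalid_set] - params[0] * pair.beta_x[fit.invalid_set]
            return neg_loglik(params[0], b_full, r, pair)

        x0 = np.concatenate([[fit.theta], fit.b_x[valid]])
        H = numerical_hessian(f, x0, h=1e-5)
        se_num = np.sqrt(np.linalg.inv(H)[0, 0])
        assert se == pytest.approx(se_num, rel=1e-5)

    def test_fisher_matches_numerical_hessian_with_rho(self, rng):
        pair = make_pair(rng, m=6, rho=0.5)
        fit = fit_fixed_k(pair, K=0, tol=1e-12, max_iter=500)
        se = se_fisher(fit, pair)

        def f(params):
            return neg_loglik(params[0], params[1:], np.zeros(6), pair)

        x0 = np.concatenate([[fit.theta], fit.b_x])
        H = numerical_hessian(f, x0, h=1e-5)
        se_num = np.sqrt(np.linalg.inv(H)[0, 0])
        assert se == pytest.approx(se_num, rel=1e-5)

    def test_se_scales_linearly_with_noise(self):
        pair = perfect_pair(m=8, theta=0.5)
        fit = fit_fixed_k(pair, K=0)
        se1 = se_fisher(fit, pair)
        scaled = SummaryPair(
            pair.snp_ids, pair.beta_x, 3.0 * pair.se_x,
            pair.beta_y, 3.0 * pair.se_y, 0.0, pair.n_x, pair.n_y,
        )
        fit2 = fit_fixed_k(scaled, K=0)
        assert se_fisher(fit2, scaled) == pytest.approx(3.0 * se1, rel=1e-8)

    def test_sandwich_equals_fisher_at_rho_zero_perfect_fit(self):
        pair = perfect_pair(m=8, theta=0.5, rho=0.0)
        fit = fit_fixed_k(pair, K=0)
        assert se_sandwich(fit, pair) == pytest.approx(se_fisher(fit, pair), rel=1e-6)

    @pytest.mark.parametrize("rho_true", [0.0, 0.5])
    def test_sandwich_calibrated_under_working_independence(self, rho_true):
        # fit with rho=0 while the data are generated at rho_true; the
        # sandwich SE should track the Monte-Carlo SD of theta-hat
        n_rep = 400
        thetas = np.empty(n_rep)
        sands = np.empty(n_rep)
        for rep in range(n_rep):
            gen = np.random.default_rng(3_000_000 + rep)
            pair = make_pair(gen, m=20, theta=0.2, rho=rho_true)
            working = SummaryPair(
                pair.snp_ids, pair.beta_x, pair.se_x, pair.beta_y, pair.se_y,
                0.0, pair.n_x, pair.n_y,
            )
            fit = fit_fixed_k(working, K=0)
            working.rho = rho_true  # meat evaluated under the true covariance
            thetas[rep] = fit.theta
            sands[rep] = se_sandwich(fit, working)
        assert thetas.std(ddof=1) == pytest.approx(sands.mean(), rel=0.10)
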