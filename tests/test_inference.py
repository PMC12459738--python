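import numpy as np
import pytest
from scipy import optimize, stats

from lgcmtrial.inference import (
    ModelSpec,
    fit_ml,
    gelman_rubin,
    loo,
    sample_posterior,
    waic,
    wald_test,
)
from lgcmtrial.lgcm import Covariates, implied_moments, LGCMParams
from lgcmtrial.measures import time_basis
from lgcmtrial.synthetic import GeneratorConfig, generate

JITTER = 1e-4


class TestFitMl:
    def test_noise_free_trajectories_recovered_exactly(self, basis):
        """With zero variance the trajectories are deterministic and the mean
        parameters are identified exactly (up to optimizer tolerance)."""
        f = basis.loading_array()
        rows, cov = [], []
        for g in (0, 1):
            for fem in (0, 1):
                for _ in range(3):
                    rows.append(5.0 - 1.0 * f)
                    cov.append([g, fem])
        fit = fit_ml(np.array(rows), np.array(cov, dtype=float), basis)
        assert fit.converged
        assert fit.params.b00 == pytest.approx(5.0, abs=1e-4)
        assert fit.params.b10 == pytest.approx(-1.0, abs=1e-4)
        for name in ("b0exp", "b0female", "b1exp", "b1female"):
            assert getattr(fit.params, name) == pytest.approx(0.0, abs=1e-4)

    def test_recovers_slope_arm_effect_within_mc_error(self, basis):
        cfg = GeneratorConfig(n_exp=1000, n_wait=1000, dropout=(0, 0, 0, 0))
        ds = generate(cfg, seed=314)
        fit = fit_ml(ds.outcome_matrix("qids"), ds.covariate_matrix(), basis)
        assert fit.converged
        assert abs(fit.params.b1exp - (-0.319)) < 3 * fit.se["b1exp"]

    def test_matches_brute_force_maximum_on_tiny_instance(self):
        """n=6, 2 waves, no covariates: L-BFGS-B agrees with an independent
        global maximisation (differential evolution + polish) of the same
        observed-data likelihood, evaluated through an independent dense
        multivariate-normal implementation."""
        tb = time_basis([0, 1])
        y = np.array([
            [2.0, 1.0], [3.5, 2.5], [1.0, np.nan],
            [2.5, 2.0], [np.nan, 1.5], [3.0, 1.0],
        ])
        cov = np.zeros((6, 2))
        f = tb.loading_array()

        def dense_negll(th):
            b00, b10, v0, v1, r, v2 = th
            psi = np.array([[v0, r * np.sqrt(v0 * v1)], [r * np.sqrt(v0 * v1), v1]])
            lam = np.column_stack([np.ones(2), f])
            sig = lam @ psi @ lam.T + v2 * np.eye(2)
            mu = b00 + b10 * f
            ll = 0.0
            for row in y:
                obs = ~np.isnan(row)
                k = obs.sum()
                sub = sig[np.ix_(obs, obs)] + JITTER * np.eye(k)
                ll += stats.multivariate_normal(mean=mu[obs], cov=sub).logpdf(row[obs])
            return -ll

        bounds = [(-5, 10), (-5, 5), (1e-6, 10), (1e-6, 10), (-0.99, 0.99), (1e-6, 10)]
        de = optimize.differential_evolution(dense_negll, bounds, seed=7, tol=1e-10,
                                             maxiter=400, polish=True)
        fit = fit_ml(y, cov, tb, spec=ModelSpec(arm_effect=False, gender_effect=False))
        assert fit.loglik == pytest.approx(-de.fun, abs=1e-4)

    def test_mcar_deletion_leaves_slope_unbiased(self, basis):
        """20% completely-at-random missingness: FIML point estimates stay
        within Monte-Carlo error of the truth."""
        cfg = GeneratorConfig(n_exp=800, n_wait=800, dropout=(0.2, 0.2, 0.2, 0.2))
        ds = generate(cfg, seed=2718)
        fit = fit_ml(ds.outcome_matrix("qids"), ds.covariate_matrix(), basis)
        assert abs(fit.params.b1exp - (-0.319)) < 3 * fit.se["b1exp"]

    def test_all_missing_outcome_rejected(self, basis):
        y = np.full((5, 4), np.nan)
        y[:, 0] = 1.0
        y[:, 1] = 2.0
        with pytest.raises(ValueError, match="wave"):
            fit_ml(y, np.zeros((5, 2)), basis)


class TestWald:
    @pytest.mark.parametrize("z, p3", [(2.321, 0.020), (-2.703, 0.007)])
    def test_z_to_p_table_pairs(self, z, p3):
        res = wald_test(z, 1.0)
        assert round(res.pvalue, 3) == p3

    def test_null_estimate(self):
        res = wald_test(0.0, 2.0)
        assert res.z == 0.0
        assert res.pvalue == pytest.approx(1.0)
        assert res.ci95[0] == -res.ci95[1]

    def test_ci_uses_normal_quantile(self):
        res = wald_test(1.0, 0.5)
        assert res.ci95 == pytest.approx((1 - 1.959964 * 0.5, 1 + 1.959964 * 0.5))

    def test_rejects_bad_se(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestGelmanRubin:
    def test_identical_chains_with_variance(self):
        # periodic sequence: the two split halves are identical, so the
        # between-half variance is exactly zero while W > 0
        chain = np.tile([0.0, 1.0, 2.0, 1.0], 50)[None, :]
        rhat = gelman_rubin(np.vstack([chain, chain]))
        assert rhat[0] <= 1 + 1e-6

    def test_duplicated_stochastic_chains_near_one(self, rng):
        # split halves of a random chain differ slightly, so R-hat sits just
        # above 1 at O(1/n) but must stay close
        chain = rng.normal(size=(1, 400))
        rhat = gelman_rubin(np.vstack([chain, chain]))
        assert 0.99 <= rhat[0] <= 1.02

    def test_same_distribution_long_chains(self, rng):
        draws = rng.normal(size=(4, 20000, 1))
        assert gelman_rubin(draws)[0] == pytest.approx(1.0, abs=5e-3)

    def test_constant_chains_at_different_values(self):
        draws = np.stack([np.zeros(50), np.ones(50)])
        assert gelman_rubin(draws)[0] == np.inf

    def test_identical_constant_chains(self):
        draws = np.ones((2, 50))
        assert gelman_rubin(draws)[0] == 1.0

    def test_shifted_chains_flagged(self, rng):
        a = rng.normal(0, 1, size=1000)
        b = rng.normal(5, 1, size=1000)
        assert gelman_rubin(np.stack([a, b]))[0] > 2.0

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


HAND_LL = np.array([[-1.0, -2.0], [-1.5, -1.0], [-2.0, -3.0]])  # 3 draws x 2 units


def _hand_waic(ll):
    import math
    s, n = ll.shape
    elpd = 0.0
    p = 0.0
    for i in range(n):
        col = ll[:, i]
        lppd = math.log(sum(math.exp(v) for v in col) / s)
        var = sum((v - col.mean()) ** 2 for v in col) / (s - 1)
        elpd += lppd - var
        p += var
    return elpd, p


def _hand_loo(ll):
    import math
    s, n = ll.shape
    elpd = 0.0
    for i in range(n):
        col = ll[:, i]
        raw = [math.exp(-v) for v in col]
        cap = (sum(raw) / s) * s**0.75
        w = [min(x, cap) for x in raw]
        elpd += math.log(sum(wi * math.exp(v) for wi, v in zip(w, col)) / sum(w))
    return elpd


class TestWaic:
    def test_single_draw_has_zero_penalty(self):
        res = waic(HAND_LL[:1])
        assert res.p_waic == 0.0
        assert res.elpd_waic == pytest.approx(HAND_LL[0].sum())

    def test_identical_draws_zero_penalty(self):
        ll = np.tile(HAND_LL[:1], (5, 1))
        assert waic(ll).p_waic == pytest.approx(0.0, abs=1e-12)

    def test_hand_matrix(self):
        elpd, p = _hand_waic(HAND_LL)
        res = waic(HAND_LL)
        assert res.elpd_waic == pytest.approx(elpd, rel=1e-12)
        assert res.p_waic == pytest.approx(p, rel=1e-12)
        assert res.deviance == pytest.approx(-2 * elpd, rel=1e-12)

    def test_invariant_to_unit_reordering(self, rng):
        ll = rng.normal(-2, 0.5, size=(20, 15))
        perm = rng.permutation(15)
        assert waic(ll[:, perm]).elpd_waic == pytest.approx(waic(ll).elpd_waic, rel=1e-12)
        assert loo(ll[:, perm]).elpd_loo == pytest.approx(loo(ll).elpd_loo, rel=1e-12)

    def test_agrees_with_arviz(self, rng):
        """Independent cross-check; arviz computes the penalty with the
        population variance (ddof=0) where we follow the sample-variance
        (ddof=1) convention, so compare after aligning the penalty."""
        az = pytest.importorskip("arviz")
        ll = rng.normal(-2, 0.3, size=(2, 100, 8))  # chains x draws x units
        idata = az.from_dict(log_likelihood={"y": ll})
        ref = az.waic(idata, scale="log")
        flat = ll.reshape(-1, 8)
        ours = waic(flat)
        s = flat.shape[0]
        elpd_pop_var = ours.elpd_waic + ours.p_waic - ours.p_waic * (s - 1) / s
        assert elpd_pop_var == pytest.approx(float(ref.elpd_waic), rel=1e-8)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            waic(np.array([[0.0, -np.inf]]))


class TestLoo:
    def test_identical_draws_equal_waic(self):
        ll = np.tile(HAND_LL[:1], (4, 1))
        assert loo(ll).elpd_loo == pytest.approx(waic(ll).elpd_waic, abs=1e-12)

    def test_hand_matrix(self):
        res = loo(HAND_LL)
        assert res.elpd_loo == pytest.approx(_hand_loo(HAND_LL), rel=1e-12)
        assert res.deviance == pytest.approx(-2 * res.elpd_loo, rel=1e-12)

    def test_never_exceeds_in_sample_lpd(self, rng):
        ll = rng.normal(-2, 0.8, size=(50, 30))
        lpd = waic(ll).elpd_waic + waic(ll).p_waic
        assert loo(ll).elpd_loo <= lpd + 1e-12


class TestSamplePosterior:
    def test_conjugate_mean_matches_closed_form(self, basis):
        """Only the grand intercept free, known residual variance: the
        posterior is conjugate normal and the sampler must land on it."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        n, sig2 = 50, 4.0
        y = rng.normal(3.0, np.sqrt(sig2), size=(n, 4))
        cov = np.zeros((n, 2))
        spec = ModelSpec(
            arm_effect=False, gender_effect=False, free_cov=False,
            fixed={"b10": 0.0, "var_e0": 0.0, "var_e1": 0.0, "var_e2": sig2},
        )
        post = sample_posterior(y, cov, basis, n_chains=2, n_iter=2500,
                                n_warmup=1500, seed=17, spec=spec)
        draws = post.flat_draws()[:, post.param_names.index("b00")]
        # prior N(mean_y, (10 sd_y)^2), likelihood 4n obs at variance sig2+jitter
        sd_y = np.nanstd(y, ddof=1)
        tau2 = (10 * sd_y) ** 2
        s2 = sig2 + JITTER
        n_obs = y.size
        post_prec = 1 / tau2 + n_obs / s2
        post_mean = (np.nanmean(y) / tau2 + y.sum() / s2) / post_prec
        ess = float(az.ess(post.draws[:, :, post.param_names.index("b00")]))
        mcse = draws.std() / np.sqrt(max(ess, 4))
        assert draws.mean() == pytest.approx(post_mean, abs=3 * max(mcse, 1e-4))
        assert draws.std() == pytest.approx(np.sqrt(1 / post_prec), rel=0.2)

    def test_reproducible_given_seed(self, basis):
        cfg = GeneratorConfig(n_exp=25, n_wait=25, dropout=(0, 0, 0, 0))
        ds = generate(cfg, seed=8)
        y = ds.outcome_matrix("qids")
        cov = ds.covariate_matrix()
        spec = ModelSpec(arm_effect=False, gender_effect=False, free_cov=False)
        a = sample_posterior(y, cov, basis, n_chains=2, n_iter=150, n_warmup=150,
                             seed=3, spec=spec)
        b = sample_posterior(y, cov, basis, n_chains=2, n_iter=150, n_warmup=150,
                             seed=3, spec=spec)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.pointwise_loglik, b.pointwise_loglik)

    def test_duplicated_chain_keeps_rhat_valid(self, rng):
        """Chains that happen to be identical still give a finite R-hat ~ 1."""
        chain = rng.normal(size=(1, 400, 2))
        rhat = gelman_rubin(np.concatenate([chain, chain], axis=0))
        assert np.all(np.isfinite(rhat))
        assert np.all(rhat <= 1.02)

    def test_elpd_stable_when_doubling_iterations(self, basis):
        cfg = GeneratorConfig(n_exp=30, n_wait=30, dropout=(0, 0, 0, 0))
        ds = generate(cfg, seed=21)
        y = ds.outcome_matrix("qids")
        cov = ds.covariate_matrix()
        spec = ModelSpec(arm_effect=False, gender_effect=False, free_cov=False)
        short = sample_posterior(y, cov, basis, n_chains=2, n_iter=1500,
                                 n_warmup=1500, seed=4, spec=spec)
        long = sample_posterior(y, cov, basis, n_chains=2, n_iter=3000,
                                n_warmup=1500, seed=4, spec=spec)
        w_s, w_l = short.waic(), long.waic()
        mc_se = max(w_s.se, w_l.se, 1e-6)
        assert abs(w_s.elpd_waic - w_l.elpd_waic) < 3 * mc_se
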