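"""Bayes modal scoring, the Gibbs sampler blocks, and MML calibration."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import invgamma, invwishart

import testmat as tm
from testmat.estimation import (
    ChainConfig,
    PriorSpec,
    _GibbsState,
    phi_conditional_params,
    sigma2_conditional_params,
)

from conftest import response_loglik


def rasch_item(b, testlet="t", iid="i", P=1, dim=0):
    a = np.zeros(P)
    a[dim] = 1.0
    return tm.Item(id=iid, a=a, b=b, testlet_id=testlet)


class TestBayesModal:
    def test_no_responses_returns_prior_mean(self):
        theta, gamma = tm.bayes_modal([], [], tm.expand_prior(tm.STUDY_PHI))
        np.testing.assert_array_equal(theta, np.zeros(3))
        assert gamma == {}

    def test_single_rasch_item_grid_oracle(self):
        # maximize -theta^2/2 + log logistic(theta) on a fine grid
        grid = np.arange(-4, 4, 1e-4)
        post = -(grid**2) / 2 + np.log(expit(grid))
        oracle = grid[np.argmax(post)]
        theta, _ = tm.bayes_modal([1], [rasch_item(0.0)], tm.expand_prior(np.eye(1)))
        assert theta[0] == pytest.approx(oracle, abs=1e-3)
        assert theta[0] == pytest.approx(0.4011, abs=1e-3)

    def test_matches_independent_optimizer_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            P = int(rng.integers(1, 3))
            testlets = ["ta", "tb"][: int(rng.integers(1, 3))]
            items = [
                tm.Item(
                    id=f"i{i}",
                    a=rng.uniform(0.4, 1.6, P),
                    b=float(rng.uniform(-1.5, 1.5)),
                    c=float(rng.uniform(0, 0.2)),
                    testlet_id=testlets[int(rng.integers(len(testlets)))],
                )
                for i in range(int(rng.integers(2, 6)))
            ]
            order = [t for t in testlets if any(i.testlet_id == t for i in items)]
            prior = tm.expand_prior(np.eye(P), [0.8] * len(order))
            u = rng.integers(0, 2, len(items)).tolist()
            theta, gamma = tm.bayes_modal(u, items, prior, testlet_order=order)
            x_pkg = np.concatenate([theta, [gamma[t] for t in order]])
            prec = prior.precision()

            def neg_post(x):
                ll = response_loglik(x[:P], dict(zip(order, x[P:])), items, u)
                return -(ll - 0.5 * x @ prec @ x)

            res = minimize(neg_post, np.zeros(P + len(order)), method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000})
            assert neg_post(x_pkg) <= res.fun + 1e-6
            np.testing.assert_allclose(x_pkg, res.x, atol=1e-3)

    def test_non_convergence_raises_with_last_iterate(self):
        with pytest.raises(tm.EstimationError) as exc:
            tm.bayes_modal([1], [rasch_item(0.0)], tm.expand_prior(np.eye(1)), max_iter=1)
        assert exc.value.last_iterate.shape == (1,)


class TestConjugateBlocks:
    """With latents held fixed the Gibbs draws must match the closed-form
    conjugate posteriors (inverse-Wishart for the ability covariance,
    inverse-Gamma for each testlet variance)."""

    @pytest.fixture()
    def tiny_state(self, small_pool):
        rng = np.random.default_rng(8)
        u = rng.integers(0, 2, (40, len(small_pool))).astype(float)
        data = tm.ResponseSet.full_matrix(u, small_pool)
        return _GibbsState(data, PriorSpec(), "MTIRT", np.random.default_rng(12))

    def test_phi_block_matches_inverse_wishart_moments(self, tiny_state):
        rng = np.random.default_rng(4)
        theta_fixed = rng.normal(size=(40, 3))
        tiny_state.theta = theta_fixed
        df, scale = phi_conditional_params(theta_fixed, tiny_state.prior)
        analytic_mean = scale / (df - 3 - 1)
        draws = []
        for _ in range(3000):
            tiny_state.update_phi()
            draws.append(tiny_state.phi.copy())
            tiny_state.theta = theta_fixed  # keep the conditional fixed
        draws = np.asarray(draws)
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        np.testing.assert_array_less(
            np.abs(draws.mean(axis=0) - analytic_mean), 3 * mc_se + 1e-12
        )
        # cross-check against scipy's own mean
        np.testing.assert_allclose(
            analytic_mean, invwishart.mean(df=df, scale=scale), atol=1e-12
        )

    def test_sigma2_block_matches_inverse_gamma_moments(self, tiny_state):
        rng = np.random.default_rng(14)
        gamma_fixed = rng.normal(scale=0.8, size=tiny_state.gamma.shape)
        tiny_state.gamma = gamma_fixed
        d = 0  # first testlet
        vals = gamma_fixed[:, 0]
        a_post, scale_post = sigma2_conditional_params(vals, tiny_state.prior)
        analytic_mean = invgamma.mean(a_post, scale=scale_post)
        draws = []
        for _ in range(4000):
            tiny_state.update_sigma2()
            draws.append(tiny_state.sigma2[d])
            tiny_state.gamma = gamma_fixed
        draws = np.asarray(draws)
        mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - analytic_mean) < 3 * mc_se


class TestGeweke:
    def test_stationary_series_scores_small(self):
        rng = np.random.default_rng(0)
        zs = [tm.geweke_z(rng.normal(size=2000)) for _ in range(20)]
        assert np.mean(np.abs(np.asarray(zs)) < 1.96) >= 0.9

    def test_drifting_series_scores_large(self):
        x = np.concatenate([np.zeros(500), np.ones(1500)]) + 0.1 * np.random.default_rng(1).normal(size=2000)
        assert abs(tm.geweke_z(x)) > 5


class TestMCMCScale:
    def test_uninformative_items_leave_prior_intact(self):
        # all-zero loadings carry no information: the theta posterior is the
        # (fixed) prior, so EAPs sit near 0 with posterior sd near 1
        with pytest.warns(UserWarning, match="all-zero loading"):
            items = [
                tm.Item(id=f"i{k}", a=np.zeros(3), b=0.0, testlet_id=f"t{k}")
                for k in range(4)
            ]
        pool = tm.ItemPool(items)
        rng = np.random.default_rng(2)
        u = rng.integers(0, 2, (150, 4)).astype(float)
        data = tm.ResponseSet.full_matrix(u, pool)
        prior = PriorSpec(estimate_phi=False, phi_fixed=np.eye(3))
        chain = ChainConfig(min_burn_in=300, burn_in_cap=1200, check_interval=300,
                            retain=400, theta_scale=1.0)
        eap, _ = tm.mcmc_scale(data, prior, chain, model="MIRT", rng=np.random.default_rng(3))
        assert abs(eap.theta.mean()) < 0.1
        assert eap.theta.std() < 0.25  # EAP of a pure prior concentrates at its mean
        assert eap.theta_sd.mean() == pytest.approx(1.0, abs=0.1)

    def test_trace_export_is_tidy(self, small_pool, tmp_path):
        rng = np.random.default_rng(6)
        u = rng.integers(0, 2, (30, len(small_pool))).astype(float)
        data = tm.ResponseSet.full_matrix(u, small_pool)
        chain = ChainConfig(min_burn_in=200, burn_in_cap=400, check_interval=200,
                            retain=100, monitor_min_exposure=1)
        out = tmp_path / "trace.csv"
        with pytest.warns(UserWarning, match="burn-in cap"):
            tm.mcmc_scale(data, chain=chain, rng=np.random.default_rng(1),
                          trace_path=str(out))
        import pandas as pd

        tidy = pd.read_csv(out)
        assert list(tidy.columns) == ["iteration", "parameter", "value"]
        params = set(tidy["parameter"])
        assert any(p.startswith("sigma2[") for p in params)
        assert any(p.startswith("phi[") for p in params)
        assert tidy["iteration"].max() == 499

    def test_zero_variance_data_recovers_near_zero(self, pool3):
        rng = np.random.default_rng(23)
        N = 250
        theta = tm.generate_abilities(N, tm.STUDY_PHI, rng)
        gamma = tm.generate_testlet_effects(N, pool3.n_testlets, 0.0, rng)
        variances = {t: 0.0 for t in pool3.testlet_ids}
        cfg = tm.CATConfig(selection="RAN")
        records = [
            tm.administer(
                (theta[j], dict(zip(pool3.testlet_ids, gamma[j]))),
                pool3, cfg, tm.STUDY_PHI, variances, rng,
            )
            for j in range(N)
        ]
        data = tm.build_response_set(records, pool3)
        chain = ChainConfig(min_burn_in=600, burn_in_cap=2000, check_interval=400, retain=300)
        eap, _ = tm.mcmc_scale(data, chain=chain, rng=np.random.default_rng(5))
        # at ~40 persons per testlet and 3 items per effect, the posterior
        # for a zero variance retains visible small-sample mass above zero;
        # this sanity bound shrinks with exposure (study-scale runs sit
        # below 0.1)
        assert eap.mean_sigma2(min_exposure=10) < 0.35

    def test_mirt_and_mtirt_agree_without_testlet_effects(self, pool3):
        # on locally independent data the over-specified testlet model must
        # not cost measurable precision
        rng = np.random.default_rng(29)
        N = 250
        theta = tm.generate_abilities(N, tm.STUDY_PHI, rng)
        gamma = np.zeros((N, pool3.n_testlets))
        variances = {t: 0.0 for t in pool3.testlet_ids}
        records = {}
        for model in ("MTIRT", "MIRT"):
            rng_m = np.random.default_rng(31)
            cfg = tm.CATConfig(selection="RAN", model=model)
            records[model] = [
                tm.administer(
                    (theta[j], dict(zip(pool3.testlet_ids, gamma[j]))),
                    pool3, cfg, tm.STUDY_PHI, variances, rng_m,
                )
                for j in range(N)
            ]
        chain = ChainConfig(min_burn_in=600, burn_in_cap=2000, check_interval=400, retain=300)
        mses = {}
        for model in ("MTIRT", "MIRT"):
            data = tm.build_response_set(records[model], pool3)
            eap, _ = tm.mcmc_scale(data, chain=chain, model=model, rng=np.random.default_rng(7))
            mses[model], _ = tm.compute_mse(eap.theta, theta)
        assert mses["MTIRT"] == pytest.approx(mses["MIRT"], abs=0.03)


class TestMMLCalibration:
    def test_symmetric_item_calibrates_to_zero(self):
        rng = np.random.default_rng(41)
        items = [rasch_item(0.0, iid=f"i{k}", testlet=f"t{k}") for k in range(3)]
        pool = tm.ItemPool(items)
        theta = rng.normal(size=(4000, 1))
        p = expit(theta - 0.0)
        u = (rng.random((4000, 3)) < p).astype(float)
        b_hat, flagged = tm.mml_calibrate_difficulties(u, pool)
        assert not flagged.any()
        np.testing.assert_allclose(b_hat, 0.0, atol=0.08)

    def test_recovery_under_locally_independent_data(self):
        # mean absolute error < 0.08 at N=5000 over b in (-3, 3)
        rng = np.random.default_rng(43)
        gp = tm.GeneratedPool(rng.uniform(-3, 3, size=(3, 36)))
        pool = gp.pool(3)
        theta = tm.generate_abilities(5000, tm.STUDY_PHI, rng)
        gamma = np.zeros((5000, pool.n_testlets))
        u = tm.simulate_responses(theta, gamma, pool, rng)
        b_hat, flagged = tm.mml_calibrate_difficulties(u, pool)
        assert not flagged.any()
        assert np.mean(np.abs(b_hat - pool.b)) < 0.08

    def test_degenerate_items_flagged_at_boundary(self, small_pool):
        u = np.ones((50, len(small_pool)))
        u[:, 0] = 0.0
        b_hat, flagged = tm.mml_calibrate_difficulties(u, small_pool)
        assert flagged[0] and b_hat[0] == 8.0
        assert flagged[1:].all() and np.all(b_hat[1:] == -8.0)

    def test_guessing_items_rejected(self):
        item = tm.Item(id="g", a=np.array([1.0]), b=0.0, c=0.2, testlet_id="t")
        pool = tm.ItemPool([item])
        with pytest.raises(ValueError, match="zero"):
            tm.mml_calibrate_difficulties(np.ones((10, 1)), pool)
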