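import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from dsemcfa import ModelSpec, default_priors, joint_logposterior, within_marginal_loglik
from dsemcfa.model_core import ModelParams, PriorSpec, log_prior
from dsemcfa.synthetic_data import NonstationaryError, PersonRandomEffects


def toy_params(lam_w, th_w, lam_b=None, th_b=None, nu=None):
    k = len(lam_w)
    return ModelParams(
        lam_w=np.asarray(lam_w, float),
        lam_b=np.ones(k) if lam_b is None else np.asarray(lam_b, float),
        nu=np.zeros(k) if nu is None else np.asarray(nu, float),
        th_w=np.asarray(th_w, float),
        th_b=0.2 * np.ones(k) if th_b is None else np.asarray(th_b, float),
        gamma=np.array([0.0, 0.4, -1.0]),
        Sigma_b=np.diag([0.25, 0.05, 0.5]),
    )


def joint_covariance(lam_w, th_w, phi, sigma2, T):
    """Brute-force oracle: the TK x TK covariance of the within data with
    the AR(1) latent states marginalized analytically."""
    lags = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    acov = sigma2 / (1 - phi**2) * phi**lags
    return np.kron(acov, np.outer(lam_w, lam_w)) + np.kron(np.eye(T), np.diag(th_w))


class TestWithinMarginalLoglik:
    def test_single_occasion_closed_form(self):
        """T=1, K=1: the density is N(0, sigma2/(1-phi^2) + theta_w)."""
        params = toy_params([1.0], [0.4])
        re = PersonRandomEffects("p", eta_b=0.3, phi=0.6, log_innovation_var=np.log(0.5))
        y = np.array([[1.7]])
        got = within_marginal_loglik(y, params, re)
        var = 0.5 / (1 - 0.36) + 0.4
        centered = 1.7 - (0.0 + 1.0 * 0.3)  # nu + lam_b * eta_b
        want = -0.5 * (np.log(2 * np.pi * var) + centered**2 / var)
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_joint_covariance_oracle(self):
        """T=5, K=3 fixed instance: the filter equals the explicit
        15-dimensional marginalized normal to 1e-8."""
        rng = np.random.default_rng(5)
        lam_w = np.array([1.0, 0.8, 1.2])
        th_w = np.array([0.3, 0.5, 0.4])
        params = toy_params(lam_w, th_w, lam_b=[1.0, 0.9, 1.1], nu=[0.5, 1.0, -0.2])
        re = PersonRandomEffects("p", 0.3, 0.6, np.log(0.5))
        y = rng.normal(size=(5, 3)) + 1.0
        got = within_marginal_loglik(y, params, re)
        cov = joint_covariance(lam_w, th_w, 0.6, 0.5, 5)
        mean = np.tile(params.nu + params.lam_b * 0.3, 5)
        want = multivariate_normal.logpdf(y.ravel(), mean=mean, cov=cov)
        assert got == pytest.approx(want, abs=1e-8)

    def test_missing_cells_drop_rows_of_joint_covariance(self):
        rng = np.random.default_rng(6)
        lam_w = np.array([1.0, 0.8, 1.2])
        th_w = np.array([0.3, 0.5, 0.4])
        params = toy_params(lam_w, th_w)
        re = PersonRandomEffects("p", 0.0, 0.5, np.log(0.3))
        y = rng.normal(size=(5, 3))
        y[1, 2] = np.nan
        y[3, 0] = np.nan
        y[4, :] = np.nan  # a fully missing occasion: state propagates only
        got = within_marginal_loglik(y, params, re)
        cov = joint_covariance(lam_w, th_w, 0.5, 0.3, 5)
        keep = ~np.isnan(y.ravel())
        want = multivariate_normal.logpdf(
            y.ravel()[keep], mean=np.zeros(keep.sum()), cov=cov[np.ix_(keep, keep)]
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_independence_limit_phi_zero(self):
        """phi=0: occasions are independent factor-analysis densities."""
        rng = np.random.default_rng(7)
        lam_w = np.array([1.0, 0.7])
        th_w = np.array([0.2, 0.6])
        params = toy_params(lam_w, th_w)
        re = PersonRandomEffects("p", 0.0, 0.0, np.log(0.8))
        y = rng.normal(size=(6, 2))
        got = within_marginal_loglik(y, params, re)
        per_occ_cov = 0.8 * np.outer(lam_w, lam_w) + np.diag(th_w)
        want = sum(multivariate_normal.logpdf(y[t], mean=np.zeros(2), cov=per_occ_cov) for t in range(6))
        assert got == pytest.approx(want, abs=1e-9)

    def test_item_permutation_invariance(self):
        rng = np.random.default_rng(8)
        lam_w = np.array([1.0, 0.8, 1.3])
        th_w = np.array([0.3, 0.5, 0.2])
        params = toy_params(lam_w, th_w, lam_b=[1.0, 0.8, 1.2], nu=[0.1, 0.2, 0.3])
        re = PersonRandomEffects("p", 0.2, 0.4, np.log(0.4))
        y = rng.normal(size=(4, 3))
        base = within_marginal_loglik(y, params, re)
        for perm in itertools.permutations(range(3)):
            p2 = toy_params(
                lam_w[list(perm)], th_w[list(perm)],
                lam_b=params.lam_b[list(perm)], nu=params.nu[list(perm)],
            )
            assert within_marginal_loglik(y[:, perm], p2, re) == pytest.approx(base, abs=1e-10)

    def test_nonstationary_error(self):
        params = toy_params([1.0], [0.4])
        with pytest.raises(NonstationaryError):
            within_marginal_loglik(
                np.array([[0.0]]), params, PersonRandomEffects("p", 0, 1.0, 0.0)
            )


class TestJointLogposterior:
    @pytest.fixture()
    def tiny_instance(self, default_params):
        from dsemcfa import simulate_panel
        from dsemcfa.synthetic_data import TrueParameters

        ids = ("item_1", "item_2")
        p = TrueParameters(
            item_ids=ids,
            loadings_within={"item_1": 1.0, "item_2": 0.8},
            loadings_between={"item_1": 1.0, "item_2": 1.1},
            intercepts={"item_1": 0.2, "item_2": -0.1},
            resid_var_within={i: 0.4 for i in ids},
            resid_var_between={i: 0.2 for i in ids},
            gamma=np.array([0.0, 0.4, -1.0]),
            Sigma_b=np.diag([0.3, 0.05, 0.4]),
        )
        data, res, _ = simulate_panel(p, n=2, length_distribution=3, seed=0)
        spec = ModelSpec(item_ids=list(ids), anchor_item="item_1")
        params = ModelParams.from_true(p)
        return data, res, spec, params

    def test_prior_separates_from_likelihood(self, tiny_instance):
        """Scaling prior variances changes only the prior term."""
        data, res, spec, params = tiny_instance
        lp1 = joint_logposterior(params, res, data, spec)
        wide = ModelSpec(
            item_ids=spec.item_ids,
            anchor_item=spec.anchor_item,
            priors=PriorSpec(
                loading_intercept_prior=(0.0, 2.0e6),
                fixed_effect_prior=(0.0, 2.0e6),
            ),
        )
        lp2 = joint_logposterior(params, res, data, wide)
        delta = lp2 - lp1
        want = log_prior(params, wide) - log_prior(params, spec)
        assert delta == pytest.approx(want, abs=1e-9)

    def test_flat_between_limit(self, tiny_instance):
        """theta_b -> large: the between measurement term becomes flat in
        eta_b (the likelihood part no longer distinguishes trait values)."""
        data, res, spec, params = tiny_instance
        big = ModelParams(
            lam_w=params.lam_w, lam_b=params.lam_b, nu=params.nu,
            th_w=params.th_w, th_b=params.th_b * 1e8,
            gamma=params.gamma, Sigma_b=params.Sigma_b,
        )
        b_scores = params.nu[None, :] + params.lam_b[None, :] * np.array([r.eta_b for r in res])[:, None]
        import dataclasses as dc

        res_shift = [dc.replace(res[0], eta_b=res[0].eta_b + 1.0), res[1]]
        lp_a = joint_logposterior(big, res, data, spec, between_scores=b_scores)
        lp_b = joint_logposterior(big, res_shift, data, spec, between_scores=b_scores)
        # remaining variation comes only from the random-effect density
        from scipy.stats import multivariate_normal as mvn

        u_a = np.array([res[0].eta_b, res[0].phi, res[0].log_innovation_var])
        u_b = u_a + np.array([1.0, 0, 0])
        re_term = mvn.logpdf(u_b, mean=params.gamma, cov=params.Sigma_b) - mvn.logpdf(
            u_a, mean=params.gamma, cov=params.Sigma_b
        )
        assert (lp_b - lp_a) == pytest.approx(re_term, abs=1e-4)

    def test_non_positive_definite_sigma_is_rejected_state(self, tiny_instance):
        data, res, spec, params = tiny_instance
        bad = ModelParams(
            lam_w=params.lam_w, lam_b=params.lam_b, nu=params.nu,
            th_w=params.th_w, th_b=params.th_b,
            gamma=params.gamma,
            Sigma_b=np.array([[1.0, 2.0, 0], [2.0, 1.0, 0], [0, 0, 1.0]]),
        )
        assert joint_logposterior(bad, res, data, spec) == -np.inf

    def test_quadrature_oracle(self, tiny_instance):
        """2 persons, T=3, K=2: the state-marginalized within term agrees
        with high-order Gauss-Hermite quadrature over the latent states."""
        data, res, spec, params = tiny_instance
        arrays = data.to_arrays()
        nodes, weights = np.polynomial.hermite_e.hermegauss(24)
        total_filter = 0.0
        total_quad = 0.0
        for i, re in enumerate(res):
            t_i = int(arrays.lengths[i])
            y = arrays.y[i, :t_i]
            total_filter += within_marginal_loglik(y, params, re)
            # AR(1) prior covariance of the states
            s2 = np.exp(re.log_innovation_var)
            lags = np.abs(np.subtract.outer(np.arange(t_i), np.arange(t_i)))
            acov = s2 / (1 - re.phi**2) * re.phi**lags
            chol = np.linalg.cholesky(acov)
            b = params.nu + params.lam_b * re.eta_b
            grid = np.array(list(itertools.product(nodes, repeat=t_i))).T
            w = np.prod(
                np.array(list(itertools.product(weights, repeat=t_i))), axis=1
            ) / np.sqrt(2 * np.pi) ** t_i
            eta = chol @ grid  # (t_i, M)
            resid = y[:, :, None] - b[None, :, None] - params.lam_w[None, :, None] * eta[:, None, :]
            ll = -0.5 * np.sum(
                np.log(2 * np.pi * params.th_w)[None, :, None] + resid**2 / params.th_w[None, :, None],
                axis=(0, 1),
            )
            m = ll.max()
            total_quad += m + np.log(np.sum(w * np.exp(ll - m)))
        assert total_filter == pytest.approx(total_quad, abs=1e-4)


class TestDefaultPriors:
    def test_diffuseness_and_propriety(self):
        spec = ModelSpec(item_ids=["item_1", "item_2"], anchor_item="item_1")
        pr = default_priors(spec)
        assert pr.loading_intercept_prior[1] >= 1e4
        shape, scale = pr.resid_var_prior
        assert scale / (shape + 1) > 0  # inverse-gamma mode is positive

    def test_inverse_wishart_mean_identity(self):
        """With an explicit IW(scale, dim + 2) the prior mean of Sigma_b
        equals the scale matrix (IW mean = scale / (df - dim - 1)); checked
        against Monte Carlo draws."""
        scale, df = 0.5 * np.eye(3), 5.0
        pr = PriorSpec(ranef_cov_prior=(scale, df))
        assert not pr.uses_huang_wand
        dim = scale.shape[0]
        assert df == dim + 2
        np.testing.assert_allclose(scale / (df - dim - 1), scale)
        # first moment only: the IW variance is infinite at df = dim + 2,
        # so a sample-mean Monte Carlo check would not converge

    def test_huang_wand_option_half_t_sds(self):
        """The default Huang-Wand covariance hierarchy gives each implied
        standard deviation a marginal half-t(nu) with scale A (checked by
        simulating the IG-IW mixture against half-t draws)."""
        spec = ModelSpec(item_ids=["item_1", "item_2"], anchor_item="item_1")
        pr = default_priors(spec)
        assert pr.uses_huang_wand
        rng = np.random.default_rng(1)
        nu, big_a, p = pr.huang_wand_nu, pr.huang_wand_scale, 3
        n_draw = 30_000
        a = (1.0 / big_a**2) / rng.gamma(0.5, 1.0, size=(n_draw, p))
        from scipy.stats import invwishart, t as student_t

        sds = np.empty(n_draw)
        for i in range(n_draw):
            sig = invwishart.rvs(df=nu + p - 1, scale=2 * nu * np.diag(1 / a[i]), random_state=rng)
            sds[i] = np.sqrt(sig[0, 0])
        ref = np.abs(student_t.rvs(df=nu, scale=big_a, size=n_draw, random_state=rng))
        # compare tail-robust quantiles of the two SD distributions
        for q in (25, 50, 75):
            assert np.percentile(sds, q) == pytest.approx(np.percentile(ref, q), rel=0.05)

    def test_df_floor_enforced(self):
        with pytest.raises(ValueError):
            PriorSpec(ranef_cov_prior=(np.eye(3), 3.0))
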