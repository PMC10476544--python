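import numpy as np
import pytest

from dsemcfa import (
    default_true_parameters,
    draw_random_effects,
    simulate_latent_series,
    simulate_panel,
)
from dsemcfa.psychometrics import analytic_icc
from dsemcfa.synthetic_data import (
    NonstationaryError,
    ParameterError,
    PersonRandomEffects,
    TrueParameters,
    population_within_variance,
)


def _flat_params(gamma, Sigma_b, beta=None, k=3):
    ids = tuple(f"item_{j}" for j in range(1, k + 1))
    return TrueParameters(
        item_ids=ids,
        loadings_within={i: 1.0 for i in ids},
        loadings_between={i: 1.0 for i in ids},
        intercepts={i: 0.0 for i in ids},
        resid_var_within={i: 0.3 for i in ids},
        resid_var_between={i: 0.1 for i in ids},
        gamma=gamma,
        Sigma_b=Sigma_b,
        beta=beta or {},
    )


class TestDrawRandomEffects:
    def test_degenerate_covariance_returns_means(self):
        p = _flat_params(np.array([0.0, 0.3, -1.0]), np.zeros((3, 3)))
        res = draw_random_effects(5, p, seed=0)
        for re in res:
            assert (re.eta_b, re.phi, re.log_innovation_var) == (0.0, 0.3, -1.0)

    def test_monte_carlo_moments(self):
        """At n=50,000 the sample mean and variance of the carryover draws
        match the |phi| < 1 truncated normal implied by N(0.45, 0.07),
        within Monte Carlo error (the upper tail holds ~2% mass, so the
        truncation visibly trims the mean)."""
        from scipy.stats import truncnorm

        p = _flat_params(np.array([0.0, 0.45, -3.0]), np.diag([0.25, 0.07, 1.0]))
        res = draw_random_effects(50_000, p, seed=1)
        phi = np.array([r.phi for r in res])
        sd = np.sqrt(0.07)
        a, b = (-1 - 0.45) / sd, (1 - 0.45) / sd
        want_mean = truncnorm.mean(a, b, loc=0.45, scale=sd)
        want_var = truncnorm.var(a, b, loc=0.45, scale=sd)
        assert abs(phi.mean() - want_mean) < abs(want_mean) * 0.01
        assert abs(phi.var() - want_var) < want_var * 0.03

    def test_covariate_shifts_group_mean(self):
        """A male dummy with beta_phi = 0.1 shifts the male group's mean
        carryover by ~0.1."""
        p = _flat_params(
            np.array([0.0, 0.3, -3.0]),
            np.diag([0.25, 0.05, 1.0]),
            beta={"male": np.array([0.0, 0.1, 0.0])},
        )
        cov = {i: {"male": 1.0 if i < 20_000 else 0.0} for i in range(40_000)}
        res = draw_random_effects(40_000, p, covariates=cov, seed=2)
        phi = np.array([r.phi for r in res])
        assert abs(phi[:20_000].mean() - 0.4) < 0.01
        assert abs(phi[20_000:].mean() - 0.3) < 0.01

    def test_stationarity_rejection(self):
        """Draws with |phi| >= 1 are redrawn; every returned person is
        stationary and the rejection count is reported."""
        p = _flat_params(np.array([0.0, 0.9, -1.0]), np.diag([0.1, 0.3, 0.1]))
        res, rejections = draw_random_effects(5000, p, seed=3, return_rejections=True)
        assert all(abs(r.phi) < 1 for r in res)
        assert rejections > 0

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ParameterError):
            _flat_params(np.zeros(3), np.array([[1, 2, 0], [2, 1, 0], [0, 0, 1.0]]))


class TestLatentSeries:
    def test_white_noise_limit(self):
        re = PersonRandomEffects("p", 0.0, 0.0, np.log(1.0))
        traj = simulate_latent_series(re, 200_000, seed=0)
        e = traj.eta_w
        r1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert abs(r1) < 0.01
        assert abs(e.var() - 1.0) < 0.02

    def test_stationary_variance_closed_form(self):
        """phi=0.5, sigma2=1: long-run variance matches 1/(1-0.25)."""
        re = PersonRandomEffects("p", 0.0, 0.5, 0.0)
        traj = simulate_latent_series(re, 1_000_000, seed=1)
        assert abs(traj.eta_w.var() - 4.0 / 3.0) < 4.0 / 3.0 * 0.01

    def test_study_carryover_recovered_as_autocorrelation(self):
        """The clinic study's carryover point value (0.454) fed to the
        simulator reappears as the series' lag-1 autocorrelation."""
        re = PersonRandomEffects("p", 0.0, 0.454, np.log(0.5))
        traj = simulate_latent_series(re, 500_000, seed=2)
        e = traj.eta_w
        r1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert abs(r1 - 0.454) < 0.01

    def test_recursion_invariant(self):
        re = PersonRandomEffects("p", 0.0, 0.7, np.log(0.2))
        traj = simulate_latent_series(re, 50, seed=3)
        np.testing.assert_allclose(
            traj.eta_w[1:], 0.7 * traj.eta_w[:-1] + traj.innovations[1:], rtol=1e-12
        )

    def test_nonstationary_rejected(self):
        with pytest.raises(NonstationaryError):
            simulate_latent_series(PersonRandomEffects("p", 0, 1.01, 0.0), 10)


class TestSimulatePanel:
    def test_noise_free_measurement(self):
        """With zero residual variance, unit loadings and no person
        heterogeneity, each response equals nu_k + eta_w exactly."""
        ids = ("item_1", "item_2")
        p = TrueParameters(
            item_ids=ids,
            loadings_within={i: 1.0 for i in ids},
            loadings_between={i: 1.0 for i in ids},
            intercepts={"item_1": 0.5, "item_2": -0.5},
            resid_var_within={i: 0.0 for i in ids},
            resid_var_between={i: 0.0 for i in ids},
            gamma=np.array([0.0, 0.0, 0.0]),
            Sigma_b=np.zeros((3, 3)),
        )
        data, res, traj = simulate_panel(p, n=4, length_distribution=6, seed=0)
        y = data.frame[list(ids)].to_numpy()
        eta = np.concatenate([t.eta_w for t in traj])
        np.testing.assert_allclose(y[:, 0], 0.5 + eta, atol=1e-12)
        np.testing.assert_allclose(y[:, 1], -0.5 + eta, atol=1e-12)

    def test_seed_determinism(self, default_params):
        a, _, _ = simulate_panel(default_params, n=20, seed=9)
        b, _, _ = simulate_panel(default_params, n=20, seed=9)
        assert a.frame.equals(b.frame)

    def test_random_effect_covariance_converges(self):
        """Empirical covariance of simulated person triples approaches
        Sigma_b (2% tolerance at n=1e5).  Carryover spread is kept small
        enough that the |phi| < 1 truncation is immaterial; the default
        study truth's wider spread is covered by the truncated-moment
        check above."""
        sd = np.sqrt([0.25, 0.01, 1.0])
        corr = np.array([[1, 0.4, 0.6], [0.4, 1, 0.25], [0.6, 0.25, 1]])
        p = _flat_params(np.array([0.0, 0.45, -3.0]), corr * np.outer(sd, sd))
        res = draw_random_effects(100_000, p, seed=4)
        u = np.array([[r.eta_b, r.phi, r.log_innovation_var] for r in res])
        emp = np.cov(u.T)
        scale = np.sqrt(np.outer(np.diag(p.Sigma_b), np.diag(p.Sigma_b)))
        assert np.all(np.abs(emp - p.Sigma_b) / scale < 0.02)

    def test_empirical_between_fraction_matches_analytic_icc(self, default_params):
        """Variance decomposition of a large simulated panel agrees with the
        analytic ICC computed from the generative parameters."""
        data, _, _ = simulate_panel(default_params, n=1500, length_distribution=30, seed=6)
        item = "item_1"
        frame = data.frame
        grand = frame[item].to_numpy()
        person_means = frame.groupby("person_id")[item].transform("mean").to_numpy()
        between = person_means.var()
        within = (grand - person_means).var()
        # person means carry ~1/T of the within variance; correct the split
        t_bar = frame.groupby("person_id")[item].count().mean()
        between_adj = between - within / (t_bar - 1)
        icc_emp = between_adj / (between_adj + within)
        icc_true = analytic_icc(default_params, item)
        assert abs(icc_emp - icc_true) < 0.04

    def test_missing_rate_bounds(self, default_params):
        with pytest.raises(ParameterError):
            simulate_panel(default_params, n=3, missing_rate=1.0, seed=0)


def test_population_within_variance_quadrature_matches_monte_carlo(default_params):
    """Gauss-Hermite value of E[sigma2/(1-phi^2)] agrees with brute-force
    Monte Carlo over the truncated random-effect law."""
    res = draw_random_effects(400_000, default_params, seed=8)
    mc = np.mean(
        [np.exp(r.log_innovation_var) / (1 - r.phi**2) for r in res]
    )
    quad = population_within_variance(default_params)
    assert abs(quad - mc) / mc < 0.02


def test_default_fixture_reliability_ranges(default_params):
    """Default measurement truth lands in the study-like reliability ranges:
    within R^2 0.2-0.4, between R^2 0.45-0.85."""
    from dsemcfa.psychometrics import analytic_r2

    for item in default_params.item_ids:
        r2_b, r2_w = analytic_r2(default_params, item)
        assert 0.15 <= r2_w <= 0.45
        assert 0.4 <= r2_b <= 0.9
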