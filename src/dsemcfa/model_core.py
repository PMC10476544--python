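"""Probability model for the two-level dynamic-factor CFA.

The observed K-vector at occasion t, given the person's between item
scores b_ik (trait part plus person-item residual), loads on a scalar
latent AR(1) state:

    y_it | eta_w_it ~ N(b_i + lam_w * eta_w_it, diag(theta_w))
    eta_w_it = phi_i eta_w_i,t-1 + zeta_it,  zeta_it ~ N(0, sigma2_i)
    b_ik ~ N(nu_k + lam_b_k * eta_b_i, theta_b_k)
    (eta_b_i, phi_i, log sigma2_i) ~ N(gamma + beta' x_i, Sigma_b)

``within_marginal_loglik`` integrates the latent states out analytically
with a scalar-state Kalman filter (rank-one observation updates via the
matrix-determinant lemma), skipping missing cells; it is both the
sampler's Metropolis target for the dynamic random effects and the
quantity checked against a brute-force joint-covariance oracle in the
tests.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .synthetic_data import NonstationaryError, PersonRandomEffects, TrueParameters

LOG2PI = math.log(2.0 * math.pi)


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Proper diffuse priors.

    Normal priors on loadings/intercepts and on fixed effects
    (mean, variance); inverse-gamma (shape, scale) on residual variances.

    The 3x3 random-effect covariance defaults to the Huang-Wand
    hierarchy ("huang-wand": an inverse-Wishart mixed over per-dimension
    inverse-gamma scales), giving each random-effect SD a heavy-tailed
    half-t(2) marginal and each correlation a near-uniform one.  The
    three variance components span two orders of magnitude (trait ~0.25,
    carryover ~0.07, log innovation variance ~1-2), and no fixed
    inverse-Wishart scale matrix is weakly informative for all of them
    at once: an identity scale measurably inflates the small components
    at realistic sample sizes, while a near-zero scale favors singular
    corners.  A fixed inverse-Wishart (scale matrix, df) may be supplied
    instead.
    """

    loading_intercept_prior: tuple[float, float] = (0.0, 1.0e6)
    fixed_effect_prior: tuple[float, float] = (0.0, 1.0e6)
    resid_var_prior: tuple[float, float] = (0.001, 0.001)
    ranef_cov_prior: tuple[np.ndarray, float] | str = "huang-wand"
    huang_wand_scale: float = 10.0  # half-t scale A on each random-effect SD
    huang_wand_nu: float = 2.0  # half-t degrees of freedom

    def __post_init__(self):
        if self.loading_intercept_prior[1] <= 0 or self.fixed_effect_prior[1] <= 0:
            raise ValueError("prior variances must be > 0")
        if not self.uses_huang_wand:
            scale, df = self.ranef_cov_prior
            if df < np.asarray(scale).shape[0] + 1:
                raise ValueError("inverse-Wishart df must be >= dimension + 1")

    @property
    def uses_huang_wand(self) -> bool:
        return isinstance(self.ranef_cov_prior, str)


@dataclasses.dataclass
class ModelSpec:
    """What to fit: items, the fixed-to-1 anchor, optional covariates."""

    item_ids: list[str]
    anchor_item: str
    covariate_ids: list[str] = dataclasses.field(default_factory=list)
    priors: PriorSpec = dataclasses.field(default_factory=PriorSpec)

    def __post_init__(self):
        if self.anchor_item not in self.item_ids:
            raise ValueError(f"anchor {self.anchor_item!r} not among items")

    @property
    def anchor_index(self) -> int:
        return self.item_ids.index(self.anchor_item)


def default_priors(spec: ModelSpec) -> PriorSpec:
    """Documented diffuse defaults: N(0, 1e6) on loadings/intercepts and
    fixed effects, IG(0.001, 0.001) on residual variances, and the
    Huang-Wand hierarchy (half-t(2, scale 10) SDs, near-uniform
    correlations) on the random-effect covariance."""
    return PriorSpec()


@dataclasses.dataclass
class ModelParams:
    """One point in parameter space (arrays ordered by spec.item_ids)."""

    lam_w: np.ndarray
    lam_b: np.ndarray
    nu: np.ndarray
    th_w: np.ndarray
    th_b: np.ndarray
    gamma: np.ndarray  # (3,): means of (eta_b, phi, log sigma2); [0] fixed at 0
    Sigma_b: np.ndarray  # (3, 3)
    beta: np.ndarray | None = None  # (p, 3) covariate effects

    def __post_init__(self):
        for name in ("lam_w", "lam_b", "nu", "th_w", "th_b", "gamma", "Sigma_b"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.beta is not None:
            self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))

    @classmethod
    def from_true(cls, params: TrueParameters, covariate_ids: Sequence[str] = ()) -> "ModelParams":
        arr = params.arrays()
        beta = None
        if covariate_ids:
            beta = np.array([params.beta[c] for c in covariate_ids])
        return cls(
            lam_w=arr["lam_w"],
            lam_b=arr["lam_b"],
            nu=arr["nu"],
            th_w=arr["th_w"],
            th_b=arr["th_b"],
            gamma=params.gamma.copy(),
            Sigma_b=params.Sigma_b.copy(),
            beta=beta,
        )

    def ranef_mean(self, x: np.ndarray | None) -> np.ndarray:
        """Mean of the random-effect triple given covariate row(s) x."""
        if x is None or self.beta is None or self.beta.size == 0:
            return self.gamma
        return self.gamma + np.atleast_2d(x) @ self.beta


def within_marginal_loglik(
    y: np.ndarray,
    params: ModelParams,
    re: PersonRandomEffects,
    between_scores: np.ndarray | None = None,
) -> float:
    """Log density of one person's data with latent states marginalized.

    ``y`` is (T, K) with NaN for missing cells.  ``between_scores`` are
    the person's item-level means b_ik; by default the person-item
    residuals are taken as zero, i.e. b = nu + lam_b * eta_b.  The state
    is initialized at its stationary law, which requires |phi| < 1.
    """
    phi = float(re.phi)
    if abs(phi) >= 1.0:
        raise NonstationaryError("|phi| >= 1: stationary initial variance undefined")
    sigma2 = math.exp(float(re.log_innovation_var))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    if between_scores is None:
        between_scores = params.nu + params.lam_b * float(re.eta_b)
    resid = y - np.asarray(between_scores, dtype=float)[None, :]

    lam, th = params.lam_w, params.th_w
    a, big_r = 0.0, sigma2 / (1.0 - phi * phi)
    ll = 0.0
    for t in range(resid.shape[0]):
        obs = ~np.isnan(resid[t])
        if obs.any():
            e = resid[t, obs] - lam[obs] * a
            inv_th = 1.0 / th[obs]
            p = float(np.sum(lam[obs] ** 2 * inv_th))  # information about the state
            s = float(np.sum(lam[obs] * inv_th * e))
            quad = float(np.sum(e * e * inv_th)) - big_r * s * s / (1.0 + big_r * p)
            ll -= 0.5 * (
                obs.sum() * LOG2PI + float(np.sum(np.log(th[obs]))) + math.log1p(big_r * p) + quad
            )
            v = big_r / (1.0 + big_r * p)
            m = a + v * s
        else:
            v, m = big_r, a
        a = phi * m
        big_r = phi * phi * v + sigma2
    return float(ll)


def _normal_logpdf(x: np.ndarray, mean: float, var: float) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return float(-0.5 * np.sum(LOG2PI + math.log(var) + (x - mean) ** 2 / var))


def _invgamma_logpdf(x: np.ndarray, shape: float, scale: float) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        return -np.inf
    return float(np.sum(shape * math.log(scale) - math.lgamma(shape) - (shape + 1) * np.log(x) - scale / x))


def log_prior(params: ModelParams, spec: ModelSpec) -> float:
    """Sum of prior log densities at ``params`` under ``spec.priors``."""
    pr = spec.priors
    a_idx = spec.anchor_index
    free = np.ones(len(spec.item_ids), dtype=bool)
    free[a_idx] = False
    m0, v0 = pr.loading_intercept_prior
    lp = _normal_logpdf(params.lam_w[free], m0, v0)
    lp += _normal_logpdf(params.lam_b[free], m0, v0)
    lp += _normal_logpdf(params.nu, m0, v0)
    mf, vf = pr.fixed_effect_prior
    lp += _normal_logpdf(params.gamma[1:], mf, vf)  # gamma[0] fixed at 0
    if params.beta is not None and params.beta.size:
        lp += _normal_logpdf(params.beta.ravel(), mf, vf)
    sh, sc = pr.resid_var_prior
    lp += _invgamma_logpdf(params.th_w, sh, sc)
    lp += _invgamma_logpdf(params.th_b, sh, sc)
    try:
        if pr.uses_huang_wand:
            # marginal Huang-Wand density of Sigma, up to a constant:
            # |S|^-(nu+2p)/2 * prod_j (nu*(S^-1)_jj + 1/A^2)^-((nu+p)/2)
            nu, a_scale = pr.huang_wand_nu, pr.huang_wand_scale
            p_dim = params.Sigma_b.shape[0]
            sign, logdet = np.linalg.slogdet(params.Sigma_b)
            if sign <= 0:
                return -np.inf
            prec_diag = np.diag(np.linalg.inv(params.Sigma_b))
            lp += -0.5 * (nu + 2 * p_dim) * logdet
            lp += -0.5 * (nu + p_dim) * float(np.sum(np.log(nu * prec_diag + a_scale**-2)))
        else:
            scale, df = pr.ranef_cov_prior
            lp += float(stats.invwishart.logpdf(params.Sigma_b, df=df, scale=scale))
    except (np.linalg.LinAlgError, ValueError):
        return -np.inf
    return lp


def joint_logposterior(
    params: ModelParams,
    ranefs: Sequence[PersonRandomEffects],
    data,
    spec: ModelSpec,
    between_scores: np.ndarray | None = None,
) -> float:
    """Unnormalized log posterior of (params, random effects, b scores).

    Sum of the per-person state-marginalized within likelihood, the
    between-level measurement density of the item scores b_ik, the
    random-effect density (mean shifted by beta' x for conditional
    models), and the priors.  A non-positive-definite Sigma_b yields
    -inf (a rejected state), not an exception.  ``between_scores`` is
    (n, K); by default person-item residuals are zero.
    """
    arrays = data.to_arrays() if hasattr(data, "to_arrays") else data
    n, k = arrays.y.shape[0], arrays.y.shape[2]
    if len(ranefs) != n:
        raise ValueError("one random-effect triple per person required")
    try:
        np.linalg.cholesky(params.Sigma_b)
    except np.linalg.LinAlgError:
        return -np.inf

    eta_b = np.array([re.eta_b for re in ranefs])
    if between_scores is None:
        between_scores = params.nu[None, :] + params.lam_b[None, :] * eta_b[:, None]
    between_scores = np.asarray(between_scores, dtype=float)

    ll = 0.0
    for i, re in enumerate(ranefs):
        t_i = int(arrays.lengths[i])
        ll += within_marginal_loglik(arrays.y[i, :t_i], params, re, between_scores=between_scores[i])
        mean_b = params.nu + params.lam_b * re.eta_b
        ll -= 0.5 * float(
            np.sum(LOG2PI + np.log(params.th_b) + (between_scores[i] - mean_b) ** 2 / params.th_b)
        )

    u = np.array([[re.eta_b, re.phi, re.log_innovation_var] for re in ranefs])
    x = arrays.covariates if (spec.covariate_ids and arrays.covariates.size) else None
    means = params.ranef_mean(x)
    if means.ndim == 1:
        means = np.tile(means, (n, 1))
    ll += float(np.sum(stats.multivariate_normal.logpdf(u - means, mean=np.zeros(3), cov=params.Sigma_b)))
    return ll + log_prior(params, spec)
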