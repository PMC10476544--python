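"""Multi-chain Gibbs/Metropolis sampler for the two-level dynamic-factor CFA.

One sweep updates, in order:

  (d) per-person (phi_i, log sigma2_i) by a joint random-walk Metropolis
      step whose target is the state-marginalized within likelihood
      (Kalman filter) times the conditional random-effect prior -- a
      partially collapsed step, placed immediately before the state
      redraw so the collapsed scan stays valid;
  (d') global funnel (ASIS residual-rescaling) and translation moves for
      the carryover and log-variance ensembles, which keep the sampler
      mobile when a random-effect spread is small and the person values
      are pinned to their grand mean;
  (a) latent AR(1) states by forward-filtering backward-sampling;
  (b) between item scores b_ik (followed by an exact recentering draw
      along the likelihood-invariant state-mean/item-score ridge),
      measurement loadings, intercepts and residual variances by
      conjugate normal / inverse-gamma draws;
  (c) trait scores eta_b_i by conjugate normal draws, plus the trait
      funnel move;
  (e) fixed effects (gamma, beta) by a constrained conjugate normal draw
      and Sigma_b by an inverse-Wishart draw (mixed over Huang-Wand
      auxiliary scales under the default prior).

Chains start from over-dispersed states, discard the first half as
burn-in, and are monitored with a two-chain potential scale reduction
(PSR) diagnostic; ``converge_and_rerun`` doubles the iteration count
until PSR clears the threshold and then re-estimates at a multiple of
the converged count to guard against premature stoppage.

Everything is vectorized over persons; a fit at the package's default
study scale (N ~= 333, mean series length ~= 11, K = 7) runs in seconds
per thousand sweeps.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .model_core import ModelParams, ModelSpec
from .panel_io import PanelArrays, PanelDataset


MH_REPEATS = 2  # marginal Metropolis refreshes of (phi_i, log sigma2_i) per sweep
ASIS_SCALE = 0.2  # proposal sd of the global residual-rescaling (funnel) moves


class SettingsError(ValueError):
    pass


class DiagnosticError(ValueError):
    pass


@dataclasses.dataclass
class McmcSettings:
    """Chain configuration.

    ``n_iterations`` counts total sweeps per chain; the first half is
    burn-in.  ``rerun_multiplier`` scales the converged iteration count
    for the final confirmation run (3-4 is the usual guard).
    """

    n_chains: int = 2
    n_iterations: int = 1000
    psr_threshold: float = 1.05
    rerun_multiplier: float = 3.0
    seed: int = 0
    thin: int = 1
    adapt: bool = True
    store_person_draws: bool = False

    def __post_init__(self):
        if self.n_chains < 2:
            raise SettingsError("PSR needs >= 2 chains")
        if self.n_iterations < 2 or self.n_iterations % 2:
            raise SettingsError("n_iterations must be a positive even count")
        if not self.psr_threshold > 1.0:
            raise SettingsError("psr_threshold must exceed 1")
        if not 1.0 <= self.rerun_multiplier:
            raise SettingsError("rerun_multiplier must be >= 1")
        if self.thin < 1:
            raise SettingsError("thin must be >= 1")


@dataclasses.dataclass
class PosteriorSamples:
    """Retained draws, per chain, for every monitored and derived scalar."""

    draws: dict[str, np.ndarray]  # name -> (n_chains, n_kept)
    burn_in: int
    n_iterations: int
    monitored: list[str]
    spec: ModelSpec
    settings: McmcSettings
    item_ids: list[str]
    covariate_ids: list[str]
    mh_acceptance: float
    person_draws: dict[str, np.ndarray] | None = None  # name -> (n_chains, n_kept, n)

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()


@dataclasses.dataclass
class PosteriorSummary:
    """Posterior medians, equal-tailed 95% intervals, and PSR per scalar."""

    table: dict[str, dict[str, float]]
    converged: bool
    max_psr: float

    def __getitem__(self, name: str) -> dict[str, float]:
        return self.table[name]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame.from_dict(self.table, orient="index")


# ---------------------------------------------------------------------------
# vectorized scalar-state filtering


def _pseudo_obs(y0, mask, b, lam_w, th_w):
    """Collapse the K item observations at each occasion into one scalar
    pseudo-observation z with information P (rank-one reduction)."""
    w = lam_w / th_w
    p = mask @ (lam_w * w)
    num = ((y0 - b[:, None, :]) * mask) @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(p > 0, num / np.where(p > 0, p, 1.0), 0.0)
    return z, p


def _ar1_relative_loglik(z, p, occ, phi, sig2):
    """Per-person log-likelihood of the pseudo-observations, up to terms
    free of (phi, sigma2).  Vectorized over persons; scalar Kalman pass."""
    n, t_max = z.shape
    ll = np.zeros(n)
    a = np.zeros(n)
    big_r = sig2 / (1.0 - phi * phi)
    for t in range(t_max):
        pt = p[:, t] * occ[:, t]
        denom = 1.0 + big_r * pt
        e = z[:, t] - a
        ll -= 0.5 * (np.log(denom) + pt * e * e / denom)
        v = big_r / denom
        m = a + v * pt * e
        a = phi * m
        big_r = phi * phi * v + sig2
    return ll


def _ffbs(z, p, occ, phi, sig2, rng):
    """Forward-filter backward-sample the latent AR(1) states."""
    n, t_max = z.shape
    m = np.zeros((n, t_max))
    v = np.zeros((n, t_max))
    a_pred = np.zeros((n, t_max))
    r_pred = np.zeros((n, t_max))
    a = np.zeros(n)
    big_r = sig2 / (1.0 - phi * phi)
    for t in range(t_max):
        a_pred[:, t] = a
        r_pred[:, t] = big_r
        pt = p[:, t] * occ[:, t]
        denom = 1.0 + big_r * pt
        vt = big_r / denom
        mt = a + vt * pt * (z[:, t] - a)
        m[:, t], v[:, t] = mt, vt
        a = phi * mt
        big_r = phi * phi * vt + sig2
    eta = np.empty((n, t_max))
    eta[:, t_max - 1] = m[:, t_max - 1] + np.sqrt(np.maximum(v[:, t_max - 1], 0.0)) * rng.standard_normal(n)
    for t in range(t_max - 2, -1, -1):
        g = phi * v[:, t] / r_pred[:, t + 1]
        mean = m[:, t] + g * (eta[:, t + 1] - a_pred[:, t + 1])
        var = np.maximum(v[:, t] - g * phi * v[:, t], 0.0)
        eta[:, t] = mean + np.sqrt(var) * rng.standard_normal(n)
    return eta


# ---------------------------------------------------------------------------
# chain machinery


def _prepare(data) -> PanelArrays:
    return data.to_arrays() if isinstance(data, PanelDataset) else data


def _init_state(arrays: PanelArrays, spec: ModelSpec, rng: np.random.Generator) -> dict:
    y0 = np.nan_to_num(arrays.y)
    mask = arrays.mask.astype(float)
    k = len(spec.item_ids)
    n = y0.shape[0]
    cnt = mask.sum(axis=1)  # (n, k) observed occasions per person-item
    with np.errstate(invalid="ignore"):
        pmeans = np.where(cnt > 0, y0.sum(axis=1) / np.maximum(cnt, 1.0), np.nan)
    item_mean = np.nanmean(pmeans, axis=0)
    item_var = np.nanvar(np.where(arrays.mask, arrays.y, np.nan), axis=(0, 1))
    item_var = np.maximum(np.nan_to_num(item_var, nan=1.0), 0.05)

    jitter = lambda s, size=None: rng.normal(0.0, s, size=size)  # noqa: E731
    lam_w = 1.0 + jitter(0.3, k)
    lam_b = 1.0 + jitter(0.3, k)
    a_idx = spec.anchor_index
    lam_w[a_idx] = lam_b[a_idx] = 1.0
    nu = item_mean + jitter(0.3, k)
    th_w = 0.5 * item_var * np.exp(jitter(0.5, k))
    th_b = 0.5 * item_var * np.exp(jitter(0.5, k))
    b = np.where(np.isnan(pmeans), nu[None, :], pmeans)
    anchor_centered = b[:, a_idx] - b[:, a_idx].mean()
    eta_b = anchor_centered + jitter(0.2, n)
    phi = rng.uniform(-0.6, 0.6, size=n)
    lv = jitter(1.0, n) + np.log(np.maximum(0.25 * item_var.mean(), 1e-3))
    p = len(spec.covariate_ids)
    a_mat = np.zeros((3, 1 + p))
    a_mat[1, 0] = phi.mean()
    a_mat[2, 0] = lv.mean()
    sigma = np.diag([max(eta_b.var(), 0.05), 0.05, 0.5]) * np.exp(jitter(0.3))
    return {
        "y0": y0,
        "mask": mask,
        "occ": arrays.occasion_mask.astype(float),
        "x": arrays.covariates if p else None,
        "lam_w": lam_w,
        "lam_b": lam_b,
        "nu": nu,
        "th_w": th_w,
        "th_b": th_b,
        "b": b,
        "eta_w": np.zeros((n, y0.shape[1])),
        "eta_b": eta_b,
        "phi": phi,
        "lv": lv,
        "A": a_mat,
        "Sigma": sigma,
        "mh_scale": np.full(n, 0.4),
        "mh_accept": np.zeros(n),
        "mh_total": 0,
        "hw_a": np.ones(3),  # Huang-Wand auxiliary scales
    }


def _sigma_log_prior(sigma: np.ndarray, state, pr) -> float:
    if pr.uses_huang_wand:
        scale = 2.0 * pr.huang_wand_nu * np.diag(1.0 / state["hw_a"])
        df = pr.huang_wand_nu + 3 - 1
    else:
        scale, df = pr.ranef_cov_prior
    try:
        return float(stats.invwishart.logpdf(sigma, df=df, scale=scale))
    except (np.linalg.LinAlgError, ValueError):
        return -np.inf


def _asis_component_move(state, j, means3, data_delta, pr, rng) -> bool:
    """Global funnel move for random-effect component j: rescale the
    conditional residuals u_ij - E[u_ij | u_i,-j] by e^eps and the
    conditional variance of Sigma_b by e^(2 eps), jointly.

    A deterministic expansion indexed by symmetric eps; the Gaussian
    random-effect density change (-n*eps) cancels against the residual
    Jacobian (+n*eps), leaving the data term, the Sigma prior ratio, and
    the +2*eps Jacobian of the conditional-variance coordinate.
    ``data_delta(new_values)`` returns the summed data log-likelihood
    change for the proposed component values (or None to force reject).
    """
    u = np.column_stack([state["eta_b"], state["phi"], state["lv"]])
    sigma = state["Sigma"]
    others = [i for i in range(3) if i != j]
    b_reg = np.linalg.solve(sigma[np.ix_(others, others)], sigma[others, j])
    cond_v = sigma[j, j] - sigma[j, others] @ b_reg
    if cond_v <= 0:
        return False
    m = means3[:, j] + (u[:, others] - means3[:, others]) @ b_reg
    eps = ASIS_SCALE * rng.standard_normal()
    new_vals = m + np.exp(eps) * (u[:, j] - m)
    delta_data = data_delta(new_vals)
    draw = rng.random()  # consumed regardless, keeps the stream aligned
    if delta_data is None:
        return False
    sigma_new = sigma.copy()
    sigma_new[j, j] = sigma[j, others] @ b_reg + np.exp(2.0 * eps) * cond_v
    log_acc = (
        delta_data
        + _sigma_log_prior(sigma_new, state, pr)
        - _sigma_log_prior(sigma, state, pr)
        + 2.0 * eps
    )
    if np.log(draw) < log_acc:
        state["Sigma"] = sigma_new
        if j == 0:
            state["eta_b"] = new_vals
        elif j == 1:
            state["phi"] = new_vals
        else:
            state["lv"] = new_vals
        return True
    return False


def _design(state) -> np.ndarray:
    n = state["b"].shape[0]
    if state["x"] is None:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), state["x"]])


def _sweep(state, spec: ModelSpec, rng: np.random.Generator, adapting: bool, recenter: bool = True):
    y0, mask, occ = state["y0"], state["mask"], state["occ"]
    n, t_max, k = y0.shape
    pr = spec.priors
    m0, v0 = pr.loading_intercept_prior
    mf, vf = pr.fixed_effect_prior
    ig_a, ig_b = pr.resid_var_prior
    a_idx = spec.anchor_index
    z_design = _design(state)
    means3 = z_design @ state["A"].T  # (n, 3) random-effect means

    # --- (d) Metropolis for (phi, log sigma2), states marginalized out.
    # Proposals follow the shape of the conditional random-effect prior
    # (Cholesky of the 2x2 conditional covariance) with a per-person
    # adaptive scale; the step repeats a few times per sweep because the
    # person-level dynamic parameters are the slowest-mixing block.
    z, p = _pseudo_obs(y0, mask, state["b"], state["lam_w"], state["th_w"])
    sigma = state["Sigma"]
    s11 = sigma[0, 0]
    cond_cov = sigma[1:, 1:] - np.outer(sigma[1:, 0], sigma[0, 1:]) / s11
    cond_prec = np.linalg.inv(cond_cov)
    cond_chol = np.linalg.cholesky(cond_cov + 1e-10 * np.eye(2))
    cond_mean = means3[:, 1:] + ((state["eta_b"] - means3[:, 0]) / s11)[:, None] * sigma[1:, 0][None, :]

    phi, lv = state["phi"], state["lv"]
    cur_ll = _ar1_relative_loglik(z, p, occ, phi, np.exp(lv))
    d = np.column_stack([phi, lv]) - cond_mean
    cur_lp = -0.5 * np.einsum("ij,jk,ik->i", d, cond_prec, d)
    n_accepted = 0
    for _ in range(MH_REPEATS):
        step = (rng.standard_normal((n, 2)) @ cond_chol.T) * state["mh_scale"][:, None]
        phi_p, lv_p = phi + step[:, 0], lv + step[:, 1]
        ok = (np.abs(phi_p) < 1.0) & (np.abs(lv_p) < 25.0)
        phi_try = np.where(ok, phi_p, phi)
        lv_try = np.where(ok, lv_p, lv)
        prop_ll = _ar1_relative_loglik(z, p, occ, phi_try, np.exp(lv_try))
        d_p = np.column_stack([phi_try, lv_try]) - cond_mean
        prop_lp = -0.5 * np.einsum("ij,jk,ik->i", d_p, cond_prec, d_p)
        log_acc = prop_ll + prop_lp - cur_ll - cur_lp
        accept = ok & (np.log(rng.random(n)) < log_acc)
        phi = np.where(accept, phi_try, phi)
        lv = np.where(accept, lv_try, lv)
        cur_ll = np.where(accept, prop_ll, cur_ll)
        cur_lp = np.where(accept, prop_lp, cur_lp)
        state["mh_accept"] += accept
        state["mh_total"] += 1
        n_accepted += int(accept.sum())
    state["phi"], state["lv"] = phi, lv
    if adapting and state["mh_total"] % (25 * MH_REPEATS) == 0:
        rate = state["mh_accept"] / (25.0 * MH_REPEATS)
        state["mh_scale"] *= np.exp(0.5 * (rate - 0.35))
        state["mh_scale"] = np.clip(state["mh_scale"], 0.05, 20.0)
        state["mh_accept"][:] = 0.0

    # --- global funnel moves for the carryover and log-variance spreads
    base_ll = cur_ll.sum()
    last_delta = [0.0]

    def _phi_delta(new_phi):
        if np.any(np.abs(new_phi) >= 0.999):
            return None
        last_delta[0] = _ar1_relative_loglik(z, p, occ, new_phi, np.exp(state["lv"])).sum() - base_ll
        return last_delta[0]

    if _asis_component_move(state, 1, means3, _phi_delta, pr, rng):
        base_ll += last_delta[0]

    def _lv_delta(new_lv):
        if np.any(np.abs(new_lv) >= 25.0):
            return None
        last_delta[0] = _ar1_relative_loglik(z, p, occ, state["phi"], np.exp(new_lv)).sum() - base_ll
        return last_delta[0]

    if _asis_component_move(state, 2, means3, _lv_delta, pr, rng):
        base_ll += last_delta[0]

    # --- global translation moves: when the carryover (or log-variance)
    # spread is small, person values are pinned to the grand mean and the
    # ensemble mean mixes only by a collective random walk; shifting every
    # person and the fixed effect together against the pooled likelihood
    # restores mixing.  Random-effect residuals are unchanged, so only the
    # data term and the (near-flat) fixed-effect prior enter.
    t_total = max(float(occ.sum()), 1.0)
    for comp, bound in ((1, 0.999), (2, 25.0)):
        scale = (1.5 if comp == 1 else 3.0) / np.sqrt(t_total)
        delta = scale * rng.standard_normal()
        vals = state["phi"] if comp == 1 else state["lv"]
        new_vals = vals + delta
        draw = rng.random()
        if np.all(np.abs(new_vals) < bound):
            if comp == 1:
                d_ll = _ar1_relative_loglik(z, p, occ, new_vals, np.exp(state["lv"])).sum() - base_ll
            else:
                d_ll = _ar1_relative_loglik(z, p, occ, state["phi"], np.exp(new_vals)).sum() - base_ll
            g_old = state["A"][comp, 0]
            d_prior = -0.5 * ((g_old + delta - mf) ** 2 - (g_old - mf) ** 2) / vf
            if np.log(draw) < d_ll + d_prior:
                if comp == 1:
                    state["phi"] = new_vals
                else:
                    state["lv"] = new_vals
                state["A"][comp, 0] = g_old + delta
                base_ll += d_ll
    means3 = z_design @ state["A"].T  # refresh after the translation moves

    # --- (a) FFBS latent states
    state["eta_w"] = _ffbs(z, p, occ, state["phi"], np.exp(state["lv"]), rng)

    # --- (b1) between item scores b_ik
    eta_w = state["eta_w"]
    resid_sum = ((y0 - state["lam_w"][None, None, :] * eta_w[:, :, None]) * mask).sum(axis=1)
    n_ik = mask.sum(axis=1)
    prior_mean = state["nu"][None, :] + state["lam_b"][None, :] * state["eta_b"][:, None]
    post_prec = n_ik / state["th_w"][None, :] + 1.0 / state["th_b"][None, :]
    post_mean = (resid_sum / state["th_w"][None, :] + prior_mean / state["th_b"][None, :]) / post_prec
    state["b"] = post_mean + rng.standard_normal((n, k)) / np.sqrt(post_prec)

    # --- recentering move along the likelihood-invariant direction
    # (eta_w + delta, b - lam_w * delta): the item scores and the state's
    # sample mean are nearly collinear at short series, so single-site
    # Gibbs mixes very slowly along this ridge; delta has an exact
    # Gaussian conditional (translation-group move), sampled per person.
    if recenter:
        phi_c, sig2_c = state["phi"], np.exp(state["lv"])
        eta_w = state["eta_w"]
        t_len = occ.sum(axis=1)
        diffs = (eta_w[:, 1:] - phi_c[:, None] * eta_w[:, :-1]) * occ[:, 1:]
        prec_ar = ((1.0 - phi_c**2) + (t_len - 1.0) * (1.0 - phi_c) ** 2) / sig2_c
        lin_ar = -((1.0 - phi_c**2) * eta_w[:, 0] + (1.0 - phi_c) * diffs.sum(axis=1)) / sig2_c
        lam_w_c = state["lam_w"]
        prec_b = float(np.sum(lam_w_c**2 / state["th_b"]))
        lin_b = (state["b"] - prior_mean) @ (lam_w_c / state["th_b"])
        q_delta = prec_ar + prec_b
        delta = (lin_ar + lin_b) / q_delta + rng.standard_normal(n) / np.sqrt(q_delta)
        eta_w = eta_w + delta[:, None]
        state["eta_w"] = eta_w
        state["b"] = state["b"] - delta[:, None] * lam_w_c[None, :]

    # --- (c) trait scores eta_b
    lam_b, th_b = state["lam_b"], state["th_b"]
    lik_prec = float(np.sum(lam_b**2 / th_b))
    lik_lin = (state["b"] - state["nu"][None, :]) @ (lam_b / th_b)
    u12 = np.column_stack([state["phi"], state["lv"]])
    sigma = state["Sigma"]  # refreshed: the funnel moves may have changed it
    s11 = sigma[0, 0]
    sig_cond_var = s11 - sigma[0, 1:] @ np.linalg.solve(sigma[1:, 1:], sigma[1:, 0])
    sig_cond_mean = means3[:, 0] + (u12 - means3[:, 1:]) @ np.linalg.solve(sigma[1:, 1:], sigma[1:, 0])
    post_prec_e = lik_prec + 1.0 / sig_cond_var
    post_mean_e = (lik_lin + sig_cond_mean / sig_cond_var) / post_prec_e
    state["eta_b"] = post_mean_e + rng.standard_normal(n) / np.sqrt(post_prec_e)

    # --- global funnel move for the trait spread
    def _eta_delta(new_eta):
        cur_fit = state["b"] - (state["nu"][None, :] + state["lam_b"][None, :] * state["eta_b"][:, None])
        new_fit = state["b"] - (state["nu"][None, :] + state["lam_b"][None, :] * new_eta[:, None])
        return -0.5 * float(np.sum((new_fit**2 - cur_fit**2) / state["th_b"][None, :]))

    _asis_component_move(state, 0, means3, _eta_delta, pr, rng)

    # --- (b2) within measurement: loadings then residual variances
    resid_b = (y0 - state["b"][:, None, :]) * mask  # y - b, zeroed where unobserved
    s_xx = (mask * eta_w[:, :, None] ** 2).sum(axis=(0, 1))
    s_xy = (resid_b * eta_w[:, :, None]).sum(axis=(0, 1))
    prec_l = s_xx / state["th_w"] + 1.0 / v0
    mean_l = (s_xy / state["th_w"] + m0 / v0) / prec_l
    lam_w_new = mean_l + rng.standard_normal(k) / np.sqrt(prec_l)
    lam_w_new[a_idx] = 1.0
    state["lam_w"] = lam_w_new
    err = (resid_b - mask * lam_w_new[None, None, :] * eta_w[:, :, None]) ** 2
    ssr_w = err.sum(axis=(0, 1))
    n_cells = mask.sum(axis=(0, 1))
    state["th_w"] = (ig_b + 0.5 * ssr_w) / rng.gamma(ig_a + 0.5 * n_cells, 1.0, size=k)

    # --- (b3) between measurement: (nu, lam_b) per item, then theta_b
    eta_b = state["eta_b"]
    design_b = np.column_stack([np.ones(n), eta_b])
    xtx = design_b.T @ design_b
    nu_new = np.empty(k)
    lam_b_new = np.empty(k)
    for j in range(k):
        if j == a_idx:
            prec = n / state["th_b"][j] + 1.0 / v0
            mean = ((state["b"][:, j] - eta_b).sum() / state["th_b"][j] + m0 / v0) / prec
            nu_new[j] = mean + rng.standard_normal() / np.sqrt(prec)
            lam_b_new[j] = 1.0
        else:
            q = xtx / state["th_b"][j] + np.eye(2) / v0
            h = design_b.T @ state["b"][:, j] / state["th_b"][j] + m0 / v0
            chol = np.linalg.cholesky(q)
            mean = np.linalg.solve(q, h)
            drawn = mean + np.linalg.solve(chol.T, rng.standard_normal(2))
            nu_new[j], lam_b_new[j] = drawn
    state["nu"], state["lam_b"] = nu_new, lam_b_new
    fitted = nu_new[None, :] + lam_b_new[None, :] * eta_b[:, None]
    ssr_b = ((state["b"] - fitted) ** 2).sum(axis=0)
    state["th_b"] = (ig_b + 0.5 * ssr_b) / rng.gamma(ig_a + 0.5 * n, 1.0, size=k)

    # --- (e) structural fixed effects and Sigma_b
    u = np.column_stack([state["eta_b"], state["phi"], state["lv"]])
    omega = np.linalg.inv(state["Sigma"])
    q_dim = z_design.shape[1]
    ztz = z_design.T @ z_design
    big_q = np.kron(omega, ztz) + np.eye(3 * q_dim) / vf
    h = (omega @ (u.T @ z_design)).ravel() + mf / vf
    # trait grand mean fixed at 0 for identification: drop coordinate (0, 0)
    keep = np.ones(3 * q_dim, dtype=bool)
    keep[0] = False
    q_ff = big_q[np.ix_(keep, keep)]
    mean_f = np.linalg.solve(q_ff, h[keep])
    chol = np.linalg.cholesky(q_ff)
    draw_f = mean_f + np.linalg.solve(chol.T, rng.standard_normal(keep.sum()))
    vec = np.zeros(3 * q_dim)
    vec[keep] = draw_f
    state["A"] = vec.reshape(3, q_dim)

    means3_new = z_design @ state["A"].T
    resid_u = u - means3_new
    s_mat = resid_u.T @ resid_u
    if pr.uses_huang_wand:
        nu_hw, a_scale = pr.huang_wand_nu, pr.huang_wand_scale
        scale_post = 2.0 * nu_hw * np.diag(1.0 / state["hw_a"]) + s_mat
        df_post = nu_hw + 3 - 1 + n
        state["Sigma"] = stats.invwishart.rvs(df=df_post, scale=scale_post, random_state=rng)
        prec_diag = np.diag(np.linalg.inv(state["Sigma"]))
        ig_scale = nu_hw * prec_diag + a_scale**-2
        state["hw_a"] = ig_scale / rng.gamma(0.5 * (nu_hw + 3), 1.0, size=3)
    else:
        scale0, df0 = pr.ranef_cov_prior
        scale_post = np.asarray(scale0) + s_mat
        state["Sigma"] = stats.invwishart.rvs(df=df0 + n, scale=scale_post, random_state=rng)
    return n_accepted


def _record(state, spec: ModelSpec, store: dict[str, list], person_store: dict[str, list] | None):
    items = spec.item_ids
    a_idx = spec.anchor_index
    for j, it in enumerate(items):
        store[f"lambda_w[{it}]"].append(state["lam_w"][j])
        store[f"lambda_b[{it}]"].append(state["lam_b"][j])
        store[f"nu[{it}]"].append(state["nu"][j])
        store[f"theta_w[{it}]"].append(state["th_w"][j])
        store[f"theta_b[{it}]"].append(state["th_b"][j])
        if j != a_idx:
            store[f"lambda_diff[{it}]"].append(state["lam_b"][j] - state["lam_w"][j])
    a_mat, sigma = state["A"], state["Sigma"]
    store["gamma_phi"].append(a_mat[1, 0])
    store["gamma_logvar"].append(a_mat[2, 0])
    for c, cov in enumerate(spec.covariate_ids, start=1):
        store[f"beta_eta[{cov}]"].append(a_mat[0, c])
        store[f"beta_phi[{cov}]"].append(a_mat[1, c])
        store[f"beta_logvar[{cov}]"].append(a_mat[2, c])
    store["var_eta_b"].append(sigma[0, 0])
    store["var_phi"].append(sigma[1, 1])
    store["var_logvar"].append(sigma[2, 2])
    store["cov_eta_phi"].append(sigma[0, 1])
    store["cov_eta_logvar"].append(sigma[0, 2])
    store["cov_phi_logvar"].append(sigma[1, 2])
    d = np.sqrt(np.diag(sigma))
    store["r_phi_eta"].append(sigma[0, 1] / (d[0] * d[1]))
    store["r_zeta_eta"].append(sigma[0, 2] / (d[0] * d[2]))
    store["r_phi_zeta"].append(sigma[1, 2] / (d[1] * d[2]))
    # person-average stationary state variance for this draw (plug-in for ICC)
    stat_var = np.exp(state["lv"]) / (1.0 - state["phi"] ** 2)
    store["vbar_w"].append(float(stat_var.mean()))
    if person_store is not None:
        person_store["phi"].append(state["phi"].copy())
        person_store["log_innovation_var"].append(state["lv"].copy())
        person_store["eta_b"].append(state["eta_b"].copy())


def _store_names(spec: ModelSpec) -> tuple[list[str], list[str]]:
    items = spec.item_ids
    monitored: list[str] = []
    for it in items:
        monitored += [f"lambda_w[{it}]", f"lambda_b[{it}]", f"nu[{it}]", f"theta_w[{it}]", f"theta_b[{it}]"]
    monitored += ["gamma_phi", "gamma_logvar"]
    for cov in spec.covariate_ids:
        monitored += [f"beta_eta[{cov}]", f"beta_phi[{cov}]", f"beta_logvar[{cov}]"]
    monitored += ["var_eta_b", "var_phi", "var_logvar", "cov_eta_phi", "cov_eta_logvar", "cov_phi_logvar"]
    derived = [f"lambda_diff[{it}]" for it in items if it != spec.anchor_item]
    derived += ["r_phi_zeta", "r_phi_eta", "r_zeta_eta", "vbar_w"]
    return monitored, derived


def run_mcmc(data, spec: ModelSpec, settings: McmcSettings) -> PosteriorSamples:
    """Run ``settings.n_chains`` chains and return retained (post burn-in,
    thinned) draws for every monitored parameter and derived contrast.

    Bit-reproducible for identical (data, spec, settings).
    """
    arrays = _prepare(data)
    missing = [c for c in spec.covariate_ids if c not in arrays.covariate_ids]
    if missing:
        raise SettingsError(f"covariates {missing} not present in panel")
    if spec.covariate_ids:
        order = [arrays.covariate_ids.index(c) for c in spec.covariate_ids]
        arrays = dataclasses.replace(arrays, covariates=arrays.covariates[:, order], covariate_ids=list(spec.covariate_ids))
    monitored, derived = _store_names(spec)
    burn_in = settings.n_iterations // 2
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    all_draws: dict[str, list[np.ndarray]] = {nm: [] for nm in monitored + derived}
    person_draws: dict[str, list[np.ndarray]] | None = (
        {nm: [] for nm in ("phi", "log_innovation_var", "eta_b")} if settings.store_person_draws else None
    )
    acc_rates = []
    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        state = _init_state(arrays, spec, rng)
        store: dict[str, list] = {nm: [] for nm in monitored + derived}
        p_store = {nm: [] for nm in ("phi", "log_innovation_var", "eta_b")} if person_draws is not None else None
        accepted_after_burnin = 0
        total_after_burnin = 0
        for it in range(settings.n_iterations):
            adapting = settings.adapt and it < burn_in
            n_acc = _sweep(state, spec, rng, adapting)
            if it >= burn_in:
                accepted_after_burnin += n_acc
                total_after_burnin += state["phi"].shape[0] * MH_REPEATS
                if (it - burn_in) % settings.thin == 0:
                    _record(state, spec, store, p_store)
        acc_rates.append(accepted_after_burnin / max(total_after_burnin, 1))
        for nm in store:
            all_draws[nm].append(np.asarray(store[nm]))
        if person_draws is not None and p_store is not None:
            for nm in p_store:
                person_draws[nm].append(np.asarray(p_store[nm]))
    draws = {nm: np.stack(chains) for nm, chains in all_draws.items()}
    persons = {nm: np.stack(chains) for nm, chains in person_draws.items()} if person_draws is not None else None
    return PosteriorSamples(
        draws=draws,
        burn_in=burn_in,
        n_iterations=settings.n_iterations,
        monitored=monitored,
        spec=spec,
        settings=settings,
        item_ids=list(spec.item_ids),
        covariate_ids=list(spec.covariate_ids),
        mh_acceptance=float(np.mean(acc_rates)),
        person_draws=persons,
    )


def compute_psr(samples: PosteriorSamples | dict[str, np.ndarray]) -> dict[str, float]:
    """Potential scale reduction per parameter from the retained halves.

    PSR = sqrt((W + B) / W) with W the mean within-chain variance and B
    the between-chain variance of the chain means; identical chains give
    exactly 1, diverging chains blow up.
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else samples
    names = samples.monitored if isinstance(samples, PosteriorSamples) else list(draws)
    out: dict[str, float] = {}
    for nm in names:
        chains = np.asarray(draws[nm], dtype=float)
        if chains.ndim != 2 or chains.shape[0] < 2:
            raise DiagnosticError("PSR requires >= 2 chains of draws")
        w = float(np.mean(np.var(chains, axis=1, ddof=1)))
        b = float(np.var(np.mean(chains, axis=1), ddof=1))
        if w <= 0.0:
            out[nm] = 1.0 if b <= 0.0 else np.inf
        else:
            out[nm] = float(np.sqrt((w + b) / w))
    return out


def summarize(samples: PosteriorSamples) -> PosteriorSummary:
    """Posterior median, equal-tailed 95% credible interval, and PSR."""
    if samples.n_kept == 0:
        raise SettingsError("no retained draws to summarize")
    psr = compute_psr(samples)
    table: dict[str, dict[str, float]] = {}
    for nm, chains in samples.draws.items():
        pooled = chains.ravel()
        lo, med, hi = np.percentile(pooled, [2.5, 50.0, 97.5])
        table[nm] = {
            "point": float(med),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "psr": psr.get(nm, float("nan")),
        }
    max_psr = max(psr.values())
    return PosteriorSummary(table=table, converged=bool(max_psr < samples.settings.psr_threshold), max_psr=float(max_psr))


def converge_and_rerun(
    data,
    spec: ModelSpec,
    settings: McmcSettings,
    max_doublings: int = 3,
) -> tuple[PosteriorSamples, PosteriorSummary]:
    """Double the iteration count until every monitored PSR clears the
    threshold, then re-estimate at ``rerun_multiplier`` times the
    converged count; the returned summary comes from the re-run.

    If the budget is exhausted the best attempt is returned with
    ``converged=False`` -- never a silent success.
    """
    arrays = _prepare(data)
    n_iter = settings.n_iterations
    best: tuple[PosteriorSamples, PosteriorSummary] | None = None
    for _ in range(max_doublings + 1):
        trial = dataclasses.replace(settings, n_iterations=n_iter)
        samples = run_mcmc(arrays, spec, trial)
        psr = compute_psr(samples)
        if max(psr.values()) < settings.psr_threshold:
            final_iter = int(np.ceil(settings.rerun_multiplier * n_iter / 2.0) * 2)
            final = dataclasses.replace(settings, n_iterations=final_iter)
            samples = run_mcmc(arrays, spec, final)
            summary = summarize(samples)
            return samples, summary
        best = (samples, summarize(samples))
        n_iter *= 2
    assert best is not None
    samples, summary = best
    summary = dataclasses.replace(summary, converged=False)
    return samples, summary
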