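"""Measurement and structural outputs of the fitted two-level model.

All derived quantities (ICC, level-specific R^2, cross-level loading
differences, random-effect correlations) are computed per retained
posterior draw and then summarized by the median and equal-tailed 95%
credible interval -- never by transforming summarized marginals, since
the interval semantics of a derived quantity require the posterior of
the transform itself.

The within-level item variance uses the person-average stationary latent
variance Vbar_w = mean_i sigma2_i / (1 - phi_i^2), evaluated per draw
from the person-specific random effects (recorded by the sampler as
``vbar_w``).  A fixed-effects plug-in mode is available for comparison:
it evaluates exp(gamma_logvar + var_logvar/2) / (1 - gamma_phi^2) from
the fixed effects and the log-variance random-effect spread alone.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .model_core import ModelSpec
from .sampler import McmcSettings, PosteriorSamples, run_mcmc
from .synthetic_data import NonstationaryError, TrueParameters, population_within_variance


class AnchorError(ValueError):
    """Raised when a difference test is requested for the anchor item."""


class AnchorSelectionError(ValueError):
    """Raised when no mutually invariant set of items can be defended."""


class UndefinedRatioError(ZeroDivisionError):
    pass


@dataclasses.dataclass(frozen=True)
class ItemPsychometrics:
    item_id: str
    icc: float
    icc_ci: tuple[float, float]
    r2_within: float
    r2_between: float
    loading_within: float
    loading_between: float
    loading_difference: float | None
    difference_ci: tuple[float, float] | None
    invariant: bool | None  # None for the anchor (no test)
    is_anchor: bool = False


@dataclasses.dataclass(frozen=True)
class StructuralSummary:
    phi_mean: dict[str, float]
    phi_var: dict[str, float]
    innovation_mean: dict[str, float]  # log scale
    innovation_var: dict[str, float]
    eta_b_var: dict[str, float]
    r_phi_innov: dict[str, float]
    r_phi_eta: dict[str, float]
    r_innov_eta: dict[str, float]
    conditional: dict[str, dict[str, dict[str, float]]] | None = None


def stationary_variance(phi: float, innovation_var: float) -> float:
    """Stationary variance of an AR(1): sigma2 / (1 - phi^2)."""
    if abs(phi) >= 1.0:
        raise NonstationaryError("|phi| >= 1 has no stationary variance")
    if innovation_var <= 0:
        raise ValueError("innovation variance must be positive")
    return float(innovation_var / (1.0 - phi * phi))


def _summ(draws: np.ndarray) -> dict[str, float]:
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return {"point": float(med), "ci_low": float(lo), "ci_high": float(hi)}


def _vbar_draws(samples: PosteriorSamples, mode: str) -> np.ndarray:
    if mode == "random":
        return samples.pooled("vbar_w")
    if mode == "fixed":
        g_phi = samples.pooled("gamma_phi")
        g_lv = samples.pooled("gamma_logvar")
        v_lv = samples.pooled("var_logvar")
        return np.exp(g_lv + 0.5 * v_lv) / (1.0 - g_phi**2)
    raise ValueError("mode must be 'random' or 'fixed'")


def _item_variance_draws(samples: PosteriorSamples, item: str, mode: str):
    lam_b = samples.pooled(f"lambda_b[{item}]")
    lam_w = samples.pooled(f"lambda_w[{item}]")
    th_b = samples.pooled(f"theta_b[{item}]")
    th_w = samples.pooled(f"theta_w[{item}]")
    var_eta = samples.pooled("var_eta_b")
    vbar = _vbar_draws(samples, mode)
    between = lam_b**2 * var_eta + th_b
    within = lam_w**2 * vbar + th_w
    return between, within, lam_b, lam_w, th_b, th_w, var_eta, vbar


def compute_icc(samples: PosteriorSamples, item: str, mode: str = "random") -> dict[str, float]:
    """Posterior ICC of an item: between / (between + within) variance,
    computed per draw and summarized by median and 95% interval."""
    between, within, *_ = _item_variance_draws(samples, item, mode)
    total = between + within
    if np.any(total <= 0):
        raise UndefinedRatioError(f"zero total variance for item {item!r}")
    return _summ(between / total)


def compute_r2(samples: PosteriorSamples, item: str, mode: str = "random") -> dict[str, dict[str, float]]:
    """Level-specific reliability: share of the item's level variance
    explained by the level's latent factor, per draw."""
    between, within, lam_b, lam_w, th_b, th_w, var_eta, vbar = _item_variance_draws(samples, item, mode)
    if np.any(between <= 0) or np.any(within <= 0):
        raise UndefinedRatioError(f"zero level variance for item {item!r}")
    r2_b = lam_b**2 * var_eta / between
    r2_w = lam_w**2 * vbar / within
    return {"r2_between": _summ(r2_b), "r2_within": _summ(r2_w)}


def loading_difference_test(samples: PosteriorSamples, item: str) -> dict[str, float | bool]:
    """Cross-level invariance test: posterior of lambda_b - lambda_w.

    The item is flagged noninvariant when the 95% equal-tailed interval
    excludes zero.  The anchor has no test (difference fixed at 0)."""
    if item == samples.spec.anchor_item:
        raise AnchorError("anchor loading difference is fixed at 0 by constraint")
    s = _summ(samples.pooled(f"lambda_diff[{item}]"))
    s["invariant"] = bool(s["ci_low"] <= 0.0 <= s["ci_high"])
    return s


def random_effect_correlations(samples: PosteriorSamples) -> dict[str, dict[str, float]]:
    """Posterior correlations among (phi, log innovation var, trait)."""
    return {
        "r_phi_zeta": _summ(samples.pooled("r_phi_zeta")),
        "r_phi_eta": _summ(samples.pooled("r_phi_eta")),
        "r_zeta_eta": _summ(samples.pooled("r_zeta_eta")),
    }


def conditional_effects(samples: PosteriorSamples, covariate: str) -> dict[str, dict[str, float]]:
    """Covariate effects on trait mean, carryover, and log innovation
    variance; each row carries a 'credible' flag (CI excludes zero).

    With a dummy covariate the fixed-effect rows of the same fit are the
    reference-group means."""
    if covariate not in samples.covariate_ids:
        raise KeyError(f"covariate {covariate!r} was not part of the fit")
    out = {}
    for target, name in (("eta_b", "beta_eta"), ("phi", "beta_phi"), ("logvar", "beta_logvar")):
        s = _summ(samples.pooled(f"{name}[{covariate}]"))
        s["credible"] = not (s["ci_low"] <= 0.0 <= s["ci_high"])
        out[target] = s
    return out


# ---------------------------------------------------------------------------
# anchor selection


def invariance_graph(samples: PosteriorSamples, level: float = 0.95) -> tuple[list[str], np.ndarray]:
    """Pairwise mutual-invariance adjacency from cross-level loading ratios.

    For each item the per-draw ratio r_k = lambda_b_k / lambda_w_k is
    formed; a pair (j, k) is mutually invariant when the equal-tailed
    interval of r_j - r_k contains zero."""
    items = samples.item_ids
    ratios = np.stack([samples.pooled(f"lambda_b[{it}]") / samples.pooled(f"lambda_w[{it}]") for it in items])
    k = len(items)
    adj = np.zeros((k, k), dtype=bool)
    q = (100 * (1 - level) / 2, 100 * (1 + level) / 2)
    for j, l in itertools.combinations(range(k), 2):
        lo, hi = np.percentile(ratios[j] - ratios[l], q)
        adj[j, l] = adj[l, j] = lo <= 0.0 <= hi
    return items, adj


def _largest_cliques(adj: np.ndarray) -> list[tuple[int, ...]]:
    k = adj.shape[0]
    for size in range(k, 1, -1):
        found = [
            c
            for c in itertools.combinations(range(k), size)
            if all(adj[a, b] for a, b in itertools.combinations(c, 2))
        ]
        if found:
            return found
    return []


def anchor_from_samples(samples: PosteriorSamples) -> tuple[str, dict]:
    """Pick an anchor from a provisional fit: the highest within-R^2 item
    of the largest mutually invariant clique."""
    items, adj = invariance_graph(samples)
    cliques = _largest_cliques(adj)
    if not cliques:
        raise AnchorSelectionError("no mutually invariant pair of items; difference table cannot be defended")
    best_clique = max(cliques, key=lambda c: sum(compute_r2(samples, items[i])["r2_within"]["point"] for i in c))
    r2w = {items[i]: compute_r2(samples, items[i])["r2_within"]["point"] for i in best_clique}
    anchor = max(r2w, key=r2w.get)
    diagnostics = {
        "clique": [items[i] for i in best_clique],
        "all_largest_cliques": [[items[i] for i in c] for c in cliques],
        "adjacency": adj,
        "items": items,
        "r2_within": r2w,
    }
    return anchor, diagnostics


def select_anchor(
    data,
    spec: ModelSpec,
    settings: McmcSettings,
    return_diagnostics: bool = False,
):
    """Data-driven anchor choice (adapted triangle heuristic).

    Runs a provisional fit anchored on ``spec.anchor_item`` (the default
    reference), tests every pair of items for equality of the
    cross-level loading ratio, and returns the highest within-R^2 member
    of the largest mutually invariant clique; this item should then be
    the fixed-to-1 anchor of the final fit."""
    if len(spec.item_ids) < 3:
        raise AnchorSelectionError("anchor selection needs at least 3 items")
    samples = run_mcmc(data, spec, settings)
    anchor, diagnostics = anchor_from_samples(samples)
    diagnostics["provisional_samples"] = samples
    if return_diagnostics:
        return anchor, diagnostics
    return anchor


# ---------------------------------------------------------------------------
# analytic (generative-truth) counterparts, used as oracles in testing


def analytic_within_item_variance(params: TrueParameters, item: str) -> tuple[float, float]:
    v_w = population_within_variance(params)
    lam = params.loadings_within[item]
    return lam**2 * v_w, params.resid_var_within[item]


def analytic_icc(params: TrueParameters, item: str) -> float:
    """Population ICC implied by generative truth."""
    sig, th_w = analytic_within_item_variance(params, item)
    between = params.loadings_between[item] ** 2 * params.Sigma_b[0, 0] + params.resid_var_between[item]
    return float(between / (between + sig + th_w))


def analytic_r2(params: TrueParameters, item: str) -> tuple[float, float]:
    """Population (r2_between, r2_within) implied by generative truth."""
    sig, th_w = analytic_within_item_variance(params, item)
    true_b = params.loadings_between[item] ** 2 * params.Sigma_b[0, 0]
    r2_b = true_b / (true_b + params.resid_var_between[item])
    r2_w = sig / (sig + th_w)
    return float(r2_b), float(r2_w)


# ---------------------------------------------------------------------------
# report assembly


def measurement_report(samples: PosteriorSamples, mode: str = "random") -> list[ItemPsychometrics]:
    """Per-item measurement table (ICC, loadings, R^2, difference test)."""
    rows = []
    for item in samples.item_ids:
        icc = compute_icc(samples, item, mode)
        r2 = compute_r2(samples, item, mode)
        lam_w = float(np.median(samples.pooled(f"lambda_w[{item}]")))
        lam_b = float(np.median(samples.pooled(f"lambda_b[{item}]")))
        if item == samples.spec.anchor_item:
            diff, ci, inv, anchor = None, None, None, True
        else:
            t = loading_difference_test(samples, item)
            diff, ci, inv, anchor = t["point"], (t["ci_low"], t["ci_high"]), t["invariant"], False
        rows.append(
            ItemPsychometrics(
                item_id=item,
                icc=icc["point"],
                icc_ci=(icc["ci_low"], icc["ci_high"]),
                r2_within=r2["r2_within"]["point"],
                r2_between=r2["r2_between"]["point"],
                loading_within=lam_w,
                loading_between=lam_b,
                loading_difference=diff,
                difference_ci=ci,
                invariant=inv,
                is_anchor=anchor,
            )
        )
    return rows


def structural_summary(samples: PosteriorSamples) -> StructuralSummary:
    """Structural table: fixed effects, random-effect variances and
    correlations, plus covariate rows when the fit was conditional."""
    conditional = None
    if samples.covariate_ids:
        conditional = {cov: conditional_effects(samples, cov) for cov in samples.covariate_ids}
    corr = random_effect_correlations(samples)
    return StructuralSummary(
        phi_mean=_summ(samples.pooled("gamma_phi")),
        phi_var=_summ(samples.pooled("var_phi")),
        innovation_mean=_summ(samples.pooled("gamma_logvar")),
        innovation_var=_summ(samples.pooled("var_logvar")),
        eta_b_var=_summ(samples.pooled("var_eta_b")),
        r_phi_innov=corr["r_phi_zeta"],
        r_phi_eta=corr["r_phi_eta"],
        r_innov_eta=corr["r_zeta_eta"],
        conditional=conditional,
    )
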