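"""Pipeline orchestration: simulate / fit / recover, with table exports.

A run proceeds in a fixed order -- validation report, anchor selection
(optional), unconditional fit with measurement and structural tables,
then the conditional fit when covariates are configured -- and leaves a
JSON manifest stamping every artifact with the config hash and seed.
Each run fits one factor (one set of items); joint multi-factor fitting
is rejected at config parse.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import psychometrics
from .model_core import ModelSpec
from .panel_io import load_panel, validate_panel, write_panel
from .psychometrics import ItemPsychometrics, measurement_report, structural_summary
from .sampler import McmcSettings, converge_and_rerun
from .synthetic_data import default_true_parameters, simulate_panel, write_truth_sidecar

log = logging.getLogger("dsemcfa")

MODES = ("simulate", "fit", "simulate-and-recover")


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    mode: str
    outdir: Path
    panel_path: Path | None = None
    item_ids: list[str] | None = None
    anchor: str = "auto"
    covariate_ids: list[str] = dataclasses.field(default_factory=list)
    mcmc: dict = dataclasses.field(default_factory=dict)
    simulate: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if raw.get("mode") not in MODES:
            raise ConfigError(f"mode must be one of {MODES}")
        model = raw.get("model", {})
        if "factors" in model:
            raise ConfigError(
                "joint multi-factor fitting is out of scope; fit one factor (one item set) per run"
            )
        paths = raw.get("paths", {})
        return cls(
            mode=raw["mode"],
            outdir=Path(paths.get("outdir", "dsemcfa_out")),
            panel_path=Path(paths["panel"]) if "panel" in paths else None,
            item_ids=list(model["items"]) if "items" in model else None,
            anchor=model.get("anchor", "auto"),
            covariate_ids=list(model.get("covariates", [])),
            mcmc=dict(raw.get("mcmc", {})),
            simulate=dict(raw.get("simulate", {})),
            seed=int(raw.get("seed", 0)),
        )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _fmt(v) -> str:
    return repr(float(v))


def render_measurement_table(report: list[ItemPsychometrics], path: str | Path | None = None) -> pd.DataFrame:
    """Measurement table with the standard column set: item, ICC, within
    loading/R^2, between loading/R^2, loading difference with interval,
    and the noninvariance flag.  The anchor row renders an em-dash in the
    difference cell."""
    rows = []
    for r in report:
        rows.append(
            {
                "item": r.item_id,
                "icc": r.icc,
                "lambda_within": r.loading_within,
                "r2_within": r.r2_within,
                "lambda_between": r.loading_between,
                "r2_between": r.r2_between,
                "difference": "—" if r.is_anchor else _fmt(r.loading_difference),
                "diff_ci_low": "" if r.is_anchor else _fmt(r.difference_ci[0]),
                "diff_ci_high": "" if r.is_anchor else _fmt(r.difference_ci[1]),
                "noninvariant": "" if r.is_anchor else ("*" if not r.invariant else ""),
            }
        )
    frame = pd.DataFrame(rows)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return frame


def parse_measurement_table(path: str | Path) -> pd.DataFrame:
    """Read back a rendered measurement table with numeric fields intact."""
    frame = pd.read_csv(path, dtype={"difference": str, "noninvariant": str})
    for col in ("icc", "lambda_within", "r2_within", "lambda_between", "r2_between"):
        frame[col] = frame[col].astype(float)
    return frame


def render_structural_table(summary, path: str | Path | None = None) -> pd.DataFrame:
    rows = [
        ("phi_mean", summary.phi_mean),
        ("phi_var", summary.phi_var),
        ("zeta_mean_log", summary.innovation_mean),
        ("zeta_var_log", summary.innovation_var),
        ("eta_b_var", summary.eta_b_var),
        ("r_phi_zeta", summary.r_phi_innov),
        ("r_phi_eta", summary.r_phi_eta),
        ("r_zeta_eta", summary.r_innov_eta),
    ]
    if summary.conditional:
        for cov, effects in summary.conditional.items():
            for target, s in effects.items():
                rows.append((f"beta_{target}[{cov}]", s))
    frame = pd.DataFrame(
        [
            {"parameter": name, "point": s["point"], "ci_low": s["ci_low"], "ci_high": s["ci_high"]}
            for name, s in rows
        ]
    )
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return frame


def _settings(config: RunConfig) -> McmcSettings:
    kw = dict(config.mcmc)
    kw.setdefault("seed", config.seed)
    return McmcSettings(**kw)


def run_pipeline(config: RunConfig) -> tuple[int, dict]:
    """Execute a configured run.  Returns (exit status, manifest).

    Status 0 on success; 1 when a fit failed to converge (partial
    artifacts are retained and flagged in the manifest)."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "artifacts": {},
        "flags": [],
    }
    status = 0
    t0 = time.time()

    params = None
    truth_re = None
    if config.mode in ("simulate", "simulate-and-recover"):
        sim = config.simulate
        beta = {c: sim.get("beta", {}).get(c, [0.0, 0.0, 0.0]) for c in config.covariate_ids}
        params = default_true_parameters(beta=beta or None)
        data, truth_re, _ = simulate_panel(
            params,
            n=int(sim.get("n", 333)),
            missing_rate=float(sim.get("missing_rate", 0.0)),
            seed=config.seed,
        )
        panel_path = config.panel_path or outdir / "panel.csv"
        write_panel(data, panel_path)
        write_truth_sidecar(outdir / "truth.yaml", params, truth_re)
        manifest["artifacts"]["panel"] = str(panel_path)
        manifest["artifacts"]["truth"] = str(outdir / "truth.yaml")
        config.panel_path = panel_path
        config.item_ids = list(params.item_ids)
        log.info("simulated panel: %d persons, %.1fs", data.n_persons, time.time() - t0)
        if config.mode == "simulate":
            _write_manifest(outdir, manifest)
            return 0, manifest

    if config.panel_path is None or config.item_ids is None:
        raise ConfigError("fit requires paths.panel and model.items")
    data = load_panel(config.panel_path, config.item_ids, config.covariate_ids)
    report = validate_panel(data)
    (outdir / "validation.json").write_text(json.dumps(dataclasses.asdict(report), indent=2, default=str))
    manifest["artifacts"]["validation"] = str(outdir / "validation.json")

    settings = _settings(config)
    if config.anchor == "auto":
        t1 = time.time()
        spec0 = ModelSpec(item_ids=list(config.item_ids), anchor_item=config.item_ids[0])
        anchor, diag = psychometrics.select_anchor(data, spec0, settings, return_diagnostics=True)
        (outdir / "anchor_selection.json").write_text(
            json.dumps({"anchor": anchor, "clique": diag["clique"]}, indent=2)
        )
        manifest["artifacts"]["anchor_selection"] = str(outdir / "anchor_selection.json")
        log.info("anchor selection: %s (%.1fs)", anchor, time.time() - t1)
    else:
        anchor = config.anchor

    spec = ModelSpec(item_ids=list(config.item_ids), anchor_item=anchor)
    t1 = time.time()
    samples, summary = converge_and_rerun(data, spec, settings)
    log.info("unconditional fit: max PSR %.3f (%.1fs)", summary.max_psr, time.time() - t1)
    manifest["unconditional_max_psr"] = summary.max_psr
    if not summary.converged:
        manifest["flags"].append("unconditional fit did not converge")
        status = 1
    meas = measurement_report(samples)
    render_measurement_table(meas, outdir / "measurement_table.csv")
    render_structural_table(structural_summary(samples), outdir / "structural_table.csv")
    manifest["artifacts"]["measurement_table"] = str(outdir / "measurement_table.csv")
    manifest["artifacts"]["structural_table"] = str(outdir / "structural_table.csv")

    if config.covariate_ids and status == 0:
        spec_c = ModelSpec(item_ids=list(config.item_ids), anchor_item=anchor, covariate_ids=list(config.covariate_ids))
        t1 = time.time()
        samples_c, summary_c = converge_and_rerun(data, spec_c, settings)
        log.info("conditional fit: max PSR %.3f (%.1fs)", summary_c.max_psr, time.time() - t1)
        manifest["conditional_max_psr"] = summary_c.max_psr
        if not summary_c.converged:
            manifest["flags"].append("conditional fit did not converge")
            status = 1
        render_structural_table(structural_summary(samples_c), outdir / "conditional_table.csv")
        manifest["artifacts"]["conditional_table"] = str(outdir / "conditional_table.csv")

    if config.mode == "simulate-and-recover" and params is not None:
        rec = _recovery_report(samples, params)
        rec.to_csv(outdir / "recovery_report.csv", index=False)
        manifest["artifacts"]["recovery_report"] = str(outdir / "recovery_report.csv")

    _write_manifest(outdir, manifest)
    return status, manifest


def _recovery_report(samples, params) -> pd.DataFrame:
    """Compare generative truth to posterior intervals (structural block)."""
    sig = params.Sigma_b
    d = np.sqrt(np.diag(sig))
    truths = {
        "gamma_phi": params.gamma[1],
        "gamma_logvar": params.gamma[2],
        "var_eta_b": sig[0, 0],
        "var_phi": sig[1, 1],
        "var_logvar": sig[2, 2],
        "r_phi_eta": sig[0, 1] / (d[0] * d[1]),
        "r_zeta_eta": sig[0, 2] / (d[0] * d[2]),
        "r_phi_zeta": sig[1, 2] / (d[1] * d[2]),
    }
    rows = []
    for name, truth in truths.items():
        pooled = samples.pooled(name)
        lo, med, hi = np.percentile(pooled, [2.5, 50.0, 97.5])
        rows.append(
            {
                "parameter": name,
                "truth": float(truth),
                "posterior_median": float(med),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "covered": bool(lo <= truth <= hi),
            }
        )
    return pd.DataFrame(rows)


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    return RunConfig.from_dict(raw)
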