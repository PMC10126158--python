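"""End-to-end pipeline: synth -> qc -> fit -> cost -> bootstrap -> simulate.

``run_pipeline`` executes the stages named in the run config, writing tidy
CSV/JSON artifacts into the output directory.  Every artifact carries the
seed and a hash of the config that produced it, so any output can be
regenerated exactly.
"""
from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap as bt
from . import io as aio
from . import qc as qcmod
from . import simulate as sim
from . import stats as st
from . import synth as sy
from .growth import fit_logistic, time_to_threshold
from .types import FitConvergenceError, GrowthCurve

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "quantify_curves"]

STAGE_ORDER = ["synth", "qc", "fit", "cost", "bootstrap", "sweep", "compete"]


def quantify_curves(curves: list[GrowthCurve], threshold: float = 0.8,
                    ttt_mode: str = "nearest_sample") -> pd.DataFrame:
    """Fit every curve and derive (lag, growth rate, TTT) phenotypes.

    Curves whose fit fails or that never reach the threshold are kept in
    the table with ``qc_pass=False`` and a reason, never silently dropped.
    """
    rows = []
    for c in curves:
        row = {"colony_id": c.colony_id, "population": c.population,
               "plasmid_id": c.plasmid_id, "replicate_id": c.replicate_id,
               "lag_h": math.nan, "growth_rate_per_h": math.nan,
               "ttt_h": math.nan, "qc_pass": True, "qc_reason": ""}
        try:
            fit = fit_logistic(c)
        except (FitConvergenceError, ValueError) as exc:
            row.update(qc_pass=False, qc_reason=f"fit_failed: {exc}")
            rows.append(row)
            continue
        if not fit.converged:
            row.update(qc_pass=False, qc_reason="fit_not_converged")
            rows.append(row)
            continue
        ttt = time_to_threshold(c, threshold=threshold, mode=ttt_mode)
        if math.isnan(ttt):
            row.update(qc_pass=False, qc_reason="threshold_not_reached")
        else:
            row.update(lag_h=fit.lam, growth_rate_per_h=fit.mu_m, ttt_h=ttt)
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_synth(cfg: dict, out: Path, seed: int, meta: dict) -> dict:
    block = dict(cfg.get("synth", {}))
    plan = block.pop("artifacts", None)
    preset_name = block.pop("preset", None)
    if preset_name:
        synth_cfg = sy.PRESETS[preset_name].colony
        synth_cfg = type(synth_cfg)(**{**synth_cfg.__dict__, **block, "seed": seed})
    else:
        synth_cfg = sy.SynthConfig(**{**block, "seed": seed})
    ss = np.random.SeedSequence(seed)
    r_phen, r_curv, r_art = (np.random.default_rng(s) for s in ss.spawn(3))
    phen = sy.gen_phenotypes(synth_cfg, rng=r_phen)
    curves = sy.render_curves(phen, synth_cfg, rng=r_curv)
    manifest = {}
    if plan:
        curves, manifest = sy.inject_artifacts(curves, plan, rng=r_art)
    aio.write_curves(curves, out / "curves.csv", meta)
    aio.write_table(phen, out / "truth.csv", meta)
    (out / "artifact_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"curves": str(out / "curves.csv"), "truth": str(out / "truth.csv"),
            "artifact_manifest": str(out / "artifact_manifest.json")}


def _stage_qc(cfg: dict, out: Path, curves, meta: dict):
    block = cfg.get("qc", {}) or {}
    passed, report = qcmod.qc_filter(curves, **block)
    aio.write_curves(passed, out / "curves_qc.csv", meta)
    (out / "qc_report.json").write_text(json.dumps({
        "passed": report.passed_ids, "rejected": report.rejected,
        "spikes_closed": report.spikes_closed}, indent=2))
    return passed, {"curves_qc": str(out / "curves_qc.csv"),
                    "qc_report": str(out / "qc_report.json")}


def _stage_cost(phen: pd.DataFrame, out: Path, meta: dict):
    ok = phen[phen["qc_pass"]]
    results = []
    plasmids = sorted(ok["plasmid_id"].unique())
    n_comp = max(len(plasmids), 1)
    for pl in plasmids:
        sub = ok[ok["plasmid_id"] == pl]
        dn = sub.loc[sub["population"] == "de_novo", "ttt_h"].to_numpy()
        ad = sub.loc[sub["population"] == "adapted", "ttt_h"].to_numpy()
        if len(dn) == 0 or len(ad) == 0:
            logger.warning("plasmid %s lacks one population; skipped", pl)
            continue
        cost = st.acquisition_cost(dn, ad, plasmid_id=pl, n_comparisons=n_comp)
        dn_sub = sub[sub["population"] == "de_novo"]
        fit = st.regress(dn_sub["lag_h"], dn_sub["growth_rate_per_h"], plasmid_id=pl) \
            if len(dn_sub) >= 3 else None
        results.append((cost, fit))
    cost_df = pd.DataFrame([{
        "plasmid_id": c.plasmid_id, "cost": c.cost, "p_adjusted": c.p_value,
        "n_de_novo": c.n_de_novo, "n_adapted": c.n_adapted,
    } for c, _ in results])
    aio.write_table(cost_df, out / "costs.csv", meta)
    trade_rows = [{
        "plasmid_id": f.plasmid_id, "slope": f.slope, "slope_lo95": f.slope_ci95[0],
        "slope_hi95": f.slope_ci95[1], "rho": f.pearson_rho, "n": f.n,
    } for _, f in results if f is not None]
    aio.write_table(pd.DataFrame(trade_rows), out / "tradeoff.csv", meta)
    artifacts = {"costs": str(out / "costs.csv"), "tradeoff": str(out / "tradeoff.csv")}
    pairs = [(c, f) for c, f in results if f is not None]
    if len(pairs) >= 3:
        table, rho = st.cost_tradeoff_summary(pairs)
        aio.write_table(table, out / "cost_tradeoff_summary.csv", meta)
        artifacts["cost_tradeoff_summary"] = str(out / "cost_tradeoff_summary.csv")
        artifacts["cost_vs_slope_rho"] = rho
    return artifacts


def _stage_bootstrap(cfg: dict, out: Path, seed: int, meta: dict):
    block = dict(cfg.get("bootstrap", {}))
    observed_ci = block.pop("observed_slope_ci", None)
    hypotheses = block.pop("hypotheses", ["constrained", "unconstrained"])
    summary = {}
    frames = []
    for i, hyp in enumerate(hypotheses):
        res = bt.bootstrap_slopes(hyp, seed=seed + i, **block)
        frames.append(pd.DataFrame({"hypothesis": hyp,
                                    "round": np.arange(res.n_rounds),
                                    "slope": res.slopes}))
        entry = {"ci95": list(res.ci95), "mean_slope": res.mean_slope,
                 "n_clones": res.n_clones, "n_rounds": res.n_rounds}
        if observed_ci is not None:
            entry["overlaps_observed"] = bt.ci_overlap(tuple(observed_ci), res.ci95)
        summary[hyp] = entry
    aio.write_table(pd.concat(frames, ignore_index=True),
                    out / "bootstrap_slopes.csv", meta)
    (out / "bootstrap_summary.json").write_text(json.dumps(summary, indent=2))
    return {"bootstrap_slopes": str(out / "bootstrap_slopes.csv"),
            "bootstrap_summary": str(out / "bootstrap_summary.json")}


def _sim_config(block: dict, seed: int) -> sim.SimConfig:
    keys = {k: block[k] for k in
            ("K", "parents", "t_end", "dt_max", "n_iterations", "sample_dt")
            if k in block}
    return sim.SimConfig(seed=seed, **keys)


def _stage_sweep(cfg: dict, out: Path, seed: int, meta: dict):
    block = dict(cfg.get("sweep", {}))
    preset = sy.PRESETS[block.get("preset", "intermediate")]
    gen = sy.clone_set_generator(
        preset, population=block.get("population", "de_novo"),
        with_tradeoff=block.get("with_tradeoff", True),
        j_max=block.get("j_max", 10000))
    densities = block.get("initial_densities", (1e2, 1e3, 1e4, 1e5, 1e6))
    table = sim.density_sweep(gen, densities, _sim_config(block, seed))
    aio.write_table(table, out / "sweep.csv", meta)
    return {"sweep": str(out / "sweep.csv")}


def _stage_compete(cfg: dict, out: Path, seed: int, meta: dict):
    block = dict(cfg.get("compete", {}))
    pa = sy.PRESETS[block.get("preset_a", "intermediate")]
    pb = sy.PRESETS[block.get("preset_b", "high")]
    with_tradeoff = block.get("with_tradeoff", True)
    j_max = block.get("j_max", 10000)
    total = block.get("total_cells", 1e5)
    config = _sim_config(block, seed)
    gen_a_ad = sy.clone_set_generator(pa, "adapted", j_max=j_max)
    gen_b_ad = sy.clone_set_generator(pb, "adapted", j_max=j_max)
    ratio, achieved = sim.calibrate_ratio(gen_a_ad, gen_b_ad, total, config,
                                          tol=block.get("tol", 0.02))
    gen_a = sy.clone_set_generator(pa, "de_novo", with_tradeoff, j_max=j_max)
    gen_b = sy.clone_set_generator(pb, "de_novo", with_tradeoff, j_max=j_max)
    mean_frac, sd_frac, fracs = sim.compete(gen_a, gen_b, ratio, total, config)
    result = {"preset_a": pa.name, "preset_b": pb.name,
              "with_tradeoff": with_tradeoff,
              "calibrated_ratio_a_to_b": ratio,
              "calibration_achieved_fraction": achieved,
              "final_fraction_a_mean": mean_frac,
              "final_fraction_a_sd": sd_frac,
              "n_iterations": config.n_iterations}
    (out / "competition.json").write_text(json.dumps(result, indent=2))
    aio.write_table(pd.DataFrame({"iteration": np.arange(len(fracs)),
                                  "final_fraction_a": fracs}),
                    out / "competition_iterations.csv", meta)
    return {"competition": str(out / "competition.json")}


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages in order; returns an artifact manifest.

    Stage blocks present in ``config`` (synth, qc, fit, cost, bootstrap,
    sweep, compete) are run in the canonical order.  A global ``seed``
    drives every stochastic stage; each output embeds the seed and config
    hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    meta = {"seed": seed, "config_hash": aio.config_hash(config)}
    manifest: dict = {"seed": seed, "config_hash": meta["config_hash"]}

    stages = [s for s in STAGE_ORDER if s in config]
    curves = None
    phen = None
    for stage in stages:
        logger.info("running stage %s", stage)
        if stage == "synth":
            manifest["synth"] = _stage_synth(config, out, seed, meta)
            curves = aio.read_curves(manifest["synth"]["curves"])
        elif stage == "qc":
            if curves is None:
                curves = aio.read_curves(config["qc"].pop("input"))
            curves, art = _stage_qc(config, out, curves, meta)
            manifest["qc"] = art
        elif stage == "fit":
            if curves is None:
                curves = aio.read_curves((config.get("fit") or {}).pop("input"))
            fit_block = config.get("fit") or {}
            phen = quantify_curves(curves,
                                   threshold=fit_block.get("threshold", 0.8),
                                   ttt_mode=fit_block.get("ttt_mode", "nearest_sample"))
            aio.write_table(phen, out / "phenotypes.csv", meta)
            manifest["fit"] = {"phenotypes": str(out / "phenotypes.csv")}
        elif stage == "cost":
            if phen is None:
                raise ValueError("cost stage requires the fit stage (phenotypes)")
            manifest["cost"] = _stage_cost(phen, out, meta)
        elif stage == "bootstrap":
            manifest["bootstrap"] = _stage_bootstrap(config, out, seed, meta)
        elif stage == "sweep":
            manifest["sweep"] = _stage_sweep(config, out, seed, meta)
        elif stage == "compete":
            manifest["compete"] = _stage_compete(config, out, seed, meta)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
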