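"""End-to-end analysis pipeline and report tables.

``run_pipeline`` composes the whole workflow behind a single YAML config:
per-trait constant and epoch fits over a set of trees, likelihood profiles,
cross-trait cumulative support, the joint shift model, signal tests, ASR and
(optionally) the null-simulation study.  Outputs are deterministic functions
of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import epoch as epoch_mod
from . import mk_core, simstudy, simstudy_io, synthetic_data, treeio

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class ReportRow:
    trait: str
    delta_lnL: float
    delta_lnL_min: float
    delta_lnL_max: float
    shift_age_Ga: float
    shift_age_min: float
    shift_age_max: float
    log10_r01: float
    log10_r10: float
    lambda_hat: float
    lambda_min: float
    lambda_max: float
    signal_p: float
    epoch_vs_constant_delta_AIC: float


def summarize_over_trees(values: list[float]) -> tuple[float, float, float]:
    """(median, min, max) across per-tree results."""
    if not values:
        raise ValueError("no per-tree results to summarize")
    return (float(statistics.median(values)), float(min(values)),
            float(max(values)))


def _settings_from(cfg: dict) -> mk_core.FitSettings:
    s = cfg.get("settings", {})
    return mk_core.FitSettings(
        root_prior=s.get("root_prior", "flat"),
        n_restarts=int(s.get("n_restarts", 3)),
        seed=int(cfg.get("seed", 0)),
        missing_policy=s.get("missing_policy", "marginalize"))


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg.setdefault("schema_version", SCHEMA_VERSION)
    if cfg["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema {cfg['schema_version']}")
    return cfg


def run_pipeline(config_file: str, out_dir: str | None = None) -> Path:
    """Run the full analysis described by a YAML config; returns the report
    directory.  A resolved copy of the config is always written first."""
    cfg = load_config(config_file)
    out = Path(out_dir or cfg.get("output_dir", "epochmk_report"))
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    root_logger = logging.getLogger("epochmk")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    try:
        _run_stages(cfg, out)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return out


def _load_inputs(cfg: dict):
    settings = _settings_from(cfg)
    if "synthetic" in cfg:
        sy = cfg["synthetic"]
        sconf = synthetic_data.SynthConfig(
            n_tips=int(sy.get("n_tips", 32)),
            root_age=float(sy.get("root_age", 2.7)),
            tree_model=sy.get("tree_model", "yule"),
            n_sets=int(sy.get("n_sets", 2)),
            trees_per_set=int(sy.get("trees_per_set", 3)),
            bl_jitter_cv=float(sy.get("bl_jitter_cv", 0.05)),
            topo_moves=int(sy.get("topo_moves", 2)),
            n_traits=int(sy.get("n_traits", 5)),
            missing_frac=float(sy.get("missing_frac", 0.0)),
            seed=int(cfg.get("seed", 0)))
        base = synthetic_data.generate_chronogram(sconf)
        scenario = sy.get("scenario", "all_constant")
        if scenario == "shared_shift":
            sh = sy.get("shift", {})
            params = epoch_mod.EpochParams(
                base=mk_core.MkRates(float(sh.get("q01", 0.5)),
                                     float(sh.get("q10", 0.5))),
                t_shift=float(sh.get("t_shift", 0.6 * sconf.root_age)),
                r01=float(sh.get("r01", 0.2)), r10=float(sh.get("r10", 0.2)))
            scenario = ("shared_shift", params)
        traits, manifest = synthetic_data.generate_trait_matrix(
            base, sconf, scenario)
        tree_sets = synthetic_data.generate_pseudo_posterior(sconf, base)
        n_per_set = int(sy.get("analysis_trees_per_set", 2))
        analysis_trees = [t for ts in tree_sets[:2]
                          for t in list(ts)[:n_per_set]]
        return analysis_trees, tree_sets, traits, manifest, settings
    trees_cfg = cfg["trees"]
    tree_sets = [treeio.read_tree_set(p, format=trees_cfg.get("format",
                                                              "newick"))
                 for p in trees_cfg["files"]]
    analysis_trees = [t for ts in tree_sets
                      for t in list(ts)[:int(trees_cfg.get("per_set", 2))]]
    tm_cfg = cfg["traits"]
    traits = treeio.read_trait_matrix(tm_cfg["file"],
                                      format=tm_cfg.get("format", "csv"))
    return analysis_trees, tree_sets, traits, None, settings


def _run_stages(cfg: dict, out: Path) -> None:
    stage = "load"
    try:
        analysis_trees, tree_sets, traits, manifest, settings = \
            _load_inputs(cfg)
        if manifest is not None:
            synthetic_data.write_manifest(manifest, str(out / "manifest.json"))
        traits.to_csv(str(out / "traits.csv"))

        names = [c for c in traits.traits
                 if traits.column_types.get(c, "binary") == "binary"]
        n_grid = int(cfg.get("n_grid", 38))

        stage = "per_trait"
        rows, profiles = [], []
        for nm in names:
            per_tree = []
            for k, tree in enumerate(analysis_trees):
                tr, tm = treeio.match_tree_and_traits(tree, traits,
                                                      "intersect")
                col = tm.binary_column(nm)
                const = mk_core.fit_mk(tr, col, "Mk2", settings)
                ef = epoch_mod.fit_epoch(tr, col, settings, "free", n_grid,
                                         constant_fit=const)
                lam = mk_core.phylo_signal_test(tr, col, settings)
                logger.info("trait=%s tree=%d lnL=%.4f dlnL=%.4f conv=%s",
                            nm, k, ef.lnL, ef.delta_lnL_vs_constant,
                            ef.converged)
                per_tree.append((ef, lam))
                if k == 0:
                    profiles.append(epoch_mod.profile_scan(
                        tr, col, settings, n_grid, constant_fit=const))
            d_med, d_min, d_max = summarize_over_trees(
                [e.delta_lnL_vs_constant for e, _ in per_tree])
            a_med, a_min, a_max = summarize_over_trees(
                [e.params.t_shift for e, _ in per_tree])
            l_med, l_min, l_max = summarize_over_trees(
                [l.lambda_hat for _, l in per_tree])
            mid = per_tree[0]
            rows.append(ReportRow(
                trait=nm, delta_lnL=d_med, delta_lnL_min=d_min,
                delta_lnL_max=d_max, shift_age_Ga=a_med, shift_age_min=a_min,
                shift_age_max=a_max, log10_r01=mid[0].log10_r01,
                log10_r10=mid[0].log10_r10, lambda_hat=l_med,
                lambda_min=l_min, lambda_max=l_max,
                signal_p=mid[1].p_value,
                epoch_vs_constant_delta_AIC=mid[0].delta_AIC_vs_constant))
        pd.DataFrame([asdict(r) for r in rows]).to_csv(
            out / "per_trait_report.csv", index=False, float_format="%.6g")

        stage = "profiles"
        prof_tab = pd.DataFrame(
            {"age": profiles[0].grid,
             **{p_nm: p.delta_lnL for p_nm, p in zip(names, profiles)}})
        prof_tab.to_csv(out / "profiles.csv", index=False,
                        float_format="%.6g")
        cum = epoch_mod.cumulative_support(profiles,
                                           float(cfg.get("threshold", 6.0)))
        pd.DataFrame({"age": cum.grid, "summed": cum.summed_support,
                      "thresholded": cum.thresholded_support}).to_csv(
            out / "cumulative_support.csv", index=False, float_format="%.6g")

        stage = "joint"
        tr, tm = treeio.match_tree_and_traits(analysis_trees[0], traits,
                                              "intersect")
        joint = epoch_mod.fit_joint(
            tr, tm, settings,
            multiplier_mode=cfg.get("multiplier_mode", "shared_pair"),
            n_grid=n_grid)
        with open(out / "joint_fit.json", "w") as fh:
            json.dump({
                "shared_t_shift": joint.shared_t_shift,
                "shared_r01": joint.shared_r01,
                "shared_r10": joint.shared_r10,
                "lnL_total": joint.lnL_total,
                "n_params": joint.n_params,
                "AIC": joint.AIC,
                "delta_AIC_vs_no_shift": joint.delta_AIC_vs_no_shift,
                "multiplier_mode": joint.multiplier_mode,
                "root_prior": str(settings.root_prior),
                "per_trait_base": {nm: [r.q01, r.q10] for nm, r in
                                   joint.per_trait_base.items()},
            }, fh, indent=2)

        stage = "asr"
        asr_rows = []
        for nm in names[:int(cfg.get("asr_traits", 3))]:
            col = tm.binary_column(nm)
            const = mk_core.fit_mk(tr, col, "Mk2", settings)
            ef = epoch_mod.fit_epoch(tr, col, settings, "free", n_grid,
                                     constant_fit=const)
            best = ef if ef.delta_AIC_vs_constant > 0 else None
            marg = (epoch_mod.epoch_asr(tr, col, ef, settings) if best
                    else mk_core.marginal_asr(tr, col, const.rates, settings))
            for node, (p0, p1) in marg.items():
                asr_rows.append({"trait": nm, "node": node,
                                 "age": tr.age[node],
                                 "model": "epoch" if best else "constant",
                                 "P0": p0, "P1": p1})
        pd.DataFrame(asr_rows).to_csv(out / "asr.csv", index=False,
                                      float_format="%.6g")

        stage = "simstudy"
        if cfg.get("simstudy", {}).get("enabled", False):
            ss = cfg["simstudy"]
            sconfig = simstudy.SimStudyConfig(
                tree_pool=tree_sets,
                n_replicates=int(ss.get("n_replicates", 20)),
                seed=int(cfg.get("seed", 0)),
                profile_grid=n_grid,
                run_profiles=bool(ss.get("run_profiles", False)))
            reps, summary = simstudy.run_null_study(
                sconfig, settings, traits=traits)
            simstudy.replicates_to_frame(reps).to_csv(
                out / "simstudy_replicates.csv", index=False,
                float_format="%.6g")
            simstudy_io.summary_to_json(summary,
                                        str(out / "simstudy_summary.json"))
    except Exception:
        logger.error("failed in stage %s", stage)
        raise
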