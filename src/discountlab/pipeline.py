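"""End-to-end orchestration: simulate/load a study, fit curves and mixed
models, compute model-based AUC, run the scalar statistics and the anxiety
path analyses, and write a reproducible report bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import PopulationParams, StudyTables, generate_study
from .curves import fit_curve, model_auc
from .inference import (
    SummaryStats,
    jzs_correlation_bf,
    paired_signed_rank,
    pearson_with_test,
    reward_sensitivity,
    welch_t_from_summary,
)
from .lmm import compare_lmm, fit_lmm, fit_pleasantness, nakagawa_r2, prepare_lmm_dataset
from .paths import (
    NO_MEDIATION,
    WITH_MEDIATION,
    fit_indices,
    fit_path,
    indirect_effect,
    moderation_regression,
    split_half_groups,
)
from .task import EXPERIENTIAL, HYPOTHETICAL, TaskConfig, TaskKind

log = logging.getLogger("discountlab")

__all__ = [
    "STAI_FEMALE_COLLEGE_STATE",
    "STAI_FEMALE_COLLEGE_TRAIT",
    "participant_curve_fits",
    "auc_table",
    "lmm_report",
    "stats_report",
    "path_report",
    "run_pipeline",
    "make_fixtures",
]

#: Normative female college sample summaries of the state/trait inventory.
STAI_FEMALE_COLLEGE_STATE = SummaryStats(mean=38.8, sd=12.0, n=481)
STAI_FEMALE_COLLEGE_TRAIT = SummaryStats(mean=40.4, sd=10.2, n=531)

_CONFIGS = {TaskKind.EXPERIENTIAL.value: EXPERIENTIAL,
            TaskKind.HYPOTHETICAL.value: HYPOTHETICAL}


def _normalized_points(sub: pd.DataFrame, config: TaskConfig):
    sv = sub["value"].to_numpy(float) / config.delayed_value
    sv_norm = (np.clip(sv, config.sv_min, 1.0) - config.sv_min) / (1.0 - config.sv_min)
    return sub["delay"].to_numpy(float), sv_norm


def participant_curve_fits(points: pd.DataFrame,
                           models: tuple[str, ...] = ("hyperbolic", "logistic2"),
                           ) -> pd.DataFrame:
    """Least-squares fits per participant, task and model (both staircase
    runs enter as separate observations)."""
    rows = []
    for (pid, kind), sub in points.groupby(["participant_id", "task_kind"]):
        config = _CONFIGS[kind]
        delays, sv_norm = _normalized_points(sub, config)
        for model in models:
            fit = fit_curve(delays, sv_norm, model=model)
            rows.append({
                "participant_id": pid, "task_kind": kind, "model": model,
                "k": fit.k, "a": fit.a, "b": fit.b, "c": fit.c,
                "rmse": fit.rmse, "r2": fit.r2, "n_points": fit.n_points,
                "converged": fit.converged,
            })
    return pd.DataFrame(rows)


def auc_table(points: pd.DataFrame) -> pd.DataFrame:
    """Model-based AUC per participant and task from the logistic-2 fit."""
    rows = []
    for (pid, kind), sub in points.groupby(["participant_id", "task_kind"]):
        config = _CONFIGS[kind]
        delays, sv_norm = _normalized_points(sub, config)
        fit = fit_curve(delays, sv_norm, model="logistic2")
        rows.append({
            "participant_id": pid, "task_kind": kind,
            "auc": model_auc(fit, config.delays[0], config.delays[-1]),
            "a": fit.a, "b": fit.b,
        })
    return pd.DataFrame(rows)


def lmm_report(points: pd.DataFrame, task_kind: str,
               boundary: str = "drop") -> dict[str, Any]:
    """Null vs hyperbolic vs logistic mixed-model comparison for one task."""
    config = _CONFIGS[task_kind]
    sub = points[points["task_kind"] == task_kind]
    data = prepare_lmm_dataset(sub, config, boundary=boundary)
    fits = {m: fit_lmm(data, m) for m in ("null", "hyperbolic", "logistic")}
    comp_rows = []
    for name, fit in fits.items():
        marg, cond = nakagawa_r2(fit)
        comp_rows.append({
            "model": name, "loglik": fit.loglik, "n_params": fit.n_params,
            "aic": fit.aic, "bic": fit.bic,
            "marginal_r2": marg, "conditional_r2": cond,
            **{f"fixed_{k}": v for k, v in fit.fixed_effects.items()},
            **{f"se_{k}": v for k, v in fit.fixed_se.items()},
        })
    lrt_rows = []
    for m0, m1 in (("null", "hyperbolic"), ("hyperbolic", "logistic")):
        lrt = compare_lmm(fits[m0], fits[m1])
        lrt_rows.append({"model0": m0, "model1": m1, "chi2": lrt.chi2,
                         "df": lrt.df, "p": lrt.p, "note": lrt.note})
    return {"fits": fits, "comparison": pd.DataFrame(comp_rows),
            "lrt": pd.DataFrame(lrt_rows), "n_obs": fits["null"].n_obs}


def stats_report(tables: StudyTables, aucs: pd.DataFrame,
                 fits: pd.DataFrame) -> dict[str, Any]:
    """Scalar statistics: AUC correlation + Bayes factor, normative Welch
    comparisons, paired signed-rank on per-participant R2, reward
    sensitivity distribution."""
    wide = aucs.pivot(index="participant_id", columns="task_kind", values="auc")
    if len(wide) >= 4:
        r, t, p = pearson_with_test(wide["experiential"], wide["hypothetical"])
        bf = jzs_correlation_bf(r, len(wide))
        auc_corr = {"r": r, "t": t, "p": p, "bf10": bf.bf10,
                    "posterior_median_r": bf.posterior_median_r}
    else:
        auc_corr = {"skipped": f"insufficient n ({len(wide)} < 4)"}

    part = tables.participants
    welch_state = welch_t_from_summary(
        SummaryStats(part["state_anxiety"].mean(), part["state_anxiety"].std(ddof=1),
                     len(part)), STAI_FEMALE_COLLEGE_STATE)
    welch_trait = welch_t_from_summary(
        SummaryStats(part["trait_anxiety"].mean(), part["trait_anxiety"].std(ddof=1),
                     len(part)), STAI_FEMALE_COLLEGE_TRAIT)

    r2_wide = (fits[fits["model"] == "logistic2"]
               .pivot(index="participant_id", columns="task_kind", values="r2"))
    if len(r2_wide) >= 5:
        v_stat, v_p = paired_signed_rank(r2_wide["experiential"],
                                         r2_wide["hypothetical"])
        signed_rank = {"V": v_stat, "p": v_p}
    else:
        signed_rank = {"skipped": f"insufficient n ({len(r2_wide)} < 5)"}

    sens = (tables.ratings.groupby("participant_id")
            .apply(lambda g: reward_sensitivity(g)[0], include_groups=False)
            .rename("reward_sensitivity").reset_index())
    return {
        "auc_correlation": auc_corr,
        "welch_state_vs_norm": asdict(welch_state),
        "welch_trait_vs_norm": asdict(welch_trait),
        "signed_rank_r2": signed_rank,
        "reward_sensitivity": sens,
        "reward_sensitivity_mean": float(sens["reward_sensitivity"].mean()),
        "state_trait_r": pearson_with_test(part["state_anxiety"],
                                           part["trait_anxiety"])[0],
    }


def path_report(tables: StudyTables, aucs: pd.DataFrame,
                sensitivity: pd.DataFrame) -> dict[str, Any]:
    """Both anxiety path models, the moderation regression and split-half."""
    wide = aucs.pivot(index="participant_id", columns="task_kind", values="auc")
    data = (tables.participants[["participant_id", "state_anxiety", "trait_anxiety"]]
            .merge(sensitivity, on="participant_id")
            .merge(wide.rename(columns={"experiential": "auc_experiential",
                                        "hypothetical": "auc_hypothetical"}),
                   on="participant_id"))
    out: dict[str, Any] = {"data": data}
    fit0 = fit_path(data, NO_MEDIATION)
    fit1 = fit_path(data, WITH_MEDIATION)
    out["no_mediation"] = {"fit": fit0, "indices": fit_indices(fit0)}
    ind = indirect_effect(fit1, "state_anxiety", "reward_sensitivity",
                          "auc_experiential")
    out["with_mediation"] = {"fit": fit1, "indices": fit_indices(fit1),
                             "indirect_state": ind}
    out["moderation"] = moderation_regression(
        data["auc_experiential"], data["state_anxiety"], data["trait_anxiety"])
    out["split_half"] = split_half_groups(
        data["trait_anxiety"], data["auc_experiential"], data["state_anxiety"])
    return out


def _path_fit_json(entry) -> dict:
    fit = entry["fit"]
    cfi, rmsea, srmr = entry["indices"]
    return {
        "paths": [
            {"outcome": o, "regressor": x, "estimate": fit.estimates[(o, x)],
             "se": fit.se[(o, x)], "p": fit.p_values[(o, x)],
             "std_all": fit.std_estimates[(o, x)],
             "std_x": fit.std_x_estimates[(o, x)]}
            for (o, x) in fit.estimates
        ],
        "r2": fit.r2, "df": fit.df, "loglik": fit.loglik,
        "cfi": cfi, "rmsea": rmsea, "srmr": srmr,
        **({"indirect_state": dict(zip(("estimate", "se", "p"),
                                       entry["indirect_state"]))}
           if "indirect_state" in entry else {}),
    }


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Execute simulate -> elicit -> fit -> lmm -> auc -> stats -> paths.

    ``config`` is a dict (or YAML path) with either a ``population`` section
    (synthetic mode) or a ``tables`` section of CSV paths (data mode), plus
    an optional top-level ``seed``.  Writes the report bundle under
    ``out_dir`` and returns the in-memory results.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    known = {"population", "tables", "seed", "boundary"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    boundary = config.get("boundary", "drop")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate/load")
    if "population" in config:
        pop = PopulationParams(**{**config["population"], "seed": seed})
        tables = generate_study(pop, seed=seed)
    else:
        paths = config["tables"]
        tables = StudyTables(
            participants=pd.read_csv(paths["participants"]),
            trials=pd.read_csv(paths["trials"]) if "trials" in paths else pd.DataFrame(
                columns=["participant_id"]),
            points=pd.read_csv(paths["points"]),
            ratings=pd.read_csv(paths["ratings"]),
        )
    tables.validate()
    tables.write_csvs(out / "tables")

    log.info("stage curve fits")
    fits = participant_curve_fits(tables.points)
    fits.to_csv(out / "curve_fits.csv", index=False)

    log.info("stage auc")
    aucs = auc_table(tables.points)
    aucs.to_csv(out / "auc.csv", index=False)

    log.info("stage mixed models")
    lmm_out = {}
    for kind in ("experiential", "hypothetical"):
        rep = lmm_report(tables.points, kind, boundary=boundary)
        rep["comparison"].to_csv(out / f"lmm_comparison_{kind}.csv", index=False)
        rep["lrt"].to_csv(out / f"lmm_lrt_{kind}.csv", index=False)
        lmm_out[kind] = rep
    pleas = fit_pleasantness(tables.ratings, random_slope=True)
    pleas_null = fit_pleasantness(tables.ratings, null=True)

    log.info("stage stats")
    stats_out = stats_report(tables, aucs, fits)

    log.info("stage paths")
    n = len(tables.participants)
    n_min = max(10, WITH_MEDIATION.n_free_params() + 1)
    if n >= n_min:
        paths_out = path_report(tables, aucs, stats_out["reward_sensitivity"])
        paths_json = {"no_mediation": _path_fit_json(paths_out["no_mediation"]),
                      "with_mediation": _path_fit_json(paths_out["with_mediation"]),
                      "moderation": paths_out["moderation"].to_dict("records"),
                      "split_half": paths_out["split_half"].to_dict("records")}
    else:
        paths_out = None
        paths_json = {"skipped": f"insufficient n ({n} < {n_min}) for path analysis"}
        log.warning("path analysis skipped: insufficient n")

    stats_json = {k: v for k, v in stats_out.items() if k != "reward_sensitivity"}
    pleas_lrt = compare_lmm(pleas_null, pleas)
    stats_json["pleasantness_lmm"] = {
        "fixed_occlusion_slope": pleas.fixed_effects.get("occlusion_level"),
        "se": pleas.fixed_se.get("occlusion_level"),
        "aic": pleas.aic, "bic": pleas.bic,
        "null_aic": pleas_null.aic,
        "lrt_chi2": pleas_lrt.chi2, "lrt_df": pleas_lrt.df, "lrt_p": pleas_lrt.p,
    }
    (out / "stats.json").write_text(json.dumps(stats_json, indent=2, default=float))
    (out / "paths.json").write_text(json.dumps(paths_json, indent=2, default=float))

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "config": config,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"tables": tables, "curve_fits": fits, "auc": aucs, "lmm": lmm_out,
            "pleasantness": pleas, "stats": stats_out, "paths": paths_out,
            "manifest": manifest}


def make_fixtures(seed: int = 7, out_dir: str | Path | None = None) -> StudyTables:
    """Small deterministic fixture study (3 agents, both tasks, ratings)."""
    pop = PopulationParams(n=3, seed=seed, tau=0.0)
    tables = generate_study(pop, seed=seed)
    if out_dir is not None:
        tables.write_csvs(out_dir)
    return tables
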