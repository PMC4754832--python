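"""End-to-end orchestration: simulate -> clump -> score -> prepare -> gxe -> power.

A run is driven by a YAML config with one block per stage; unknown keys are
errors (catches parameter typos).  One global seed deterministically derives
per-stage seeds, and every output table carries '#' metadata headers with
the config hash and seed, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import gxe, io, scoring
from .clump import DEFAULT_THRESHOLD_GRID, ClumpParams, clump, validate_threshold_grid
from .power import PowerScenario, estimate_power
from .simulate import N_CTQ_ITEMS, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "clump", "score", "prepare", "gxe", "power")

_PREPARE_KEYS = {"n_pcs", "bdi_threshold", "ctq_cutpoints", "ctq_max_missing"}
_GXE_KEYS = {"models", "environments", "B", "m", "alpha", "ge_subset", "sensitivity", "fig3_threshold"}
_TOP_KEYS = {"seed", "out_dir", "stages", "simulate", "clump", "thresholds", "prepare", "gxe", "power"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    _check_keys(cfg, _TOP_KEYS, "top level")
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    _check_keys(cfg.get("simulate", {}) or {}, sim_fields - {"seed"}, "simulate")
    _check_keys(cfg.get("clump", {}) or {}, {f.name for f in dataclasses.fields(ClumpParams)}, "clump")
    _check_keys(cfg.get("prepare", {}) or {}, _PREPARE_KEYS, "prepare")
    _check_keys(cfg.get("gxe", {}) or {}, _GXE_KEYS, "gxe")
    for i, sc in enumerate(cfg.get("power", []) or []):
        _check_keys(sc, {f.name for f in dataclasses.fields(PowerScenario)} - {"seed"}, f"power[{i}]")
    stages = cfg.get("stages", list(ALL_STAGES))
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, ALL_STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def run_pipeline(cfg: dict, out_dir=None, seed: int | None = None) -> dict:
    """Execute the requested stages in dependency order.

    Returns a run report: per-stage record counts and output paths.  A
    stage failure propagates with the stage named.
    """
    cfg = validate_config(dict(cfg))
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(out_dir or cfg.get("out_dir", "prsgxe_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages", ALL_STAGES))
    meta = {"config_hash": io.config_hash(sorted(cfg.items(), key=str)), "seed": seed}
    report: dict = {"out_dir": str(out), "stages": {}}
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        try:
            counts = _STAGE_FNS[stage](cfg, state, out, seed, meta)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        report["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)
    return report


def _stage_simulate(cfg, state, out, seed, meta):
    sim_cfg = SimulationConfig(seed=_stage_seed(seed, "simulate"), **(cfg.get("simulate") or {}))
    cohort = simulate_cohort(sim_cfg)
    state["cohort"] = cohort
    io.write_sumstats(cohort.sumstats, out / "sumstats.tsv", meta)
    io.write_dosage_raw(cohort.panel, out / "dosages.raw", meta)
    io.write_bim(cohort.panel, out / "panel.bim")
    io.write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv", meta)
    io.write_environment(cohort.environment, out / "environment.tsv", meta)
    return {"n_samples": cohort.panel.n_samples, "n_snps": cohort.panel.n_snps}


def _load_cohort_tables(state, out):
    if "cohort" in state:
        c = state["cohort"]
        return c.panel, c.sumstats, c.phenotypes, c.environment
    bim = io.read_bim(out / "panel.bim")
    panel = io.read_dosage_raw(out / "dosages.raw", bim=bim)
    sumstats = io.read_sumstats(out / "sumstats.tsv")
    pheno = io.read_table(out / "phenotypes.tsv")
    env = io.read_table(out / "environment.tsv")
    return panel, sumstats, pheno, env


def _stage_clump(cfg, state, out, seed, meta):
    panel, sumstats, _, _ = _load_cohort_tables(state, out)
    params = ClumpParams(**(cfg.get("clump") or {}))
    grid = validate_threshold_grid(cfg.get("thresholds", DEFAULT_THRESHOLD_GRID))
    idx = clump(sumstats, panel, params)
    state["clump_index"] = idx
    retained = sumstats[sumstats["snp"].isin(idx.retained)].reset_index(drop=True)
    state["retained"] = retained

    report = pd.DataFrame(
        {
            "index_snp": list(idx.clump_members),
            "n_members": [len(v) for v in idx.clump_members.values()],
            "members": [",".join(v) if v else "" for v in idx.clump_members.values()],
        }
    )
    io.write_table(report, out / "clump_report.tsv", meta)
    rows = []
    for p_t in grid:
        for s in sorted(retained.loc[retained["p"] < p_t, "snp"]):
            rows.append((p_t, s))
    io.write_table(pd.DataFrame(rows, columns=["p_t", "snp"]), out / "threshold_subsets.tsv", meta)
    return {"n_index": len(idx.clump_members), "n_retained": len(idx.retained)}


def _stage_score(cfg, state, out, seed, meta):
    panel, sumstats, _, _ = _load_cohort_tables(state, out)
    if "retained" not in state:
        subs = io.read_table(out / "threshold_subsets.tsv")
        keep = set(subs["snp"].astype(str))
        # the widest threshold reproduces the retained set at p < max(grid);
        # SNPs above it are re-included from the clump report survivors
        state["retained"] = sumstats[sumstats["snp"].isin(keep)].reset_index(drop=True)
    grid = validate_threshold_grid(cfg.get("thresholds", DEFAULT_THRESHOLD_GRID))
    weights = scoring.align_alleles(sumstats, panel)
    scores = scoring.score_grid(panel, weights, state["retained"], grid)
    state["scores"] = scores
    io.write_table(scores.to_frame(), out / "scores.tsv", meta)
    io.write_table(
        pd.DataFrame({"p_t": grid, "n_snps": scores.snp_counts}),
        out / "score_snp_counts.tsv",
        meta,
    )
    return {"thresholds": len(grid), "snps_at_max": scores.snp_counts[-1]}


def _stage_prepare(cfg, state, out, seed, meta):
    panel, _, pheno, env = _load_cohort_tables(state, out)
    pc = cfg.get("prepare") or {}
    k = int(pc.get("n_pcs", 2))
    cutpoints = tuple(pc.get("ctq_cutpoints", cov.DEFAULT_CTQ_CUTPOINTS))
    max_missing = float(pc.get("ctq_max_missing", 0.10))

    pcs = cov.compute_pcs(panel, k=k)
    table = pd.concat([pheno.reset_index(drop=True), pcs], axis=1)
    table = cov.impute_missing_age(table)
    case = table["case"].to_numpy()
    env2 = cov.adjust_sle_counts(env, table, case)
    items = env2[[f"ctq_item_{j + 1}" for j in range(N_CTQ_ITEMS)]].to_numpy(dtype=float)
    total, category = cov.ctq_score(items, cutpoints=cutpoints, max_missing_frac=max_missing)
    env2["ctq_total"] = total
    env2["ct_category"] = category
    state["covariates"] = table
    state["environment_prepared"] = env2
    io.write_table(table, out / "covariates.tsv", meta)
    io.write_table(env2, out / "environment_prepared.tsv", meta)
    return {"n_pcs": k, "n_ct_observed": int(np.isfinite(total).sum())}


def _prepare_inputs(cfg, state, out):
    if "covariates" not in state:
        state["covariates"] = io.read_table(out / "covariates.tsv")
        state["environment_prepared"] = io.read_table(out / "environment_prepared.tsv")
    if "scores" not in state:
        sdf = io.read_table(out / "scores.tsv")
        thresholds = validate_threshold_grid(cfg.get("thresholds", DEFAULT_THRESHOLD_GRID))
        raw = np.column_stack([sdf[f"prs_raw_{t:g}"] for t in thresholds])
        std = np.column_stack([sdf[f"prs_std_{t:g}"] for t in thresholds])
        counts = io.read_table(out / "score_snp_counts.tsv")["n_snps"].tolist()
        state["scores"] = scoring.ScoreMatrix(
            sample_ids=sdf["sample_id"].to_numpy(),
            thresholds=thresholds,
            raw=raw,
            std=std,
            snp_counts=counts,
        )
    return state["covariates"], state["environment_prepared"], state["scores"]


def _stage_gxe(cfg, state, out, seed, meta):
    table, env2, scores = _prepare_inputs(cfg, state, out)
    gc = dict(cfg.get("gxe") or {})
    sensitivity = gc.pop("sensitivity", True)
    fig3_t = gc.pop("fig3_threshold", 0.05)
    if "models" in gc:
        gc["models"] = tuple(gc["models"])
    if "environments" in gc:
        gc["environments"] = tuple(gc["environments"])
    plan = gxe.AnalysisPlan(
        grid=validate_threshold_grid(cfg.get("thresholds", DEFAULT_THRESHOLD_GRID)),
        seed=_stage_seed(seed, "gxe"),
        **gc,
    )
    pc_cols = [c for c in table.columns if c.startswith("PC")]
    pcs = table[pc_cols].to_numpy(dtype=float)
    y = table["case"].to_numpy(dtype=float)
    envs = {name: env2[name].to_numpy(dtype=float) for name in plan.environments}

    results = gxe.run_threshold_grid(plan, scores, pcs, y, envs)
    io.write_table(results, out / "gxe_results.tsv", meta)

    if "ct_category" in env2.columns and fig3_t in scores.thresholds:
        fig3 = gxe.figure_logodds_by_category(
            y, scores.std_col(fig3_t), env2["ct_category"].to_numpy()
        )
        io.write_table(fig3, out / "fig3_logodds_by_ct_category.tsv", meta)

    counts = {"n_results": len(results)}
    if sensitivity:
        bdi_thr = float((cfg.get("prepare") or {}).get("bdi_threshold", 29))
        bdi = table["bdi"].to_numpy(dtype=float)

        def rerun(keep):
            envs_k = {k2: v[keep] for k2, v in envs.items()}
            return gxe.run_threshold_grid(plan, _subset_scores(scores, keep), pcs[keep], y[keep], envs_k)

        sens = gxe.sensitivity_exclude_depressed(rerun, bdi, y == 1, bdi_threshold=bdi_thr)
        io.write_table(sens, out / "gxe_results_sensitivity.tsv", meta)
        counts["n_results_sensitivity"] = len(sens)
    return counts


def _subset_scores(scores: scoring.ScoreMatrix, keep: np.ndarray) -> scoring.ScoreMatrix:
    return scoring.ScoreMatrix(
        sample_ids=scores.sample_ids[keep],
        thresholds=scores.thresholds,
        raw=scores.raw[keep],
        std=scores.std[keep],
        snp_counts=scores.snp_counts,
    )


def _stage_power(cfg, state, out, seed, meta):
    rows = []
    for i, sc in enumerate(cfg.get("power", []) or []):
        scenario = PowerScenario(seed=_stage_seed(seed, "power") + i, **sc)
        p, mcse = estimate_power(scenario)
        rows.append(
            {
                "n_cases": scenario.n_cases,
                "n_controls": scenario.n_controls,
                "or_g": scenario.or_g,
                "or_e": scenario.or_e,
                "or_gxe": scenario.or_gxe,
                "env_prevalence": scenario.env_prevalence,
                "alpha": scenario.alpha,
                "n_reps": scenario.n_reps,
                "power": p,
                "mc_se": mcse,
            }
        )
    df = pd.DataFrame(rows)
    io.write_table(df, out / "power.tsv", meta)
    return {"n_scenarios": len(rows)}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "clump": _stage_clump,
    "score": _stage_score,
    "prepare": _stage_prepare,
    "gxe": _stage_gxe,
    "power": _stage_power,
}
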