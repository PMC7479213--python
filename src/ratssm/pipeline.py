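"""End-to-end orchestration: simulate or load a cohort, run the SSM ->
selection -> bootstrap -> behavior -> statistics chain, write a report.

The pipeline config is a plain mapping (usually loaded from YAML):

.. code-block:: yaml

    seed: 0
    simulate:              # either this block ...
      n_young: 10
      n_aged: 10
    # inputs:              # ... or explicit paths
    #   volumes: [gm_a.nii.gz, ...]
    #   mask: mask.nii.gz
    #   subjects: subjects.csv
    #   trials: trials.csv
    #   geometry: pool_geometry.json
    smoothing_fwhm_um: 0   # 0 = volumes are already smoothed
    selection: {max_components: 8, max_subset_size: 4}
    bootstrap: {n_iter: 500, z_threshold: 3.5, extent: 50, connectivity: 1}

Simulated cohorts are round-tripped through disk (NIfTI/CSV) so the file
readers are on the executed path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behavior_table, load_trials
from .bootstrap import bootstrap_pattern, extract_extrema
from .data import load_stack, save_volume
from .preprocess import gaussian_smooth
from .selection import covariate_adjusted_test, select_components
from .ssm import SSMPCA
from .stats import (mann_whitney, mixed_ancova, score_behavior_regression,
                    shapiro_wilk_gate)
from .synthetic import CohortConfig, write_cohort

__all__ = ["run_full_pipeline", "load_config"]

logger = logging.getLogger("ratssm")

_STAGES = ("inputs", "ssm", "selection", "bootstrap", "behavior", "stats",
           "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _simulate_inputs(config: dict, seed: int, out: Path) -> dict:
    sim_kwargs = dict(config.get("simulate") or {})
    sim_kwargs.setdefault("seed", seed)
    cohort_cfg = CohortConfig(**sim_kwargs)
    paths = write_cohort(cohort_cfg, out / "cohort")
    return paths


def run_full_pipeline(config: dict | str | Path, out_dir: str | Path,
                      seed: int | None = None) -> dict:
    """Execute every analysis stage and write the report bundle.

    Returns a dict with the in-memory results (``ssm``, ``selection``,
    ``bootstrap``, ``behavior``, ``stats``) plus the paths written. Any stage
    failure aborts with the stage name.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.get("log_level", "INFO"))
    bundle: dict[str, Any] = {"out_dir": str(out), "seed": seed}

    try:
        stage = "inputs"
        logger.info("ratssm %s starting, seed=%d", __version__, seed)
        if "simulate" in config or "inputs" not in config:
            paths = _simulate_inputs(config, seed, out)
            logger.info("simulated cohort written under %s", out / "cohort")
        else:
            paths = dict(config["inputs"])
        stack, subjects = load_stack(paths["volumes"], paths["mask"],
                                     paths["subjects"])
        fwhm = float(config.get("smoothing_fwhm_um", 0) or 0)
        if fwhm > 0:
            smoothed = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for i in range(stack.n_subjects):
                    vol = gaussian_smooth(stack.unmask(stack.data[i]),
                                          fwhm, stack.voxel_size_um)
                    smoothed.append(vol[stack.mask])
            stack = dataclasses.replace(stack, data=np.vstack(smoothed))
            logger.info("smoothed volumes with FWHM %.0f um", fwhm)

        stage = "ssm"
        ssm_res = SSMPCA(stack).fit()
        logger.info("SSM: %d components, comp-1 variance fraction %.3f",
                    ssm_res.n_components, ssm_res.variance_fraction[0])
        bundle["ssm"] = ssm_res

        stage = "selection"
        sel_cfg = config.get("selection") or {}
        sel = select_components(
            ssm_res,
            max_components=int(sel_cfg.get("max_components", 8)),
            max_subset_size=int(sel_cfg.get("max_subset_size", 4)),
        )
        if "etiv" in subjects.columns:
            sel.covariate_test = covariate_adjusted_test(
                stack.group_indicator(), sel.composite_scores,
                subjects["etiv"].to_numpy(),
            )
        logger.info("selection: subset %s, R^2 = %.3f", sel.subset, sel.r_squared)
        bundle["selection"] = sel

        stage = "bootstrap"
        bs_cfg = config.get("bootstrap") or {}
        boot = bootstrap_pattern(
            stack, sel,
            n_iter=int(bs_cfg.get("n_iter", 500)),
            seed=seed,
            z_threshold=float(bs_cfg.get("z_threshold", 3.5)),
            extent=int(bs_cfg.get("extent", 50)),
            connectivity=int(bs_cfg.get("connectivity", 1)),
        )
        labels, clusters = boot.clusters()
        extrema = extract_extrema(labels, boot.z_volume())
        logger.info("bootstrap: %d iterations, %d surviving clusters",
                    boot.n_iterations, len(clusters))
        bundle["bootstrap"] = boot
        bundle["clusters"] = clusters

        stage = "behavior"
        trials = load_trials(paths["trials"], paths["geometry"])
        behavior = behavior_table(trials, n_days=int(config.get("n_days", 4)))
        behavior = (behavior.set_index("subject_id")
                    .loc[stack.subject_ids].reset_index())
        bundle["behavior"] = behavior
        logger.info("behavior: %d trials, %d subjects", len(trials),
                    len(behavior))

        stage = "stats"
        stats_block = _run_stats(stack, subjects, behavior, sel)
        bundle["stats"] = stats_block

        stage = "report"
        report_paths = _write_report(out, stack, ssm_res, sel, boot, labels,
                                     clusters, extrema, behavior, stats_block,
                                     subjects)
        bundle["paths"] = {**paths, **report_paths, "log": str(log_path)}
        logger.info("report written under %s", out)
    except Exception as exc:  # noqa: BLE001 - stage attribution is the contract
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return bundle


def _run_stats(stack, subjects, behavior, sel) -> dict:
    group = stack.group_indicator()
    young, aged = group == 0, group == 1
    out: dict[str, Any] = {}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if {"visual_day1", "visual_day2"} <= set(subjects.columns):
            for day in (1, 2):
                vals = subjects[f"visual_day{day}"].to_numpy()
                out[f"mw_visual_day{day}"] = mann_whitney(vals[young], vals[aged])
            covariate = subjects[["visual_day1", "visual_day2"]].mean(axis=1).to_numpy()
        else:
            covariate = None

        day_cols = [c for c in behavior.columns if c.startswith("day")]
        day_matrix = behavior[day_cols].to_numpy()
        out["mixed_ancova"] = mixed_ancova(day_matrix, group, covariate)
        out["score_behavior"] = score_behavior_regression(
            sel.composite_scores, behavior["learning_index"].to_numpy())
        gates = {}
        gates["composite_scores"] = shapiro_wilk_gate(sel.composite_scores)
        gates["learning_index"] = shapiro_wilk_gate(
            behavior["learning_index"].to_numpy())
        if covariate is not None:
            gates["visual_covariate"] = shapiro_wilk_gate(covariate)
        out["normality_gates"] = gates
    return out


def _stats_text(stats_block: dict, sel) -> str:
    lines = ["ratssm statistics report", "=" * 46]
    for day in (1, 2):
        key = f"mw_visual_day{day}"
        if key in stats_block:
            lines.append(f"visual task day {day}: {stats_block[key].summary()}")
    lines.append("")
    lines.append(stats_block["mixed_ancova"].summary().rstrip())
    lines.append("")
    subset = "{" + ", ".join(map(str, sel.subset)) + "}"
    lines.append(f"age-group discrimination (subset {subset}): "
                 f"R^2 = {sel.r_squared:.3f}, F({sel.df[0]},{sel.df[1]}) = "
                 f"{sel.f_statistic:.2f}, p = {sel.p_value:.3g}")
    if sel.covariate_test is not None:
        lines.append(sel.covariate_test.summary().rstrip())
    lines.append("")
    lines.append("score-behavior regression: "
                 + stats_block["score_behavior"].summary())
    lines.append("")
    for name, gate in stats_block["normality_gates"].items():
        lines.append(f"normality {name}: {gate.summary()}")
    return "\n".join(lines) + "\n"


def _write_report(out, stack, ssm_res, sel, boot, labels, clusters, extrema,
                  behavior, stats_block, subjects) -> dict:
    paths = {}

    n_save = min(ssm_res.n_components, 8)
    for k in range(n_save):
        p = out / f"pattern_comp{k + 1}.nii.gz"
        stack.save_map(ssm_res.patterns[k], p)
    paths["patterns"] = str(out / "pattern_comp1.nii.gz")

    scores = pd.DataFrame(
        ssm_res.scores[:, :n_save],
        columns=[f"comp{k + 1}" for k in range(n_save)],
    )
    scores.insert(0, "subject_id", stack.subject_ids)
    scores.insert(1, "group", stack.group_labels)
    scores["composite"] = sel.composite_scores
    scores.to_csv(out / "subject_scores.csv", index=False)
    paths["scores"] = str(out / "subject_scores.csv")

    sel.candidates.assign(
        subset=sel.candidates["subset"].map(
            lambda s: "+".join(map(str, s)) if s else "intercept")
    ).to_csv(out / "aicc_candidates.csv", index=False)
    paths["candidates"] = str(out / "aicc_candidates.csv")
    stack.save_map(sel.composite_pattern, out / "composite_pattern.nii.gz")
    paths["composite"] = str(out / "composite_pattern.nii.gz")

    save_volume(boot.z_volume(), stack.affine, out / "bootstrap_z.nii.gz")
    save_volume(labels.astype(np.int16), stack.affine,
                out / "cluster_labels.nii.gz")
    clusters.to_csv(out / "clusters.csv", index=False)
    extrema.to_csv(out / "cluster_extrema.csv", index=False)
    paths["z_map"] = str(out / "bootstrap_z.nii.gz")
    paths["clusters"] = str(out / "clusters.csv")

    behavior.to_csv(out / "behavior_table.csv", index=False)
    paths["behavior"] = str(out / "behavior_table.csv")

    text = _stats_text(stats_block, sel)
    (out / "statistics.txt").write_text(text)
    paths["stats_text"] = str(out / "statistics.txt")

    summary = {
        "version": __version__,
        "n_subjects": stack.n_subjects,
        "n_voxels": stack.n_voxels,
        "variance_fraction": ssm_res.variance_fraction[:n_save].tolist(),
        "selected_subset": list(sel.subset),
        "selection_r2": sel.r_squared,
        "selection_f": sel.f_statistic,
        "selection_df": list(sel.df),
        "n_clusters": int(len(clusters)),
        "ancova": {
            "f_group": stats_block["mixed_ancova"].f_group,
            "df_group": list(stats_block["mixed_ancova"].df_group),
            "f_day": stats_block["mixed_ancova"].f_day,
            "df_day": list(stats_block["mixed_ancova"].df_day),
            "f_interaction": stats_block["mixed_ancova"].f_interaction,
        },
        "score_behavior_r": stats_block["score_behavior"].r,
    }
    if sel.covariate_test is not None:
        summary["etiv_f_change"] = sel.covariate_test.f_change
        summary["etiv_df_change"] = list(sel.covariate_test.df_change)
    (out / "report.json").write_text(json.dumps(summary, indent=1))
    paths["report"] = str(out / "report.json")
    return paths
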