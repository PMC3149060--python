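"""End-to-end orchestration: simulate -> episodes -> features -> impute ->
fit -> evaluate -> surveil, with a deterministic manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, imputation, model, synth_cohort
from .episodes import apply_exclusions, build_episodes, episodes_to_frame, merge_readmissions
from .synth_cohort import GeneratorConfig

__all__ = ["RunConfig", "run_pipeline", "StageError"]

# predictor kinds used by the univariate screen
VARIABLE_KINDS = {
    "drain_type_evd": "binary",
    "n_drains": "continuous_skewed",
    "crp": "continuous_skewed",
    "blood_leukocytes": "continuous_skewed",
    "csf_leukocytes_log": "continuous_normal",
    "culture_positive": "binary",
    "empiric_abx": "binary",
    "n_abx_started": "continuous_skewed",
    "total_drain_days": "continuous_skewed",
    "icu_days": "continuous_skewed",
    "admission_days": "continuous_skewed",
    "hemoglobin": "continuous_normal",
    "thrombocytes": "continuous_skewed",
    "csf_erythrocytes": "continuous_skewed",
    "csf_neutrophil_pct": "continuous_normal",
    "csf_neutrophils": "continuous_skewed",
    "csf_glucose": "continuous_normal",
    "csf_protein": "continuous_skewed",
    "abx_after_day4": "binary",
    "csf_leuko_binary": "binary",
}

# candidate predictors offered to the multivariable model (the CRP power
# terms enter alongside the linear term; screening-only variables that
# survive the univariate filter are candidates too)
MODEL_CANDIDATES = [
    "drain_type_evd",
    "n_drains",
    "crp",
    "crp_sq",
    "crp_cu",
    "blood_leukocytes",
    "csf_leukocytes_log",
    "culture_positive",
    "empiric_abx",
    "n_abx_started",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "run_output"
    mode: str = "simulate-and-fit"  # fit-only | score-only | surveil
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_dir: str | None = None  # event tables for non-simulate modes
    model_path: str | None = None  # stored rule for score-only / surveil modes
    m: int = 10
    bootstrap_B: int = 100
    alpha: float = 0.05
    cutoffs: tuple = (0.107, 0.175)
    seed: int = 0
    inject_missingness: bool = True

    def __post_init__(self):
        for c in self.cutoffs:
            if not 0 < c < 1:
                raise ValueError("cutoffs must lie in (0, 1)")
        if self.mode != "simulate-and-fit" and self.input_dir is None:
            raise ValueError(f"mode {self.mode!r} requires input_dir")
        if self.mode in ("score-only", "surveil") and self.model_path is None:
            raise ValueError(f"mode {self.mode!r} requires model_path")


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run report.

    Identical config (and seed) produces identical manifest hashes.  A stage
    failure raises :class:`StageError` tagged with the stage name; artifacts
    of completed stages are retained in ``config.out_dir``.
    """
    from . import io as dio

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # hash the scientific configuration only; output location must not
    # change the result identity
    cfg_dict = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    report: dict = {"config_hash": _hash_obj(cfg_dict), "stages": []}
    manifest: dict = {"seed": config.seed, "schema_version": dio.SCHEMA_VERSION, "artifacts": {}}

    # ---- stage: simulate / load ----------------------------------------
    try:
        if config.mode == "simulate-and-fit":
            gen = dataclasses.replace(config.generator, seed=config.seed)
            tables = synth_cohort.generate_cohort(gen)
            if config.inject_missingness:
                tables = synth_cohort.inject_missingness(tables, gen)
            manifest["artifacts"].update(dio.write_tables(tables, out_dir / "events"))
        else:
            if not Path(config.input_dir or "").exists():
                raise FileNotFoundError(f"input directory not found: {config.input_dir}")
            tables = dio.read_tables(config.input_dir)
        report["stages"].append("simulate" if config.mode == "simulate-and-fit" else "load")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    # ---- stage: episodes -------------------------------------------------
    try:
        eps = build_episodes(tables)
        eps = merge_readmissions(eps)
        included, exclusion_log = apply_exclusions(eps, tables.patients)
        ep_frame = episodes_to_frame(included)
        ep_frame.to_csv(out_dir / "episodes.csv", index=False)
        exclusion_log.to_csv(out_dir / "exclusions.csv", index=False)
        manifest["artifacts"]["episodes"] = _hash_frame(ep_frame)
        report["stages"].append("episodes")
        report["n_episodes"] = len(included)
        report["n_excluded"] = len(exclusion_log)
    except Exception as exc:
        raise StageError("episodes", str(exc)) from exc

    # ---- stage: features -------------------------------------------------
    try:
        feats = features.build_feature_table(included, tables)
        outcome = tables.outcomes.set_index("patient_id")["drm_flag"]
        feats["drm_flag"] = feats["patient_id"].map(outcome).astype(int)
        feats.to_csv(out_dir / "features.csv", index=False)
        manifest["artifacts"]["features"] = _hash_frame(feats)
        report["stages"].append("features")
    except Exception as exc:
        raise StageError("features", str(exc)) from exc

    # ---- score-only / surveil: apply a stored rule, no development -------
    if config.mode in ("score-only", "surveil"):
        try:
            rule = model.PredictionRule.from_json(config.model_path)
            needed = list(rule.coefficients)
            complete = feats.dropna(subset=needed)
            probs = rule.predict(complete)
            report["n_scored"] = len(complete)
            report["n_unscorable"] = len(feats) - len(complete)  # missing predictors
            y = complete["drm_flag"].to_numpy(dtype=int) if "drm_flag" in complete else None
            if config.mode == "score-only" and y is not None:
                report["confusion"] = {
                    str(c): evaluation.confusion_metrics(probs, y, c).as_dict()
                    for c in config.cutoffs
                }
            ep_sub = ep_frame.loc[complete.index]
            summaries = evaluation.surveillance_summary(probs, ep_sub, truth=y)
            report["surveillance"] = [dataclasses.asdict(s) for s in summaries]
            report["stages"].append(config.mode)
        except Exception as exc:
            raise StageError(config.mode, str(exc)) from exc
        report["manifest"] = manifest
        dio.write_report(report, out_dir / "report.json")
        return report

    # ---- stage: impute ---------------------------------------------------
    try:
        imp = imputation.impute(feats, m=config.m, seed=config.seed)
        mean_df = imputation.mean_dataset(imp, binary_cols=features.BINARY_FEATURES)
        report["stages"].append("impute")
        report["imputation_method"] = imp.method
    except Exception as exc:
        raise StageError("impute", str(exc)) from exc

    # ---- stage: fit ------------------------------------------------------
    try:
        screen = model.univariate_screen(mean_df, "drm_flag", VARIABLE_KINDS, config.alpha)
        screened_in = {s.variable for s in screen if s.selected}
        candidates = [
            c for c in MODEL_CANDIDATES
            if c in screened_in or c in ("crp", "crp_sq", "crp_cu")
        ]
        selected, trace = model.backward_select(
            imp, candidates, "drm_flag", alpha=config.alpha
        )
        pooled, fit_rep = model.pooled_fit(imp, selected, "drm_flag")
        boot = model.bootstrap_optimism(
            imp, selected, "drm_flag", B=config.bootstrap_B, seed=config.seed + 1
        )
        coefs = pd.Series(pooled.q_bar, index=pooled.names)
        rule = model.shrink_and_recalibrate(
            coefs, boot["shrinkage"], mean_df[selected], mean_df["drm_flag"]
        )
        rule.to_json(out_dir / "model.json")
        manifest["artifacts"]["model"] = dio.sha256_file(out_dir / "model.json")
        report["stages"].append("fit")
        report["screening"] = [dataclasses.asdict(s) for s in screen]
        report["selected_predictors"] = selected
        report["selection_trace"] = trace
        report["bootstrap"] = boot
        report["separation_fallback"] = fit_rep["separation"]
        report["odds_ratios"] = rule.odds_ratios
        report["intercept"] = rule.intercept
    except Exception as exc:
        raise StageError("fit", str(exc)) from exc

    # ---- stage: evaluate -------------------------------------------------
    try:
        probs = rule.predict(mean_df)
        y = mean_df["drm_flag"].to_numpy(dtype=int)
        auc, auc_ci = evaluation.roc_auc(probs, y)
        report["auc_apparent"] = auc
        report["auc_ci"] = auc_ci
        # optimism estimated by bootstrap, subtracted from the final rule's
        # apparent AUC (Harrell-style internal validation)
        report["auc_corrected"] = auc - boot["optimism"]
        report["confusion"] = {
            str(c): evaluation.confusion_metrics(probs, y, c).as_dict()
            for c in config.cutoffs
        }
        report["workload"] = {
            str(c): evaluation.workload_reduction(probs, c) for c in config.cutoffs
        }
        report["calibration"] = evaluation.calibration_table(probs, y).to_dict("records")
        report["stages"].append("evaluate")
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc

    # ---- stage: surveil --------------------------------------------------
    try:
        summaries = evaluation.surveillance_summary(probs, ep_frame, truth=y)
        report["surveillance"] = [dataclasses.asdict(s) for s in summaries]
        report["stages"].append("surveil")
    except Exception as exc:
        raise StageError("surveil", str(exc)) from exc

    manifest["report_hash"] = _hash_obj(
        {k: v for k, v in report.items() if k != "manifest"}
    )
    report["manifest"] = manifest
    from .io import write_report

    write_report(report, out_dir / "report.json")
    return report
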