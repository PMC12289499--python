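"""End-to-end pipeline runner.

Reproduces the full study flow on synthetic or user-supplied tables:
reproducibility (ICC) filtering -> iterative stability selection ->
model-family training on the robust features -> best-scorer choice ->
clinical screening and staged logistic integration -> Clinical-Radiomic
Score with ROC/DeLong, Hosmer-Lemeshow, calibration and decision-curve
evaluation on the derivation and temporal validation cohorts. Every
stochastic stage draws its RNG substream from the master seed, so a fixed
config reproduces bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import (
    export_nomogram,
    fit_clin_rad,
    screen_clinical,
    staged_logistic_selection,
)
from .io import (
    FeatureTable,
    icc_filter,
    impute_clinical,
    load_clinical_table,
    load_feature_table,
)
from .models import (
    LINEAR_FAMILIES,
    ModelAssessment,
    assess_scorer,
    assessments_frame,
    final_split,
    select_best_scorer,
    train_linear_scorer,
    tune_knn,
    tune_svm,
)
from .selection import SelectionConfig, run_iterations, select_robust_features
from .stats import (
    calibration_bins,
    decision_curve,
    delong_compare,
    hosmer_lemeshow,
    permutation_test_scores,
    report_at_cutoff,
    youden_cutoff,
)
from .synthetic import SimulationConfig, generate_clinical_table, generate_feature_table, \
    generate_rater_replicates, inject_missingness

log = logging.getLogger(__name__)

ALL_FAMILIES = LINEAR_FAMILIES + ("knn", "svm")


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``input_paths`` (feature/clinical CSV files) or
    ``synthetic`` (a SimulationConfig) provides the cohorts.
    """

    synthetic: SimulationConfig | None = None
    input_paths: dict | None = None  # feature_{derivation,validation}, clinical_{...}
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    families: tuple = ALL_FAMILIES
    icc_threshold: float = 0.75
    clinical_alpha: float = 0.05
    cutoff_adjusted: float | None = None
    output_dir: str = "runs/latest"
    seed: int = 0
    run_icc: bool = True

    def validate(self) -> None:
        if (self.synthetic is None) == (self.input_paths is None):
            raise ValueError("exactly one of synthetic config or input paths must be given")
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")


def _load_cohorts(config: PipelineConfig):
    if config.synthetic is not None:
        sim = dataclasses.replace(config.synthetic, seed=config.seed)
        feat_d, truth = generate_feature_table(sim, "derivation")
        feat_v, _ = generate_feature_table(sim, "validation")
        clin_d = generate_clinical_table(sim, "derivation")
        clin_v = generate_clinical_table(sim, "validation")
        if sim.missing_rate > 0:
            clin_d = inject_missingness(clin_d, sim.missing_rate, config.seed + 101)
            clin_v = inject_missingness(clin_v, sim.missing_rate, config.seed + 102)
        replicates = generate_rater_replicates(feat_d, sim.rater_noise_sd, config.seed + 103)
        return feat_d, feat_v, clin_d, clin_v, replicates, truth
    paths = config.input_paths
    feat_d = load_feature_table(paths["feature_derivation"])
    feat_v = load_feature_table(paths["feature_validation"])
    clin_d = load_clinical_table(paths["clinical_derivation"])
    clin_v = load_clinical_table(paths["clinical_validation"])
    return feat_d, feat_v, clin_d, clin_v, None, None


def _train_family(family: str, table: FeatureTable, seed: int,
                  cv_folds: int) -> ModelAssessment:
    if family in LINEAR_FAMILIES:
        train, test = final_split(table, seed)
        scorer = train_linear_scorer(train, family, cv_folds=cv_folds, seed=seed)
        return assess_scorer(scorer, train, test, rng=seed)
    if family == "knn":
        train, test = final_split(table, seed)
        _, model = tune_knn(train, cv_folds=cv_folds, seed=seed)
        return assess_scorer(model, train, test, rng=seed)
    kernel, model, train, test = tune_svm(table, seed=seed)
    log.info("svm kernel selected: %s", kernel)
    return assess_scorer(model, train, test, rng=seed)


def _cohort_report(scores, labels, cutoff, n_perm, rng):
    rep = report_at_cutoff(scores, labels, cutoff)
    perm_p = permutation_test_scores(scores, labels, n_perm, rng)
    return rep, perm_p


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow and write artifacts under ``output_dir``.

    Returns the run manifest (paths, chosen model, headline metrics).
    """
    config.validate()
    out = Path(config.output_dir)
    (out / "scorers").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": {}}
    feat_d, feat_v, clin_d, clin_v, replicates, truth = _load_cohorts(config)

    # --- ICC reproducibility filter -------------------------------------
    if config.run_icc and replicates is not None:
        retained, icc_report = icc_filter(*replicates, threshold=config.icc_threshold)
        icc_report.to_frame(feat_d.feature_classes).to_csv(out / "icc_report.csv", index=False)
        feat_d = feat_d.subset_features(retained)
        feat_v = feat_v.subset_features([n for n in retained if n in feat_v.feature_names])
        manifest["stages"]["icc"] = {"n_retained": len(retained)}

    # --- stability selection ---------------------------------------------
    sel_cfg = dataclasses.replace(config.selection, seed=config.seed)
    result = run_iterations(feat_d, sel_cfg)
    result.to_json(out / "selection.json")
    result.counts_frame().to_csv(out / "counts.csv", index=False)
    robust = select_robust_features(result, sel_cfg.min_count)
    manifest["stages"]["selection"] = {
        "total_candidates": result.total_candidates,
        "n_accepted": result.n_accepted,
        "robust_features": robust,
    }
    if len(robust) < 2:
        raise RuntimeError(
            f"stability selection retained {len(robust)} feature(s); "
            "cannot train the final models (artifacts persisted)"
        )
    feat_d_rob = feat_d.subset_features(robust)
    feat_v_rob = feat_v.subset_features(robust)

    # --- model families ---------------------------------------------------
    assessments = []
    for k, family in enumerate(config.families):
        try:
            assessments.append(_train_family(family, feat_d_rob, config.seed + 17 * (k + 1),
                                             sel_cfg.cv_folds))
        except Exception as exc:  # noqa: BLE001
            log.warning("family %s failed: %s", family, exc)
    frame = assessments_frame(assessments)
    frame.to_csv(out / "model_assessments.csv", index=False)
    best = select_best_scorer(assessments)
    manifest["stages"]["models"] = {
        "families_run": [a.model_family for a in assessments],
        "best": best.model_family,
        "best_test_auc": best.test_report.auc,
    }
    if hasattr(best.model, "scorer"):
        with open(out / "scorers" / f"{best.model_family}.json", "w") as fh:
            json.dump(best.model.scorer.to_dict(), fh, indent=1)

    # --- clinical integration ---------------------------------------------
    rs_d = np.asarray(best.model.score_table(feat_d_rob), float)
    rs_v = np.asarray(best.model.score_table(feat_v_rob), float)
    clin_d = impute_clinical(clin_d)
    clin_v = impute_clinical(clin_v)
    screening = screen_clinical(clin_d, alpha=config.clinical_alpha)
    screening.to_frame().to_csv(out / "clinical_screening.csv", index=False)
    retained = staged_logistic_selection(clin_d, screening.flagged_variables, rs_d,
                                         alpha=config.clinical_alpha)
    if "RS" not in retained:
        retained = retained + ["RS"]
        log.warning("RS not significant in staged selection; forced into the fused model")
    model = fit_clin_rad(clin_d, retained, rs_d, cutoff_adjusted=config.cutoff_adjusted)
    with open(out / "clin_rad_model.json", "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
    manifest["stages"]["clinical"] = {
        "screened": screening.flagged_variables,
        "retained": retained,
        "cutoff_youden": model.cutoff_youden,
    }

    # --- evaluation --------------------------------------------------------
    rng = np.random.default_rng(config.seed + 999)
    frames, rows = {}, []
    dca_rows, cal_rows = [], []
    for cohort, clin, rs in (("derivation", clin_d, rs_d), ("validation", clin_v, rs_v)):
        dframe = clin.data.copy()
        dframe["RS"] = rs
        probs = model.predict(dframe)
        labels = clin.labels
        rep, perm_p = _cohort_report(probs, labels, model.cutoff, sel_cfg.n_permutations, rng)
        hl_stat, hl_df, hl_p = hosmer_lemeshow(np.clip(probs, 1e-9, 1 - 1e-9), labels)
        rs_rep = report_at_cutoff(rs, labels, youden_cutoff(rs, labels).cutoff)
        row = rep.as_dict()
        row.update({"cohort": cohort, "perm_p": perm_p, "hl_stat": hl_stat,
                    "hl_p": hl_p, "rs_only_auc": rs_rep.auc})
        rows.append(row)
        frames[cohort] = (probs, labels)
        dca = decision_curve(probs, labels)
        for t, nb, ta in zip(dca.thresholds, dca.net_benefit, dca.treat_all):
            dca_rows.append({"cohort": cohort, "threshold": t, "net_benefit": nb,
                             "treat_all": ta, "treat_none": 0.0})
        for mp, obs, cnt in calibration_bins(probs, labels, n_bins=min(10, len(labels) // 5)):
            cal_rows.append({"cohort": cohort, "mean_predicted": mp,
                             "observed_rate": obs, "count": cnt})
        pd.DataFrame([row]).to_csv(out / f"report_{cohort}.csv", index=False)
    _, delong_p = delong_compare(frames["derivation"][0], frames["derivation"][1],
                                 frames["validation"][0], frames["validation"][1])
    pd.DataFrame(dca_rows).to_csv(out / "dca.csv", index=False)
    pd.DataFrame(cal_rows).to_csv(out / "calibration.csv", index=False)

    nomogram = export_nomogram(model)
    nomo_rows = []
    for var, axis in nomogram["axes"].items():
        for _, r in axis.iterrows():
            nomo_rows.append({"variable": var, "value": r["value"], "points": r["points"]})
    pd.DataFrame(nomo_rows).to_csv(out / "nomogram.csv", index=False)
    nomogram["total_points_to_probability"].to_csv(out / "nomogram_probability.csv", index=False)

    manifest["stages"]["evaluation"] = {
        "derivation": rows[0], "validation": rows[1],
        "cross_cohort_delong_p": float(delong_p),
    }
    manifest["config"] = {
        "selection": dataclasses.asdict(sel_cfg),
        "synthetic": dataclasses.asdict(config.synthetic) if config.synthetic else None,
        "families": list(config.families),
        "icc_threshold": config.icc_threshold,
        "clinical_alpha": config.clinical_alpha,
        "cutoff_adjusted": config.cutoff_adjusted,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return manifest
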