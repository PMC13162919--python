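"""End-to-end driver: simulate/read -> folds -> OOF modality scores ->
unimodal baselines and five fusion models -> stratification -> metrics,
with every table exported as tidy CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .cox import neg_log_partial_likelihood
from .fusion import (
    FusionConfig,
    compute_epv,
    fit_cox_meta,
    fit_logistic_stack,
    fit_tree_meta,
    fit_weighted_average,
    make_outer_folds,
    oof_modality_scores,
    _fit_cox_safe,
    _numeric_matrix,
    _standardise,
    CLINICAL_COLS,
    DEMOGRAPHIC_COLS,
)
from .grouplasso import (
    GroupStructure,
    compute_lambda_max,
    cv_select_lambda,
    default_lambda_grid,
    selection_frequency,
)
from .metrics import calibration_groups, evaluate_model, km_fit
from .stratify import fold_averaged_stratification
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "MODEL_ORDER"]

MODEL_ORDER = [
    "radiomics_cox",
    "clinical_cox",
    "demographics_cox",
    "rsf_meta",
    "cox_meta",
    "logistic_stack",
    "weighted_average",
    "xgb_meta",
]
UNIMODAL = MODEL_ORDER[:3]
FUSION = MODEL_ORDER[3:]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Exactly one of (cohort_path, taxonomy_path) or simulation_spec."""

    cohort_path: str | None = None
    taxonomy_path: str | None = None
    simulation_spec: CohortSpec | None = None
    t_star: float = 1.5
    k_folds: int = 5
    seed: int = 0
    out_dir: str = "fusesurv_out"
    fusion: FusionConfig = field(default_factory=FusionConfig)
    inner_folds_glasso: int = 5
    lambda_grid_size: int = 100
    lambda_min_ratio: float = 0.001
    gl_tol: float = 1e-6
    min_group_fraction: float = 0.15
    cutoff_range: tuple = (0.15, 0.85)
    cutoff_step: float = 0.025
    n_bootstrap: int = 0

    def __post_init__(self):
        has_files = self.cohort_path is not None
        has_spec = self.simulation_spec is not None
        if has_files == has_spec:
            raise ValueError(
                "exactly one of input paths or a simulation spec must be given"
            )
        if has_files and self.taxonomy_path is None:
            raise ValueError("taxonomy_path required with cohort_path")


def _cox_group_hrs(groups, time, event, ref: str, order: list) -> pd.DataFrame:
    """Hazard ratios (and Wald CIs) of group dummies vs a reference."""
    groups = np.asarray(groups).astype(str)
    levels = [g for g in order if g != ref and (groups == g).any()]
    if not levels or not (groups == ref).any():
        return pd.DataFrame()
    X = np.column_stack([(groups == g).astype(float) for g in levels])
    fit = _fit_cox_safe(X, time, event, "hazard-ratio model")
    _, _, H = neg_log_partial_likelihood(np.asarray(X, float), time, event, fit.beta)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    rows = []
    for j, g in enumerate(levels):
        b = fit.beta[j]
        rows.append(
            {
                "level": g,
                "reference": ref,
                "hr": float(np.exp(b)),
                "hr_lo": float(np.exp(b - 1.96 * se[j])),
                "hr_hi": float(np.exp(b + 1.96 * se[j])),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict of
    DataFrames and writes each to ``<out_dir>/<name>.csv``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, pd.DataFrame] = {}

    def persist():
        for name, df in bundle.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)

    stage = "load"
    try:
        if config.simulation_spec is not None:
            cohort = generate_cohort(config.simulation_spec)
        else:
            cohort = fio.read_cohort(config.cohort_path, config.taxonomy_path)
        time, event = cohort.time, cohort.event
        n_events = int(event.sum())

        stage = "folds"
        folds = make_outer_folds(event, k=config.k_folds, seed=config.seed)

        stage = "oof_modality_scores"
        meta = oof_modality_scores(
            cohort,
            folds,
            t_star=config.t_star,
            seed=config.seed,
            inner_folds=config.inner_folds_glasso,
            lambda_grid_size=config.lambda_grid_size,
            lambda_min_ratio=config.lambda_min_ratio,
            gl_tol=config.gl_tol,
        )
        bundle["selection_frequency"] = selection_frequency(
            meta.radiomic_fold_coefs, meta.feature_names
        )
        bundle["selection_frequency_refit"] = selection_frequency(
            meta.radiomic_refit_coefs, meta.feature_names
        )

        stage = "whole_data_unimodal"
        whole = {}
        modal_cols = {
            "radiomics_cox": meta.feature_names,
            "clinical_cox": CLINICAL_COLS,
            "demographics_cox": DEMOGRAPHIC_COLS,
        }
        # whole-data radiomic model: group-lasso signature selected by CV
        # on the full cohort, then an unpenalised refit
        Xrad = _numeric_matrix(cohort.data, meta.feature_names)
        Xrad = _standardise(Xrad)[0]
        gs_full = GroupStructure.from_taxonomy(meta.feature_names, cohort.taxonomy)
        full_path = cv_select_lambda(
            Xrad, time, event, gs_full,
            k_folds=config.inner_folds_glasso, seed=config.seed,
            tol=config.gl_tol,
            lambda_grid=default_lambda_grid(
                compute_lambda_max(Xrad, time, event, gs_full),
                config.lambda_grid_size, config.lambda_min_ratio,
            ),
        )
        sel_idx = full_path.active_features()
        rad_cols = (
            [meta.feature_names[j] for j in sel_idx]
            if sel_idx.size
            else meta.feature_names
        )
        from .cox import predict_absolute_risk, predict_risk_score

        for model, cols in modal_cols.items():
            use = rad_cols if model == "radiomics_cox" else cols
            X = _numeric_matrix(cohort.data, use)
            Xs = _standardise(X)[0]
            fit = _fit_cox_safe(Xs, time, event, f"{model} whole-data")
            whole[model] = {
                "score": predict_risk_score(fit, Xs),
                "risk": predict_absolute_risk(fit, Xs, config.t_star).risk,
            }

        stage = "fusion"
        results = {
            "radiomics_cox": {
                "oof_score": meta.df["score_radiomic"].to_numpy(),
                "oof_risk": meta.df["risk_radiomic"].to_numpy(),
                "whole_score": whole["radiomics_cox"]["score"],
                "whole_risk": whole["radiomics_cox"]["risk"],
            },
            "clinical_cox": {
                "oof_score": meta.df["score_clinical"].to_numpy(),
                "oof_risk": meta.df["risk_clinical"].to_numpy(),
                "whole_score": whole["clinical_cox"]["score"],
                "whole_risk": whole["clinical_cox"]["risk"],
            },
            "demographics_cox": {
                "oof_score": meta.df["score_demographic"].to_numpy(),
                "oof_risk": meta.df["risk_demographic"].to_numpy(),
                "whole_score": whole["demographics_cox"]["score"],
                "whole_risk": whole["demographics_cox"]["risk"],
            },
        }
        fus_cfg = config.fusion
        results["cox_meta"] = fit_cox_meta(meta, time, event, config.t_star)
        results["weighted_average"] = fit_weighted_average(
            meta, time, event, mode="optimized", t_star=config.t_star,
            weight_step=fus_cfg.weight_grid_step,
        )
        results["logistic_stack"] = fit_logistic_stack(
            meta, time, event, t_star=config.t_star,
            alpha_grid=fus_cfg.alpha_grid, c_grid=fus_cfg.c_grid,
            inner_folds=fus_cfg.inner_folds, seed=config.seed,
        )
        results["rsf_meta"] = fit_tree_meta(meta, time, event, "rsf_meta", fus_cfg)
        results["xgb_meta"] = fit_tree_meta(meta, time, event, "xgb_meta", fus_cfg)

        stage = "epv"
        n_radiomic = len(rad_cols)
        bundle["epv"] = pd.DataFrame(
            [
                ("radiomics_cox", "selected radiomic features", n_radiomic),
                ("clinical_cox", "overall stage, T stage, N stage", 3),
                ("demographics_cox", "age, gender", 2),
                ("fusion_models", "three modality risk scores", 3),
            ],
            columns=["model", "predictors", "n_predictors"],
        ).assign(
            n_events=n_events,
            epv=lambda d: [
                round(compute_epv(n_events, k), 4) for k in d["n_predictors"]
            ],
        )

        stage = "metrics"
        perf_rows = []
        for model in MODEL_ORDER:
            r = results[model]
            rep_cv = evaluate_model(
                r["oof_risk"], r["oof_score"], time, event,
                n_bootstrap=config.n_bootstrap, seed=config.seed,
            )
            rep_whole = evaluate_model(
                r["whole_risk"], r["whole_score"], time, event,
            )
            perf_rows.append(
                {
                    "model": model,
                    "whole_c_index": rep_whole.c_index,
                    "whole_auc": rep_whole.mean_auc,
                    "whole_ibs": rep_whole.ibs,
                    "cv_c_index": rep_cv.c_index,
                    "cv_auc": rep_cv.mean_auc,
                    "cv_ibs": rep_cv.ibs,
                    **{
                        f"cv_{k}_lo": v[0]
                        for k, v in rep_cv.ci.items()
                    },
                    **{
                        f"cv_{k}_hi": v[1]
                        for k, v in rep_cv.ci.items()
                    },
                }
            )
        perf = pd.DataFrame(perf_rows)
        bundle["performance_unimodal"] = perf[perf.model.isin(UNIMODAL)]
        bundle["performance_fusion"] = perf[perf.model.isin(FUSION)]

        stage = "stratify"
        group_rows, km_rows, calib_rows, hr_rows, flow_rows = [], [], [], [], []
        strat_labels = {}
        for model in MODEL_ORDER:
            r = results[model]
            strat = fold_averaged_stratification(
                r["oof_risk"], folds, time, event,
                min_fraction=config.min_group_fraction,
                search_range=config.cutoff_range,
                step=config.cutoff_step,
            )
            strat_labels[model] = strat.groups
            s = strat.summary.copy()
            s.insert(0, "model", model)
            s["logrank_chisq"] = strat.logrank
            s["cutoff_1"] = strat.cutoffs.cutoff_1
            s["cutoff_2"] = strat.cutoffs.cutoff_2
            group_rows.append(s)
            for grp in s["risk_group"]:
                mask = strat.groups == grp
                km = km_fit(time[mask], event[mask])
                for t, sv in zip(km.times, km.survival):
                    km_rows.append(
                        {"model": model, "risk_group": grp,
                         "time_years": float(t), "survival": float(sv)}
                    )
            try:
                _, slope, intercept = calibration_groups(
                    r["oof_risk"], strat.groups, time, event, config.t_star
                )
                calib_rows.append(
                    {"model": model, "slope": slope, "intercept": intercept}
                )
            except ValueError as exc:
                logger.warning("calibration skipped for %s: %s", model, exc)
            hr = _cox_group_hrs(
                strat.groups, time, event, "low", ["low", "medium", "high"]
            )
            if len(hr):
                hr.insert(0, "model", model)
                hr_rows.append(hr)
            stages = cohort.data["overall_stage"].to_numpy()
            for st in np.unique(stages):
                for grp in ("low", "medium", "high"):
                    flow_rows.append(
                        {
                            "model": model,
                            "overall_stage": int(st),
                            "risk_group": grp,
                            "n": int(
                                ((stages == st) & (strat.groups == grp)).sum()
                            ),
                        }
                    )
        bundle["risk_groups"] = pd.concat(group_rows, ignore_index=True)
        bundle["km_curves"] = pd.DataFrame(km_rows)
        bundle["calibration"] = pd.DataFrame(calib_rows)
        stage_hr = _cox_group_hrs(
            cohort.data["overall_stage"].astype(str), time, event, "1",
            ["1", "2", "3"],
        )
        if len(stage_hr):
            stage_hr.insert(0, "model", "clinical_stage")
            hr_rows.append(stage_hr)
        bundle["hazard_ratios"] = (
            pd.concat(hr_rows, ignore_index=True) if hr_rows else pd.DataFrame()
        )
        bundle["stage_by_risk_group"] = pd.DataFrame(flow_rows)

        stage = "meta_features"
        bundle["meta_features"] = meta.df.copy()

        persist()
        return bundle
    except Exception as exc:
        persist()  # keep partial outputs for debugging
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
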