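"""Nested cross-validation orchestration and late-fusion meta-learners.

Produces leakage-free out-of-fold (OOF) modality risk scores (clinical,
demographic, radiomic) and fuses them with five meta-learners: Cox,
weighted averaging (equal or simplex-optimised), landmark logistic
stacking with elastic-net mixing, a random survival forest, and a
gradient-boosted-tree stack. The two tree learners are external library
calls behind a fit/predict contract; everything around them is owned.

Outer folds are shared across all models so comparisons are paired.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import (
    ConvergenceError,
    CoxFit,
    breslow_baseline,
    fit_cox,
    predict_absolute_risk,
    predict_risk_score,
)
from .grouplasso import (
    GroupStructure,
    compute_lambda_max,
    cv_select_lambda,
    default_lambda_grid,
)
from .metrics import harrell_cindex

logger = logging.getLogger(__name__)

__all__ = [
    "ModalitySpec",
    "MetaFeatures",
    "FusionConfig",
    "make_outer_folds",
    "oof_modality_scores",
    "fit_cox_meta",
    "fit_weighted_average",
    "fit_logistic_stack",
    "fit_tree_meta",
    "compute_epv",
    "default_modalities",
]

CLINICAL_COLS = ["overall_stage", "t_stage", "n_stage"]
DEMOGRAPHIC_COLS = ["age", "gender"]


@dataclass
class ModalitySpec:
    name: str  # clinical | demographic | radiomic
    columns: list


@dataclass
class FusionConfig:
    """Meta-learner settings; tree grids default to the printed tuning
    grids (2*7*4*4 = 224 forest configurations, 3*3 boosted-tree grid)."""

    t_star: float = 1.5
    seed: int = 0
    rsf_mtry: tuple = (1, 2)
    rsf_node_size: tuple = (5, 8, 10, 15, 20, 25, 30)
    rsf_trees: tuple = (500, 750, 1000, 1500)
    rsf_splits: tuple = (1, 3, 5, 10)
    rsf_draws: int = 60
    xgb_depths: tuple = (1, 2, 3)
    xgb_learning_rates: tuple = (0.03, 0.05, 0.1)
    xgb_n_estimators: int = 200
    alpha_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    c_grid: tuple = (0.01, 0.1, 1.0, 10.0)
    inner_folds: int = 3
    weight_grid_step: float = 0.05

    def rsf_grid(self):
        return list(
            itertools.product(
                self.rsf_mtry, self.rsf_node_size, self.rsf_trees, self.rsf_splits
            )
        )


@dataclass
class MetaFeatures:
    """Per-patient OOF modality scores and landmark absolute risks."""

    df: pd.DataFrame  # fold, score_*, risk_* columns
    folds: np.ndarray
    feature_names: list = field(default_factory=list)
    radiomic_fold_coefs: list = field(default_factory=list)  # penalised, per fold
    radiomic_refit_coefs: list = field(default_factory=list)
    radiomic_selected: list = field(default_factory=list)
    selected_lambdas: list = field(default_factory=list)

    SCORE_COLS = ("score_clinical", "score_demographic", "score_radiomic")
    RISK_COLS = ("risk_clinical", "risk_demographic", "risk_radiomic")

    def scores(self) -> np.ndarray:
        return self.df[list(self.SCORE_COLS)].to_numpy()


def default_modalities(feature_names) -> list:
    return [
        ModalitySpec("clinical", list(CLINICAL_COLS)),
        ModalitySpec("demographic", list(DEMOGRAPHIC_COLS)),
        ModalitySpec("radiomic", list(feature_names)),
    ]


def compute_epv(n_events: int, n_predictors: int) -> float:
    """Events-per-variable = events / predictors."""
    if n_predictors < 1:
        raise ValueError("number of predictors must be at least 1")
    return n_events / n_predictors


def make_outer_folds(event, k: int = 5, seed: int = 0) -> np.ndarray:
    """Near-equal folds stratified by event status; redraws (up to 100)
    until every fold contains at least one event."""
    event = np.asarray(event, int)
    n = event.size
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} patients for k={k} folds")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        labels = np.empty(n, dtype=int)
        counts = np.zeros(k, dtype=int)
        for val in (1, 0):  # events dealt first, then censored
            idx = rng.permutation(np.flatnonzero(event == val))
            order = np.argsort(counts, kind="stable")
            base, rem = divmod(idx.size, k)
            start = 0
            for rank, f in enumerate(order):
                sz = base + (1 if rank < rem else 0)
                labels[idx[start : start + sz]] = f
                counts[f] += sz
                start += sz
        if all(event[labels == f].sum() > 0 for f in range(k)):
            return labels
    raise RuntimeError("could not build folds with events in every fold")


def _standardise(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((a - mu) / sd for a in (train, *others)) + (mu, sd)


def _numeric_matrix(data: pd.DataFrame, columns) -> np.ndarray:
    out = np.empty((len(data), len(columns)))
    for j, c in enumerate(columns):
        col = data[c]
        if c == "gender":
            out[:, j] = (col == "male").astype(float)
        else:
            out[:, j] = col.to_numpy(dtype=float)
    return out


def _fit_cox_safe(X, time, event, label="model") -> CoxFit:
    """Cox fit with a tiny-ridge fallback for collinear designs."""
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        logger.warning("%s: collinear design, using ridge fallback", label)
        return fit_cox(X, time, event, l2=1e-6)
    try:
        return fit_cox(X, time, event)
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        logger.warning("%s: %s; using ridge fallback", label, exc)
        return fit_cox(X, time, event, l2=1e-6, max_iter=200)


def _null_risk(time, event, t_star: float) -> float:
    """Baseline-only absolute risk (Breslow with beta = 0)."""
    zeros = np.zeros((len(time), 1))
    bt, bh = breslow_baseline(zeros, time, event, np.zeros(1))
    idx = np.searchsorted(bt, t_star, side="right")
    H0 = 0.0 if idx == 0 else bh[idx - 1]
    return 1.0 - np.exp(-H0)


def oof_modality_scores(
    cohort,
    folds,
    specs=None,
    t_star: float = 1.5,
    seed: int = 0,
    inner_folds: int = 5,
    lambda_grid_size: int = 100,
    lambda_min_ratio: float = 0.001,
    gl_tol: float = 1e-6,
) -> MetaFeatures:
    """Out-of-fold modality risk scores under fold-specific standardisation.

    Per outer fold: clinical and demographic Cox models and the
    group-lasso radiomic signature (inner CV for the penalty, unpenalised
    refit on the selected features) are fitted on the training fold only;
    held-out linear predictors and landmark absolute risks use the
    training-fold Breslow baselines.
    """
    folds = np.asarray(folds)
    if specs is None:
        specs = default_modalities(cohort.feature_names)
    by_name = {s.name: s for s in specs}
    for req in ("clinical", "demographic", "radiomic"):
        if req not in by_name:
            raise ValueError(f"missing modality spec {req!r}")
    data = cohort.data
    time = cohort.time
    event = cohort.event
    n = len(data)
    out = {
        c: np.full(n, np.nan)
        for c in MetaFeatures.SCORE_COLS + MetaFeatures.RISK_COLS
    }
    gs = GroupStructure.from_taxonomy(
        by_name["radiomic"].columns, cohort.taxonomy
    )
    p_rad = len(by_name["radiomic"].columns)
    fold_coefs, refit_coefs, selected_feats, sel_lams = [], [], [], []
    for f in sorted(np.unique(folds)):
        tr = folds != f
        te = ~tr
        # unimodal Cox models on standardised training columns
        for name in ("clinical", "demographic"):
            Xall = _numeric_matrix(data, by_name[name].columns)
            Xtr, Xte, mu, sd = _standardise(Xall[tr], Xall[te])
            fit = _fit_cox_safe(Xtr, time[tr], event[tr], f"{name} fold {f}")
            out[f"score_{name}"][te] = predict_risk_score(fit, Xte)
            out[f"risk_{name}"][te] = predict_absolute_risk(fit, Xte, t_star).risk
        # radiomic signature via inner-CV group lasso
        Xall = _numeric_matrix(data, by_name["radiomic"].columns)
        Xtr, Xte, mu, sd = _standardise(Xall[tr], Xall[te])
        try:
            path = cv_select_lambda(
                Xtr,
                time[tr],
                event[tr],
                gs,
                k_folds=inner_folds,
                seed=seed + 1000 * (int(f) + 1),
                lambda_grid=default_lambda_grid(
                    compute_lambda_max(Xtr, time[tr], event[tr], gs),
                    lambda_grid_size,
                    lambda_min_ratio,
                ),
                tol=gl_tol,
            )
        except (RuntimeError, ValueError) as exc:
            raise RuntimeError(f"inner CV failed on outer fold {f}: {exc}") from exc
        pen_coef = path.selected_coef
        sel = path.active_features()
        fold_coefs.append(pen_coef.copy())
        sel_lams.append(path.selected_lambda)
        selected_feats.append(
            [by_name["radiomic"].columns[j] for j in sel]
        )
        refit = np.zeros(p_rad)
        if sel.size == 0:
            logger.warning("fold %s: empty radiomic signature; null model", f)
            out["score_radiomic"][te] = 0.0
            out["risk_radiomic"][te] = _null_risk(time[tr], event[tr], t_star)
        else:
            try:
                fit = fit_cox(Xtr[:, sel], time[tr], event[tr])
            except ConvergenceError as exc:
                logger.warning(
                    "fold %s: radiomic refit failed (%s); using penalised "
                    "coefficients",
                    f,
                    exc,
                )
                bt, bh = breslow_baseline(Xtr, time[tr], event[tr], pen_coef)
                fit = CoxFit(pen_coef[sel], bt, bh)
                # baseline computed under full penalised beta; scores below
                # use the selected columns only, consistent with pen_coef
            refit[sel] = fit.beta
            out["score_radiomic"][te] = predict_risk_score(fit, Xte[:, sel])
            out["risk_radiomic"][te] = predict_absolute_risk(
                fit, Xte[:, sel], t_star
            ).risk
        refit_coefs.append(refit)
    df = pd.DataFrame({"fold": folds, **out})
    return MetaFeatures(
        df=df,
        folds=folds,
        feature_names=list(by_name["radiomic"].columns),
        radiomic_fold_coefs=fold_coefs,
        radiomic_refit_coefs=refit_coefs,
        radiomic_selected=selected_feats,
        selected_lambdas=sel_lams,
    )


# ---------------------------------------------------------------------------
# meta-learners: each returns {"oof_risk", "oof_score", "whole_risk",
# "whole_score", ...} with risks at t_star in [0, 1]
# ---------------------------------------------------------------------------


def fit_cox_meta(meta: MetaFeatures, time, event, t_star: float = 1.5) -> dict:
    """Cox meta-learner on the three OOF modality scores."""
    S = meta.scores()
    folds = meta.folds
    n = S.shape[0]
    oof_risk = np.full(n, np.nan)
    oof_score = np.full(n, np.nan)
    for f in sorted(np.unique(folds)):
        tr = folds != f
        te = ~tr
        Xtr, Xte, _, _ = _standardise(S[tr], S[te])
        fit = _fit_cox_safe(Xtr, time[tr], event[tr], f"cox_meta fold {f}")
        oof_score[te] = predict_risk_score(fit, Xte)
        oof_risk[te] = predict_absolute_risk(fit, Xte, t_star).risk
    Xall = _standardise(S)[0]
    whole = _fit_cox_safe(Xall, time, event, "cox_meta whole-data")
    return {
        "oof_risk": oof_risk,
        "oof_score": oof_score,
        "whole_risk": predict_absolute_risk(whole, Xall, t_star).risk,
        "whole_score": predict_risk_score(whole, Xall),
        "whole_beta": whole.beta,
    }


def _comparable_pairs(time, event):
    """Index pairs (i, j) with i the earlier event; for fast repeated
    concordance evaluation over candidate weightings."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ii, jj = [], []
    for i in np.flatnonzero(event == 1):
        later = np.flatnonzero(time > time[i])
        ii.append(np.full(later.size, i))
        jj.append(later)
    return np.concatenate(ii), np.concatenate(jj)


def _pair_cindex(scores, ii, jj):
    si, sj = scores[ii], scores[jj]
    return float(np.mean((si > sj) + 0.5 * (si == sj)))


def _rank_transform(train_col, *others):
    """ECDF transform to [0, 1] fitted on the training column."""
    srt = np.sort(np.asarray(train_col, float))
    n = srt.size

    def ecdf(x):
        return (np.searchsorted(srt, x, side="right")) / (n + 1)

    return tuple(ecdf(np.asarray(a, float)) for a in (train_col, *others))


def _simplex_grid(step: float):
    ws = []
    m = int(round(1.0 / step))
    for i in range(m + 1):
        for j in range(m + 1 - i):
            ws.append((i * step, j * step, 1.0 - i * step - j * step))
    return ws


def _calibrated_risk(score_tr, time_tr, event_tr, score_te, t_star):
    """One-parameter Cox calibration of a fused score to absolute risk."""
    fit = _fit_cox_safe(score_tr[:, None], time_tr, event_tr, "score calibration")
    return (
        predict_absolute_risk(fit, score_te[:, None], t_star).risk,
        predict_risk_score(fit, score_te[:, None]),
    )


def fit_weighted_average(
    meta: MetaFeatures,
    time,
    event,
    mode: str = "optimized",
    t_star: float = 1.5,
    weight_step: float = 0.05,
) -> dict:
    """Equal or simplex-optimised weighted average of rank-standardised
    OOF scores, calibrated to absolute risk through a one-parameter Cox."""
    if mode not in ("equal", "optimized"):
        raise ValueError("mode must be 'equal' or 'optimized'")
    S = meta.scores()
    folds = meta.folds
    n = S.shape[0]
    oof_risk = np.full(n, np.nan)
    oof_score = np.full(n, np.nan)
    fold_weights = []
    for f in sorted(np.unique(folds)):
        tr = folds != f
        te = ~tr
        R_tr = np.empty((tr.sum(), 3))
        R_te = np.empty((te.sum(), 3))
        for j in range(3):
            R_tr[:, j], R_te[:, j] = _rank_transform(S[tr, j], S[te, j])
        if mode == "equal":
            w = (1 / 3, 1 / 3, 1 / 3)
        else:
            ii, jj = _comparable_pairs(time[tr], event[tr])
            best, w = -np.inf, (1 / 3, 1 / 3, 1 / 3)
            for cand in _simplex_grid(weight_step):
                c = _pair_cindex(R_tr @ np.asarray(cand), ii, jj)
                if c > best + 1e-12:
                    best, w = c, cand
        fold_weights.append(w)
        fused_tr = R_tr @ np.asarray(w)
        fused_te = R_te @ np.asarray(w)
        oof_risk[te], oof_score[te] = _calibrated_risk(
            fused_tr, time[tr], event[tr], fused_te, t_star
        )
    # whole-data variant
    R = np.empty_like(S)
    for j in range(3):
        (R[:, j],) = _rank_transform(S[:, j])
    if mode == "equal":
        w = (1 / 3, 1 / 3, 1 / 3)
    else:
        ii, jj = _comparable_pairs(time, event)
        best, w = -np.inf, (1 / 3, 1 / 3, 1 / 3)
        for cand in _simplex_grid(weight_step):
            c = _pair_cindex(R @ np.asarray(cand), ii, jj)
            if c > best + 1e-12:
                best, w = c, cand
    fused = R @ np.asarray(w)
    whole_risk, whole_score = _calibrated_risk(fused, time, event, fused, t_star)
    return {
        "oof_risk": oof_risk,
        "oof_score": oof_score,
        "whole_risk": whole_risk,
        "whole_score": whole_score,
        "fold_weights": fold_weights,
        "weights": w,
    }


def _landmark_labels(time, event, t_star):
    """Binary event-by-horizon labels; censored-before-horizon excluded."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    include = (time > t_star) | ((time <= t_star) & (event == 1))
    labels = ((time <= t_star) & (event == 1)).astype(int)
    return include, labels


def fit_logistic_stack(
    meta: MetaFeatures,
    time,
    event,
    t_star: float = 1.5,
    alpha_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    c_grid=(0.01, 0.1, 1.0, 10.0),
    inner_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Landmark logistic stacking with elastic-net mixing.

    The mixing parameter and penalty strength are chosen by inner CV on
    log-loss; patients censored before the horizon are excluded from
    meta-training but still scored.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import log_loss
    from sklearn.model_selection import StratifiedKFold

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    S = meta.scores()
    folds = meta.folds
    n = S.shape[0]
    oof_risk = np.full(n, np.nan)

    def tune_and_fit(Xtr, ytr, rs):
        if ytr.min() == ytr.max():
            raise ValueError("landmark labels are all one class; cannot stack")
        best = (np.inf, None)
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=rs)
        for alpha in alpha_grid:
            for C in c_grid:
                losses = []
                for itr, ite in skf.split(Xtr, ytr):
                    if ytr[itr].min() == ytr[itr].max():
                        continue
                    clf = LogisticRegression(
                        solver="saga",
                        l1_ratio=alpha,
                        C=C,
                        max_iter=5000,
                        random_state=rs,
                    )
                    clf.fit(Xtr[itr], ytr[itr])
                    losses.append(
                        log_loss(ytr[ite], clf.predict_proba(Xtr[ite])[:, 1],
                                 labels=[0, 1])
                    )
                mean_loss = np.mean(losses) if losses else np.inf
                if mean_loss < best[0] - 1e-12:
                    best = (mean_loss, (alpha, C))
        alpha, C = best[1]
        clf = LogisticRegression(
            solver="saga", l1_ratio=alpha, C=C, max_iter=5000, random_state=rs
        )
        clf.fit(Xtr, ytr)
        return clf, (alpha, C)

    chosen = []
    for f in sorted(np.unique(folds)):
        tr = folds != f
        te = ~tr
        inc, labels = _landmark_labels(time[tr], event[tr], t_star)
        Xtr_all, Xte, mu, sd = _standardise(S[tr], S[te])
        clf, hp = tune_and_fit(Xtr_all[inc], labels[inc], seed + int(f))
        chosen.append(hp)
        oof_risk[te] = clf.predict_proba(Xte)[:, 1]
    inc, labels = _landmark_labels(time, event, t_star)
    Xall = _standardise(S)[0]
    clf, hp = tune_and_fit(Xall[inc], labels[inc], seed)
    whole_risk = clf.predict_proba(Xall)[:, 1]
    return {
        "oof_risk": oof_risk,
        "oof_score": oof_risk.copy(),
        "whole_risk": whole_risk,
        "whole_score": whole_risk.copy(),
        "hyperparams": chosen,
    }


def _surv_y(time, event):
    from sksurv.util import Surv

    return Surv.from_arrays(event=np.asarray(event, bool),
                            time=np.asarray(time, float))


def _rsf_risk_at(model, X, t_star):
    surv = model.predict_survival_function(X, return_array=False)
    return np.array([1.0 - fn(min(t_star, fn.domain[1])) for fn in surv])


def fit_tree_meta(
    meta: MetaFeatures,
    time,
    event,
    kind: str,
    config: FusionConfig | None = None,
) -> dict:
    """Tree-based meta-learners behind a fit/predict-risk contract.

    ``rsf_meta``: random survival forest, seeded random search over the
    candidate grid, selected by inner-CV C-index. ``xgb_meta``:
    gradient-boosted trees on the binary event-by-horizon endpoint,
    exhaustive depth x learning-rate grid, selected by inner-CV log-loss.
    """
    if kind not in ("rsf_meta", "xgb_meta"):
        raise ValueError("kind must be 'rsf_meta' or 'xgb_meta'")
    config = config or FusionConfig()
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    S = meta.scores()
    folds = meta.folds
    n = S.shape[0]
    t_star = config.t_star
    oof_risk = np.full(n, np.nan)
    oof_score = np.full(n, np.nan)
    rng = np.random.default_rng(config.seed)

    if kind == "rsf_meta":
        try:
            from sksurv.ensemble import RandomSurvivalForest
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "scikit-survival is required for rsf_meta; install it"
            ) from exc
        grid = config.rsf_grid()
        n_draw = min(config.rsf_draws, len(grid))
        draw_idx = rng.choice(len(grid), size=n_draw, replace=False)
        candidates = [grid[i] for i in draw_idx]

        def make(params, rs):
            mtry, node, trees, splits = params
            return RandomSurvivalForest(
                n_estimators=trees,
                max_features=mtry,
                min_samples_leaf=node,
                min_samples_split=max(2, splits),
                random_state=rs,
                n_jobs=1,
            )

        def fit_score(params, Xtr, ttr, etr, Xte, tte, ete, rs):
            model = make(params, rs)
            model.fit(Xtr, _surv_y(ttr, etr))
            return harrell_cindex(model.predict(Xte), tte, ete)

    else:
        from sklearn.ensemble import GradientBoostingClassifier
        from sklearn.metrics import log_loss

        candidates = list(
            itertools.product(config.xgb_depths, config.xgb_learning_rates)
        )

        def make(params, rs):
            depth, lr = params
            return GradientBoostingClassifier(
                max_depth=depth,
                learning_rate=lr,
                n_estimators=config.xgb_n_estimators,
                random_state=rs,
            )

    chosen = []
    for f in sorted(np.unique(folds)):
        tr = folds != f
        te = ~tr
        Xtr_all, Xte, _, _ = _standardise(S[tr], S[te])
        ttr, etr = time[tr], event[tr]
        inner = make_outer_folds(etr, k=config.inner_folds,
                                 seed=config.seed + 77 * (int(f) + 1))
        best = (-np.inf, candidates[0])
        for params in candidates:
            scores = []
            for g in range(config.inner_folds):
                itr = inner != g
                ite = ~itr
                if kind == "rsf_meta":
                    try:
                        c = fit_score(
                            params, Xtr_all[itr], ttr[itr], etr[itr],
                            Xtr_all[ite], ttr[ite], etr[ite], config.seed,
                        )
                    except ValueError:
                        continue
                    scores.append(c)
                else:
                    inc, lab = _landmark_labels(ttr[itr], etr[itr], t_star)
                    if lab[inc].min() == lab[inc].max():
                        continue
                    clf = make(params, config.seed)
                    clf.fit(Xtr_all[itr][inc], lab[inc])
                    inc2, lab2 = _landmark_labels(ttr[ite], etr[ite], t_star)
                    if inc2.sum() == 0:
                        continue
                    scores.append(
                        -log_loss(
                            lab2[inc2],
                            clf.predict_proba(Xtr_all[ite][inc2])[:, 1],
                            labels=[0, 1],
                        )
                    )
            mean_score = np.mean(scores) if scores else -np.inf
            if mean_score > best[0] + 1e-12:
                best = (mean_score, params)
        params = best[1]
        chosen.append(params)
        if kind == "rsf_meta":
            model = make(params, config.seed)
            model.fit(Xtr_all, _surv_y(ttr, etr))
            oof_risk[te] = _rsf_risk_at(model, Xte, t_star)
            oof_score[te] = model.predict(Xte)
        else:
            inc, lab = _landmark_labels(ttr, etr, t_star)
            model = make(params, config.seed)
            model.fit(Xtr_all[inc], lab[inc])
            oof_risk[te] = model.predict_proba(Xte)[:, 1]
            oof_score[te] = oof_risk[te]
    # whole-data variant with the modal selected configuration
    params = max(chosen, key=lambda p: (chosen.count(p), -chosen.index(p)))
    Xall = _standardise(S)[0]
    if kind == "rsf_meta":
        model = make(params, config.seed)
        model.fit(Xall, _surv_y(time, event))
        whole_risk = _rsf_risk_at(model, Xall, t_star)
        whole_score = model.predict(Xall)
    else:
        inc, lab = _landmark_labels(time, event, t_star)
        model = make(params, config.seed)
        model.fit(Xall[inc], lab[inc])
        whole_risk = model.predict_proba(Xall)[:, 1]
        whole_score = whole_risk.copy()
    return {
        "oof_risk": oof_risk,
        "oof_score": oof_score,
        "whole_risk": whole_risk,
        "whole_score": whole_score,
        "hyperparams": chosen,
        "search_space_size": (
            len(config.rsf_grid()) if kind == "rsf_meta" else len(candidates)
        ),
        "n_candidates_evaluated": len(candidates),
    }
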