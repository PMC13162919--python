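import numpy as np
import pytest

from fusesurv.metrics import (
    brier,
    calibration_groups,
    evaluate_model,
    harrell_cindex,
    integrated_brier,
    km_fit,
    td_auc,
)
from fusesurv.synthetic import (
    CohortSpec,
    generate_cohort,
    linear_predictor,
    true_absolute_risk,
)

from conftest import make_surv


# ---------------------------------------------------------------- oracles

def oracle_cindex(scores, time, event):
    """Brute-force enumeration of comparable pairs."""
    conc = comp = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / comp


def oracle_km(time, event):
    """Hand product-limit over distinct event times."""
    out = []
    s = 1.0
    for t in sorted(set(time[event == 1])):
        n_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1 - d / n_risk
        out.append((t, s))
    return out


def oracle_censoring_surv_before(time, event, t):
    """KM of censoring distribution evaluated at t- (deaths leave first)."""
    s = 1.0
    for u in sorted(set(time)):
        if u >= t:
            break
        n_risk = np.sum(time >= u)
        d = np.sum((time == u) & (event == 1))
        c = np.sum((time == u) & (event == 0))
        if c > 0:
            s *= 1 - c / (n_risk - d)
    return s


def oracle_td_auc(risks, time, event, t):
    """IPCW-weighted pair enumeration."""
    cases = [i for i in range(len(time)) if time[i] <= t and event[i] == 1]
    controls = [j for j in range(len(time)) if time[j] > t]
    num = den = 0.0
    for i in cases:
        w = 1.0 / oracle_censoring_surv_before(time, event, time[i])
        for j in controls:
            num += w * (
                1.0 if risks[i] > risks[j] else 0.5 if risks[i] == risks[j] else 0.0
            )
            den += w
    return num / den


def oracle_brier(S_pred, time, event, t):
    total = 0.0
    Gt_fn = oracle_censoring_surv_before
    # right-continuous G(t): evaluate just after t
    eps = 1e-9
    for i in range(len(time)):
        if time[i] <= t and event[i] == 1:
            total += S_pred[i] ** 2 / Gt_fn(time, event, time[i])
        elif time[i] > t:
            total += (1 - S_pred[i]) ** 2 / Gt_fn(time, event, t + eps)
    return total / len(time)


# ----------------------------------------------------------------- c-index

class TestHarrellCindex:
    def test_all_ties_half(self):
        time = np.array([1.0, 2.0, 3.0])
        assert harrell_cindex(np.ones(3), time, np.ones(3, int)) == 0.5

    def test_perfect_ranking(self):
        time = np.array([1.0, 2.0, 3.0])
        assert harrell_cindex([3, 2, 1], time, np.ones(3, int)) == 1.0

    def test_worked_example(self):
        # 3 concordant of 4 comparable pairs
        c = harrell_cindex(
            [0.9, 0.5, 0.2, 0.7],
            np.array([1.0, 2.0, 3.0, 4.0]),
            np.array([1, 0, 1, 1]),
        )
        assert c == pytest.approx(0.75, abs=1e-12)

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            _, time, event = make_surv(rng, 10)
            scores = rng.normal(size=10)
            assert harrell_cindex(scores, time, event) == pytest.approx(
                oracle_cindex(scores, time, event), abs=1e-10
            )

    def test_all_censored_error(self):
        with pytest.raises(ValueError):
            harrell_cindex([1, 2], np.array([1.0, 2.0]), np.zeros(2, int))

    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(1)
        _, time, event = make_surv(rng, 200)
        scores = rng.normal(size=200)
        assert harrell_cindex(scores, time, event) == pytest.approx(
            1.0 - concordance_index(time, scores, event), abs=1e-10
        )


# ---------------------------------------------------------------------- km

class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = km_fit(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, int))
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_identity(self):
        km = km_fit(np.array([1.0, 2.0]), np.zeros(2, int))
        assert km.times.size == 0
        assert km.at(5.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        km = km_fit(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        assert km.at(1.0) == pytest.approx(2 / 3, abs=1e-12)
        assert km.at(3.0) == pytest.approx(0.0, abs=1e-12)
        assert km.median() == pytest.approx(3.0)

    def test_no_censoring_equals_empirical(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(size=50)
        km = km_fit(time, np.ones(50, int))
        for t in rng.choice(time, 5, replace=False):
            assert km.at(t) == pytest.approx(np.mean(time > t), abs=1e-12)

    def test_matches_oracle_and_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        _, time, event = make_surv(rng, 100)
        km = km_fit(time, event)
        for t, s in oracle_km(time, event):
            assert km.at(t) == pytest.approx(s, abs=1e-10)
        kmf = KaplanMeierFitter().fit(time, event)
        for t in km.times:
            assert km.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_survival_nonincreasing(self):
        rng = np.random.default_rng(4)
        _, time, event = make_surv(rng, 200)
        km = km_fit(time, event)
        assert np.all(np.diff(km.survival) <= 1e-15)


# ------------------------------------------------------------------ td-auc

class TestTdAuc:
    def test_perfect_separation(self):
        time = np.array([0.5, 0.8, 2.0, 3.0])
        event = np.array([1, 1, 0, 1])
        risks = np.array([0.9, 0.8, 0.1, 0.2])
        assert td_auc(risks, time, event, 1.0) == 1.0

    def test_constant_score_half(self):
        rng = np.random.default_rng(5)
        _, time, event = make_surv(rng, 50)
        assert td_auc(np.ones(50), time, event, np.median(time)) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_matches_oracle_with_censoring(self):
        time = np.array([0.3, 0.6, 0.9, 1.2, 2.0, 2.5])
        event = np.array([1, 0, 1, 1, 0, 1])
        risks = np.array([0.9, 0.7, 0.4, 0.8, 0.2, 0.3])
        assert td_auc(risks, time, event, 1.0) == pytest.approx(
            oracle_td_auc(risks, time, event, 1.0), abs=1e-10
        )

    def test_no_censoring_equals_binary_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        _, time, event = make_surv(rng, 150, censor=0.0)
        risks = -time + rng.normal(scale=0.5, size=150)
        for t in np.quantile(time, [0.3, 0.6]):
            y = (time <= t).astype(int)
            assert td_auc(risks, time, event, t) == pytest.approx(
                roc_auc_score(y, risks), abs=1e-10
            )

    def test_errors(self):
        time = np.array([2.0, 3.0])
        with pytest.raises(ValueError, match="cases"):
            td_auc([1, 2], time, np.ones(2, int), 1.0)
        with pytest.raises(ValueError, match="controls"):
            td_auc([1, 2], time, np.ones(2, int), 5.0)


# ------------------------------------------------------------------- brier

class TestBrier:
    def test_perfect_predictions_zero(self):
        time = np.array([0.5, 1.5, 2.5, 3.5])
        event = np.ones(4, int)
        t = 2.0
        S = (time > t).astype(float)
        assert brier(S, time, event, t) == 0.0

    def test_constant_half_quarter(self):
        rng = np.random.default_rng(7)
        _, time, event = make_surv(rng, 60, censor=0.0)
        t = np.median(time)
        assert brier(np.full(60, 0.5), time, event, t) == pytest.approx(0.25)

    def test_no_censoring_equals_mse(self):
        rng = np.random.default_rng(8)
        _, time, event = make_surv(rng, 80, censor=0.0)
        S = rng.random(80)
        t = np.quantile(time, 0.4)
        mse = np.mean((S - (time > t)) ** 2)
        assert brier(S, time, event, t) == pytest.approx(mse, abs=1e-12)

    def test_matches_oracle_censored(self):
        time = np.array([0.3, 0.6, 0.9, 1.2, 2.0, 2.5, 3.0])
        event = np.array([1, 0, 1, 1, 0, 1, 0])
        S = np.array([0.1, 0.5, 0.3, 0.2, 0.9, 0.6, 0.8])
        for t in (1.0, 1.5, 2.2):
            assert brier(S, time, event, t) == pytest.approx(
                oracle_brier(S, time, event, t), abs=1e-10
            )

    def test_integrated_brier_constant_brier(self):
        rng = np.random.default_rng(9)
        _, time, event = make_surv(rng, 60, censor=0.0)
        tau = np.quantile(time, 0.8)
        # constant-half predictions: Brier = 0.25 at every t -> IBS = 0.25
        ibs = integrated_brier(lambda t: np.full(60, 0.5), time, event, tau)
        assert ibs == pytest.approx(0.25, abs=1e-12)

    def test_invalid_predictions(self):
        with pytest.raises(ValueError):
            brier([1.5], np.array([1.0]), np.array([1]), 0.5)


# -------------------------------------------------------------- calibration

class TestCalibration:
    def test_identity_line(self):
        # three groups engineered so observed event rate == mean predicted
        time = np.concatenate([
            np.r_[np.full(2, 0.5), np.full(8, 2.0)],   # 20% events by t=1
            np.r_[np.full(5, 0.5), np.full(5, 2.0)],   # 50%
            np.r_[np.full(8, 0.5), np.full(2, 2.0)],   # 80%
        ])
        event = np.ones(30, int)
        groups = np.repeat(["a", "b", "c"], 10)
        pred = np.repeat([0.2, 0.5, 0.8], 10)
        pts, slope, intercept = calibration_groups(pred, groups, time, event, 1.0)
        assert slope == pytest.approx(1.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_affine_shift(self):
        time = np.concatenate([
            np.r_[np.full(3, 0.5), np.full(7, 2.0)],
            np.r_[np.full(6, 0.5), np.full(4, 2.0)],
            np.r_[np.full(9, 0.5), np.full(1, 2.0)],
        ])
        event = np.ones(30, int)
        groups = np.repeat(["a", "b", "c"], 10)
        pred = np.repeat([0.2, 0.5, 0.8], 10)  # observed = pred + 0.1
        _, slope, intercept = calibration_groups(pred, groups, time, event, 1.0)
        assert slope == pytest.approx(1.0, abs=1e-10)
        assert intercept == pytest.approx(0.1, abs=1e-10)

    def test_generating_model_calibrated(self):
        spec = CohortSpec(n_patients=5000, seed=21)
        cohort = generate_cohort(spec)
        data = cohort.data
        Z = np.empty((len(data), 0))
        # reconstruct latent z from the affine map used by the generator
        fams = list(spec.family_sizes)
        zcols = []
        for k, fam in enumerate(fams):
            cols = [f for f in cohort.feature_names if f.startswith(fam + "_")]
            zcols.append((data[cols].to_numpy() - 10.0 * k) / (1.0 + 2.0 * k))
        Z = np.hstack(zcols)
        lp = linear_predictor(
            spec, Z,
            data["overall_stage"].to_numpy(),
            data["t_stage"].to_numpy(),
            data["n_stage"].to_numpy(),
            data["age"].to_numpy(),
            (data["gender"] == "male").to_numpy().astype(int),
        )
        risk = true_absolute_risk(spec, lp, 1.5)
        bins = np.digitize(risk, np.quantile(risk, np.linspace(0.1, 0.9, 9)))
        _, slope, intercept = calibration_groups(
            risk, bins, cohort.time, cohort.event, 1.5
        )
        assert 0.9 <= slope <= 1.1
        assert -0.05 <= intercept <= 0.05


# ----------------------------------------------------------- evaluate_model

class TestEvaluateModel:
    def test_null_scores_near_half(self):
        rng = np.random.default_rng(10)
        _, time, event = make_surv(rng, 400)
        scores = rng.normal(size=400)
        rep = evaluate_model(rng.random(400), scores, time, event)
        assert 0.4 < rep.c_index < 0.6
        assert 0.4 < rep.mean_auc < 0.6

    def test_report_finite_and_bootstrap(self):
        rng = np.random.default_rng(11)
        X, time, event = make_surv(rng, 300, signal=[0.8])
        scores = X[:, 0]
        risk = 1 / (1 + np.exp(-scores))
        rep = evaluate_model(risk, scores, time, event, n_bootstrap=25, seed=1)
        assert np.isfinite(rep.c_index) and np.isfinite(rep.ibs)
        assert 0 <= rep.c_index <= 1
        assert np.isfinite(rep.mean_auc)
        assert "c_index" in rep.ci
        lo, hi = rep.ci["c_index"]
        assert lo <= rep.c_index <= hi

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        X, time, event = make_surv(rng, 150, signal=[0.5])
        risk = 1 / (1 + np.exp(-X[:, 0]))
        r1 = evaluate_model(risk, X[:, 0], time, event, n_bootstrap=10, seed=3)
        r2 = evaluate_model(risk, X[:, 0], time, event, n_bootstrap=10, seed=3)
        assert r1.ci == r2.ci
        assert r1.c_index == r2.c_index
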