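"""Survival model evaluation: Harrell C-index, time-dependent AUC and
Brier score with inverse-probability-of-censoring weights, Kaplan-Meier,
integrated Brier score, and group-level calibration slope/intercept.

Everything here is implemented directly from the estimator definitions so
it can serve as an auditable reference implementation; censoring weights
use the Kaplan-Meier estimate of the censoring distribution evaluated
just before the relevant time (left limits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KaplanMeier",
    "MetricReport",
    "harrell_cindex",
    "km_fit",
    "censoring_km",
    "td_auc",
    "brier",
    "integrated_brier",
    "calibration_groups",
    "evaluate_model",
]


@dataclass
class KaplanMeier:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t), right-continuous; 1 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def at_minus(self, t: float) -> float:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.times, t, side="left")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def at_minus_many(self, ts) -> np.ndarray:
        """Vectorised left limits S(t-)."""
        idx = np.searchsorted(self.times, np.asarray(ts, float), side="left")
        out = np.ones(idx.size)
        nz = idx > 0
        out[nz] = self.survival[idx[nz] - 1]
        return out

    def median(self) -> float:
        """Smallest time with S(t) <= 0.5, or NaN when never reached."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else float("nan")


@dataclass
class MetricReport:
    c_index: float
    auc_times: np.ndarray
    td_auc: np.ndarray
    mean_auc: float
    brier_times: np.ndarray
    brier: np.ndarray
    ibs: float
    calibration_slope: float = np.nan
    calibration_intercept: float = np.nan
    ci: dict = field(default_factory=dict)


def harrell_cindex(scores, time, event) -> float:
    """Concordance over comparable pairs; ties in score credit 0.5.

    A pair is comparable iff the earlier observed time belongs to an event
    (tied times with one event are comparable in the usual orientation).
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = time.size
    conc = 0.0
    comp = 0
    # i restricted to events: only events can be the earlier member
    ev_idx = np.flatnonzero(event == 1)
    for i in ev_idx:
        later = time > time[i]
        m = int(later.sum())
        if m:
            comp += m
            conc += np.sum(scores[i] > scores[later])
            conc += 0.5 * np.sum(scores[i] == scores[later])
    if comp == 0:
        raise ValueError("no comparable pairs (all observations censored?)")
    return float(conc / comp)


def km_fit(time, event) -> KaplanMeier:
    """Kaplan-Meier product-limit estimator.

    Ties at a time are processed jointly; patients censored exactly at an
    event time are counted as at risk for that event (events first).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    uniq = np.unique(t)
    times, surv, at_risk, nev = [], [], [], []
    s = 1.0
    n_risk = t.size
    for u in uniq:
        mask = t == u
        d_u = int(d[mask].sum())
        c_u = int(mask.sum()) - d_u
        if d_u > 0:
            s *= 1.0 - d_u / n_risk
            times.append(u)
            surv.append(s)
            at_risk.append(n_risk)
            nev.append(d_u)
        n_risk -= d_u + c_u
    return KaplanMeier(
        times=np.array(times),
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(nev, dtype=int),
    )


def censoring_km(time, event) -> KaplanMeier:
    """KM of the censoring distribution G (event indicator flipped).

    At tied times deaths are removed from the risk set before censorings
    are processed, the standard convention for IPCW weights.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    uniq = np.unique(time)
    times, surv, at_risk, nc = [], [], [], []
    s = 1.0
    n_risk = time.size
    for u in uniq:
        mask = time == u
        d_u = int(event[mask].sum())
        c_u = int(mask.sum()) - d_u
        if c_u > 0:
            # deaths at u leave first
            s *= 1.0 - c_u / (n_risk - d_u) if n_risk - d_u > 0 else 0.0
            times.append(u)
            surv.append(s)
            at_risk.append(n_risk - d_u)
            nc.append(c_u)
        n_risk -= d_u + c_u
    return KaplanMeier(
        times=np.array(times),
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(nc, dtype=int),
    )


def td_auc(risks, time, event, t: float) -> float:
    """Cumulative/dynamic time-dependent AUC with IPCW on the cases.

    Cases: event observed by t. Controls: still under observation beyond t.
    Case i is weighted by 1/G(T_i-); the common control weight 1/G(t)
    cancels in the ratio. Score ties credit 0.5.
    """
    risks = np.asarray(risks, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    cases = (time <= t) & (event == 1)
    controls = time > t
    if not cases.any():
        raise ValueError(f"no cases (events by t={t})")
    if not controls.any():
        raise ValueError(f"no controls (observations beyond t={t})")
    G = censoring_km(time, event)
    w = 1.0 / G.at_minus_many(time[cases])
    rc = risks[cases]
    rk = risks[controls]
    gt = (rc[:, None] > rk[None, :]).sum(axis=1)
    eq = (rc[:, None] == rk[None, :]).sum(axis=1)
    num = float(np.sum(w * (gt + 0.5 * eq)))
    den = float(w.sum() * controls.sum())
    return num / den


def brier(pred_surv_at_t, time, event, t: float) -> float:
    """IPCW Brier score at time t (Graf convention).

    Patients with an event by t contribute (0 - S)^2 / G(T_i-); patients
    beyond t contribute (1 - S)^2 / G(t); patients censored before t
    contribute only through the weight normalisation (divisor n).
    """
    S = np.asarray(pred_surv_at_t, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if np.any((S < 0) | (S > 1)):
        raise ValueError("predicted survival probabilities must lie in [0,1]")
    G = censoring_km(time, event)
    n = time.size
    Gt = G.at(t)
    dead = (time <= t) & (event == 1)
    alive = time > t
    g_dead = G.at_minus_many(time[dead])
    if np.any(g_dead <= 0) or (alive.any() and Gt <= 0):
        raise ValueError(
            "censoring KM weight 0 encountered; truncate the time grid"
        )
    total = float(np.sum(S[dead] ** 2 / g_dead))
    total += float(np.sum((1.0 - S[alive]) ** 2)) / Gt if alive.any() else 0.0
    return total / n


def integrated_brier(pred_surv_fn, time, event, tau: float, grid=None) -> float:
    """Trapezoidal average of the Brier score over [grid[0], tau].

    ``pred_surv_fn(t)`` returns the per-patient predicted survival at t.
    """
    if grid is None:
        grid = np.linspace(0.05 * tau, tau, 20)
    grid = np.asarray(grid, float)
    bs = np.array([brier(pred_surv_fn(t), time, event, t) for t in grid])
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


def calibration_groups(pred_risk_at_t, groups, time, event, t: float):
    """Group-level calibration: mean predicted risk vs 1 - KM(t) per group.

    Returns (points, slope, intercept) where points is a list of
    (group, mean_predicted, observed) tuples and the line is the
    least-squares fit of observed on predicted.
    """
    pred = np.asarray(pred_risk_at_t, float)
    groups = np.asarray(groups)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    pts = []
    for g in np.unique(groups):
        mask = groups == g
        km = km_fit(time[mask], event[mask])
        if km.times.size and t > np.max(time[mask]):
            logger.warning("group %s KM undefined at t=%.3g; dropped", g, t)
            continue
        obs = 1.0 - km.at(t)
        pts.append((g, float(pred[mask].mean()), float(obs)))
    if len(pts) < 2:
        raise ValueError("fewer than 2 calibration groups with defined KM")
    x = np.array([p[1] for p in pts])
    y = np.array([p[2] for p in pts])
    slope, intercept = np.polyfit(x, y, 1)
    return pts, float(slope), float(intercept)


def _default_time_grid(time, event, tau):
    ev_times = np.asarray(time)[np.asarray(event) == 1]
    ev_times = ev_times[(ev_times >= 0.25) & (ev_times <= tau)]
    if ev_times.size == 0:
        raise ValueError("no event times inside [0.25, tau]")
    qs = np.quantile(ev_times, np.linspace(0.1, 0.9, 9))
    return np.unique(qs)


def evaluate_model(
    oof_risks,
    oof_scores,
    time,
    event,
    times=None,
    tau: float | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
    surv_fn=None,
) -> MetricReport:
    """Assemble the full discrimination / prediction-error report.

    ``oof_risks`` are absolute risks at the landmark (used for Brier via
    ``1 - risk`` unless a richer ``surv_fn(t)`` is supplied); ``oof_scores``
    are ranking scores for C-index/AUC. The AUC column is the mean td-AUC
    over the time grid.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if tau is None:
        tau = 0.8 * float(time.max())
    if times is None:
        times = _default_time_grid(time, event, tau)
    times = np.asarray(times, float)

    def compute(idx):
        t_, e_ = time[idx], event[idx]
        sc = np.asarray(oof_scores, float)[idx]
        rk = np.asarray(oof_risks, float)[idx]
        c = harrell_cindex(sc, t_, e_)
        aucs = []
        for t in times:
            try:
                aucs.append(td_auc(sc, t_, e_, t))
            except ValueError:
                aucs.append(np.nan)
        aucs = np.array(aucs)
        if surv_fn is not None:
            fn = lambda t: np.asarray(surv_fn(t), float)[idx]
        else:
            fn = lambda t: 1.0 - rk  # horizon-static surrogate
        bs = np.array([brier(np.clip(fn(t), 0, 1), t_, e_, t) for t in times])
        ibs = integrated_brier(lambda t: np.clip(fn(t), 0, 1), t_, e_, tau,
                               grid=times)
        return c, aucs, bs, ibs

    idx_all = np.arange(time.size)
    c, aucs, bs, ibs = compute(idx_all)
    report = MetricReport(
        c_index=c,
        auc_times=times,
        td_auc=aucs,
        mean_auc=float(np.nanmean(aucs)),
        brier_times=times,
        brier=bs,
        ibs=ibs,
    )
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        stats = {"c_index": [], "mean_auc": [], "ibs": []}
        for _ in range(n_bootstrap):
            idx = rng.integers(0, time.size, time.size)
            try:
                cb, ab, _, ib = compute(idx)
            except ValueError:
                continue
            stats["c_index"].append(cb)
            stats["mean_auc"].append(float(np.nanmean(ab)))
            stats["ibs"].append(ib)
        for k, v in stats.items():
            if v:
                lo, hi = np.percentile(v, [2.5, 97.5])
                report.ci[k] = (float(lo), float(hi))
    return report
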